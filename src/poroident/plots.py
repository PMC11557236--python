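"""Figure generation for the identifiability analyses.

All functions take result objects and return a matplotlib Figure; the
CLI saves them as vector graphics.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .eigen import EigenReport
from .global_identifiability import ClusterTree, CorrelationMatrix
from .optimizer_diagnostics import (RANDOM_GUESS_BASELINE, TEN_PCT_BASELINE,
                                    ErrorReport, OptimizationTrace)


def correlation_heatmap(corr: CorrelationMatrix,
                        tree: ClusterTree | None = None):
    """Correlation-vector heatmap, rows ordered by the UPGMA dendrogram."""
    names = list(corr.parameter_names)
    if tree is not None:
        order = [n for n in tree.leaf_order() if n in names]
        idx = [names.index(n) for n in order]
    else:
        order, idx = names, list(range(len(names)))
    vals = corr.values[idx]
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.imshow(vals, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_yticks(range(len(order)), order)
    # annotate protocol segment boundaries
    segs = [lbl.split(" t=")[0] for lbl in corr.time_labels]
    bounds = [i for i in range(1, len(segs)) if segs[i] != segs[i - 1]]
    for b in bounds:
        ax.axvline(b - 0.5, color="k", lw=0.5)
    ax.set_xlabel("protocol time point (ramp/hold segments)")
    fig.colorbar(im, ax=ax, label=r"Pearson $\rho$(parameter, $F_z$)")
    fig.tight_layout()
    return fig


def eigen_spectrum(report: EigenReport, log: bool = False):
    """Bar plot of the (normalized) eigen-spectrum with its threshold line."""
    fig, ax = plt.subplots(figsize=(6, 4))
    n = report.eigenvalues.size
    x = np.arange(1, n + 1)
    if report.kind == "percent":
        vals = report.normalized_pct
        ax.axhline(report.threshold, color="r", ls=":",
                   label=f"{report.threshold:g} % threshold")
        ax.set_ylabel("eigenvalue (% of sum)")
        if log:
            ax.set_yscale("log")
        ax.bar(x, vals, color="steelblue")
    else:
        vals = report.eigenvalues
        pos = vals > 0
        ax.bar(x[pos], vals[pos], color="steelblue", label="positive")
        if (~pos).any():
            ax.bar(x[~pos], -vals[~pos], color="firebrick", label="negative")
        ax.axhline(report.threshold, color="g", ls=":",
                   label="numerical noise floor")
        ax.set_yscale("log")
        ax.set_ylabel("|eigenvalue|")
    ax.set_xlabel("eigenvector index")
    ax.legend()
    fig.tight_layout()
    return fig


def hessian_spectra(reports: list[EigenReport], noise_floor: float):
    """Eigenvalues of several Hessians (one marker column per truth)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for k, rep in enumerate(reports):
        lam = rep.eigenvalues
        pos = lam > 0
        ax.scatter(np.full(pos.sum(), k + 1), lam[pos], marker="o",
                   color="steelblue", s=18)
        ax.scatter(np.full((~pos).sum(), k + 1), -lam[~pos], marker="x",
                   color="firebrick", s=18)
    ax.axhline(noise_floor, color="g", ls=":", label="noise floor")
    ax.set_yscale("log")
    ax.set_xlabel("truth sample")
    ax.set_ylabel("|eigenvalue| (o positive, x negative)")
    ax.legend()
    fig.tight_layout()
    return fig


def convergence_plot(trace: OptimizationTrace):
    """Cost and parameter-estimate evolution across iterations."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.semilogy(trace.costs, color="k")
    ax1.set_ylabel("SSE cost")
    its = np.array(trace.iterates)
    for j in range(its.shape[1]):
        ax2.plot(its[:, j], lw=0.8)
    if trace.theta_star is not None:
        for v in trace.theta_star:
            ax2.axhline(v, color="gray", lw=0.4, ls=":")
    ax2.set_xlabel("iteration")
    ax2.set_ylabel("scaled estimate")
    fig.tight_layout()
    return fig


def error_boxplot(report: ErrorReport):
    """Distribution of scaled estimation errors per parameter."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(np.abs(report.errors), tick_labels=list(report.parameter_names),
               whis=(0, 100))
    ax.axhline(TEN_PCT_BASELINE, color="orange", ls=":", label="10% of range")
    ax.axhline(RANDOM_GUESS_BASELINE, color="r", ls=":",
               label="random guess (E|U-V| = 1/3)")
    ax.set_ylabel(r"|$\hat\theta - \theta^*$| (scaled)")
    ax.legend()
    fig.tight_layout()
    return fig
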