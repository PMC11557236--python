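"""Study orchestration: run configured analyses and render reports.

`run_study` executes the requested analysis blocks in dependency order
and writes all artifacts (CSV/JSON + trace stores) with provenance
metadata.  `render_reports` reads artifacts back from disk — never
recomputing them — and produces the figures and a text summary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import StudyConfig
from .constitutive import BiphasicParameters
from .eigen import EigenReport
from .global_identifiability import (CorrelationMatrix, cluster_parameters,
                                     correlation_vectors, run_ensemble,
                                     sensitivity_indices, svd_identifiability)
from .local_identifiability import (fd_hessian, hessian_eigen_report,
                                    make_biphasic_cost, step_size_sweep)
from .optimizer_diagnostics import error_report, fit_truth_set, make_truth_set
from .parameters import SampleSet, full_factorial, sample_uniform
from .simulator import solve_confined_compression, validate_simulation

log = logging.getLogger("poroident")


def _eigen_to_json(report: EigenReport) -> dict:
    return {
        "eigenvalues": report.eigenvalues.tolist(),
        "normalized_pct": report.normalized_pct.tolist(),
        "eigenvectors": report.eigenvectors.tolist(),
        "parameter_names": list(report.parameter_names),
        "threshold": report.threshold,
        "kind": report.kind,
        "n_identifiable": report.n_identifiable,
    }


def _eigen_from_json(d: dict) -> EigenReport:
    return EigenReport(np.array(d["eigenvalues"]), np.array(d["eigenvectors"]),
                       tuple(d["parameter_names"]), d["threshold"], d["kind"])


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured analyses; return the artifact directory."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "study.log")
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    space = config.space()
    protocol = config.protocol.build()
    grid = config.grid.build()
    env = config.environment.build()
    (out / "provenance.json").write_text(json.dumps({
        "config": config.model_dump(mode="json"),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "code_version": __version__,
    }, indent=2))

    try:
        if config.simulate is not None:
            log.info("running single simulation")
            theta = (np.array(config.simulate.theta)
                     if config.simulate.theta is not None else space.midpoint)
            res = solve_confined_compression(
                BiphasicParameters.from_array(theta), protocol, grid, env,
                substeps=config.simulate.substeps)
            d = out / "simulate"
            d.mkdir(exist_ok=True)
            res.to_frame().to_csv(d / "force.csv", index=False)
            rep = validate_simulation(res, protocol)
            (d / "diagnostics.json").write_text(json.dumps({
                "eps_fs": res.eps_fs, "lam0": res.lam0,
                "min_J": res.min_J,
                "displacement_error_mm": res.displacement_error,
                "adherence": {
                    "all_times_present": rep.all_times_present,
                    "displacement_ok": rep.displacement_ok,
                    "solver_converged": rep.solver_converged,
                    "invariants_ok": rep.invariants_ok,
                    "passed": rep.passed}}, indent=2))

        if config.global_analysis is not None:
            gc = config.global_analysis
            log.info("global identifiability analysis (levels=%d)", gc.levels)
            if gc.free_parameters:
                from .parameters import ParameterSpace
                sub = ParameterSpace.subset(space, gc.free_parameters)
                design = full_factorial(sub, gc.levels)
                data = np.tile(space.midpoint, (design.n_samples, 1))
                for j, name in enumerate(sub.names):
                    data[:, space.index(name)] = design.data[:, j]
                samples = SampleSet(data, space.names, "factorial",
                                    levels=gc.levels)
            else:
                samples = full_factorial(space, gc.levels)
            d = out / "global"
            d.mkdir(exist_ok=True)
            samples.save(d / "samples.csv")
            ens = run_ensemble(samples, protocol, grid, env,
                               substeps=gc.substeps,
                               cache_path=d / "ensemble_cache.npz")
            pd.DataFrame(ens.excluded, columns=["id", "reason"]).to_csv(
                d / "exclusions.csv", index=False)
            pd.DataFrame(ens.forces,
                         index=[samples.ids[i] for i in ens.retained],
                         columns=[f"{t:.6g}" for t in ens.times]
                         ).to_csv(d / "forces.csv", index_label="id")
            corr = correlation_vectors(ens)
            corr.to_frame().to_csv(d / "correlation.csv", index_label="parameter")
            tree = cluster_parameters(corr)
            tree.to_frame().to_csv(d / "linkage.csv", index=False)
            (d / "leaf_order.json").write_text(json.dumps(tree.leaf_order()))
            report = svd_identifiability(corr, gc.threshold_pct)
            (d / "eigen.json").write_text(json.dumps(_eigen_to_json(report),
                                                     indent=2))
            report.to_frame().to_csv(d / "eigen.csv", index_label="parameter")
            sens = sensitivity_indices(ens)
            s1, st = sens.to_frames()
            s1.to_csv(d / "sensitivity_first.csv", index_label="parameter")
            st.to_csv(d / "sensitivity_total.csv", index_label="parameter")
            log.info("global: %d retained, %d excluded, %d constrained",
                     ens.n_retained, len(ens.excluded), report.n_identifiable)

        if config.local_analysis is not None:
            lc = config.local_analysis
            log.info("local identifiability analysis (n=%d)", lc.n_truths)
            d = out / "local"
            d.mkdir(exist_ok=True)
            truths = sample_uniform(space, lc.n_truths, config.seed)
            truths.save(d / "truths.csv")
            for i in range(lc.n_truths):
                x_star = space.scale(truths.data[i])
                cost = make_biphasic_cost(x_star, space, protocol, grid, env,
                                          substeps=lc.substeps)
                hrep = fd_hessian(cost, x_star, lc.step)
                hrep.to_frame(space.names).to_csv(d / f"hessian_{i:02d}.csv")
                erep = hessian_eigen_report(hrep, lc.noise_floor, space.names)
                (d / f"eigen_{i:02d}.json").write_text(
                    json.dumps(_eigen_to_json(erep), indent=2))
                if lc.sweep:
                    sw = step_size_sweep(cost, x_star)
                    sw.to_frame().to_csv(d / f"sweep_{i:02d}.csv", index=False)

        if config.optimize is not None:
            oc = config.optimize
            log.info("optimizer diagnostics (n=%d)", oc.n_truths)
            d = out / "optimize"
            d.mkdir(exist_ok=True)
            tset = make_truth_set(space, oc.n_truths, config.seed, protocol,
                                  grid, env, substeps=oc.substeps)
            tset.samples.save(d / "truths.csv")
            for method in oc.methods:
                traces = fit_truth_set(tset, space, protocol, grid, env,
                                       method=method, substeps=oc.substeps,
                                       max_fev=oc.max_fev)
                tdir = d / "traces"
                for i, tr in enumerate(traces):
                    tr.save(tdir, f"{method}_{i:02d}")
                rep = error_report(traces, space)
                rep.to_frame().to_csv(d / f"errors_{method}.csv",
                                      index_label="parameter")
                (d / f"error_report_{method}.json").write_text(json.dumps({
                    "median_abs": rep.median_abs.tolist(),
                    "parameter_names": list(rep.parameter_names),
                    "errors": rep.errors.tolist(),
                    "baseline_random": rep.baseline_random,
                    "baseline_ten_pct": rep.baseline_ten_pct}, indent=2))
    finally:
        log.removeHandler(fh)
        fh.close()
    return out


def render_reports(artifact_dir: str | Path) -> tuple[Path, list[str]]:
    """Render figures and a text summary from a study's artifacts.

    Every numeric value in the summary is re-read from the artifact
    files.  Missing artifacts produce explicit per-figure skip messages;
    if nothing at all is found a FileNotFoundError is raised.
    """
    from . import plots
    from .global_identifiability import ClusterTree

    art = Path(artifact_dir)
    fig_dir = art / "figures"
    messages: list[str] = []
    summary: list[str] = []
    rendered = 0

    gdir = art / "global"
    if (gdir / "correlation.csv").exists():
        fig_dir.mkdir(exist_ok=True)
        cdf = pd.read_csv(gdir / "correlation.csv", index_col="parameter")
        corr = CorrelationMatrix(cdf.to_numpy(), tuple(cdf.index),
                                 list(cdf.columns))
        tree = None
        if (gdir / "linkage.csv").exists():
            Z = pd.read_csv(gdir / "linkage.csv").to_numpy()
            leaf_names = tuple(sorted(cdf.index))
            tree = ClusterTree(Z, leaf_names, np.array([]))
        plots.correlation_heatmap(corr, tree).savefig(
            fig_dir / "correlation_heatmap.svg")
        rendered += 1
    else:
        messages.append("skip correlation heatmap: global/correlation.csv missing")

    if (gdir / "eigen.json").exists():
        fig_dir.mkdir(exist_ok=True)
        rep = _eigen_from_json(json.loads((gdir / "eigen.json").read_text()))
        plots.eigen_spectrum(rep).savefig(fig_dir / "global_eigen.svg")
        plots.eigen_spectrum(rep, log=True).savefig(
            fig_dir / "global_eigen_log.svg")
        summary.append(f"global analysis: {rep.n_identifiable} constrained "
                       f"directions (threshold {rep.threshold:g} % of "
                       "eigenvalue sum)")
        rendered += 1
    else:
        messages.append("skip global eigen spectrum: global/eigen.json missing")

    ldir = art / "local"
    ljsons = sorted(ldir.glob("eigen_*.json")) if ldir.exists() else []
    if ljsons:
        fig_dir.mkdir(exist_ok=True)
        reps = [_eigen_from_json(json.loads(p.read_text())) for p in ljsons]
        plots.hessian_spectra(reps, reps[0].threshold).savefig(
            fig_dir / "local_eigen.svg")
        counts = [r.n_identifiable for r in reps]
        summary.append(f"local analysis: {int(np.median(counts))} constrained "
                       f"directions (median over {len(counts)} truths; "
                       f"range {min(counts)}-{max(counts)})")
        rendered += 1
    else:
        messages.append("skip Hessian spectra: local/eigen_*.json missing")

    odir = art / "optimize"
    ejsons = sorted(odir.glob("error_report_*.json")) if odir.exists() else []
    for p in ejsons:
        fig_dir.mkdir(exist_ok=True)
        d = json.loads(p.read_text())
        from .optimizer_diagnostics import ErrorReport
        rep = ErrorReport(np.array(d["errors"]), tuple(d["parameter_names"]),
                          np.array(d["median_abs"]))
        method = p.stem.replace("error_report_", "")
        plots.error_boxplot(rep).savefig(fig_dir / f"errors_{method}.svg")
        n_bad = int(rep.exceeds_ten_pct.sum())
        summary.append(f"optimizer ({method}): {n_bad}/"
                       f"{len(rep.parameter_names)} parameters with median "
                       "error above 10 % of range")
        rendered += 1
        tr = sorted((odir / "traces").glob(f"{method}_*.npz"))
        if tr:
            from .optimizer_diagnostics import OptimizationTrace
            with np.load(tr[0]) as z:
                trace = OptimizationTrace(
                    method=method, theta_star=z["theta_star"],
                    x0=z["x0"], xhat=z["xhat"], fun=float(z["costs"][-1]),
                    status="", n_fev=0,
                    iterates=list(z["iterates"]), costs=list(z["costs"]))
            plots.convergence_plot(trace).savefig(
                fig_dir / f"convergence_{method}_00.svg")
    if not ejsons:
        messages.append("skip error box plot: optimize/error_report_*.json missing")

    if rendered == 0:
        raise FileNotFoundError(
            f"no renderable artifacts under {art}: " + "; ".join(messages))
    (art / "summary.txt").write_text("\n".join(summary) + "\n")
    return fig_dir, messages
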