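"""Global identifiability analysis over a sampled parameter space.

Pipeline: run the forward model over a (typically full factorial)
sample set; form per-time-point Pearson correlation vectors between
each parameter and F_z; cluster the vectors by UPGMA with unsigned
cosine distance; and count linearly independent parameter-space
directions via SVD of the correlation matrix with a threshold of 1 % of
the eigenvalue sum.  First-order and total sensitivity indices are
computed by exact factorial ANOVA decomposition on the same ensemble.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .constitutive import BiphasicParameters, Environment
from .eigen import EigenReport
from .exceptions import PoroidentError
from .parameters import SampleSet
from .simulator import (Grid1D, Protocol, solve_confined_compression,
                        validate_simulation)


@dataclass
class EnsembleResult:
    """Forward-model outputs for the retained samples of a design."""

    samples: SampleSet
    times: np.ndarray
    segments: list[str]
    forces: np.ndarray  # (n_retained, T)
    retained: np.ndarray  # indices into samples
    excluded: list[tuple[str, str]]  # (sample id, reason)
    n_simulated: int = 0  # simulations actually run (cache misses)

    @property
    def n_retained(self) -> int:
        return self.forces.shape[0]

    def retained_matrix(self) -> np.ndarray:
        """Parameter values of retained samples, (n_retained, P)."""
        return self.samples.data[self.retained]


def _row_key(row: np.ndarray, settings: tuple) -> str:
    h = hashlib.sha1()
    h.update(np.asarray(row, dtype=float).tobytes())
    h.update(repr(settings).encode())
    return h.hexdigest()


def run_ensemble(samples: SampleSet,
                 protocol: Protocol | None = None,
                 grid: Grid1D | None = None,
                 env: Environment | None = None,
                 *, substeps: int = 1,
                 cache_path: str | Path | None = None,
                 log_squared: bool = False,
                 progress: bool = False) -> EnsembleResult:
    """Simulate the protocol for every sample; exclude protocol deviations.

    Rows whose simulation fails the automatic adherence checks (or whose
    free-swelling solve fails) are excluded and logged with a reason.
    With `cache_path`, already-computed rows (matched by a content hash
    of the parameter vector and solver settings) are reused, making
    re-runs idempotent.
    """
    protocol = protocol or Protocol()
    grid = grid or Grid1D()
    env = env or Environment()
    settings = (protocol.initial_height, protocol.initial_diameter,
                protocol.n_increments, protocol.increment_strain,
                protocol.ramp_duration, protocol.hold_duration,
                protocol.points_per_ramp, protocol.points_per_hold,
                grid.n_nodes, env.T, env.c_star, substeps, log_squared)

    cache: dict[str, np.ndarray] = {}
    if cache_path is not None:
        cache_path = Path(cache_path)
        if cache_path.exists():
            with np.load(cache_path, allow_pickle=False) as z:
                cache = {k: z[k] for k in z.files}

    times = protocol.output_times()
    forces, retained, excluded = [], [], []
    n_sim = 0
    for i in range(samples.n_samples):
        row = samples.data[i]
        key = _row_key(row, settings) if cache_path is not None else None
        if key is not None and key in cache:
            forces.append(cache[key])
            retained.append(i)
            continue
        try:
            params = BiphasicParameters.from_array(row)
            res = solve_confined_compression(
                params, protocol, grid, env, substeps=substeps,
                store_fields=False, log_squared=log_squared)
            n_sim += 1
        except (PoroidentError, ValueError) as exc:
            excluded.append((samples.ids[i], f"simulation error: {exc}"))
            continue
        report = validate_simulation(res, protocol)
        if not report.passed:
            reasons = [n for n, ok in (
                ("missing output times", report.all_times_present),
                ("displacement deviation", report.displacement_ok),
                ("solver divergence", report.solver_converged),
                ("invariant violation", report.invariants_ok)) if not ok]
            excluded.append((samples.ids[i], "; ".join(reasons)))
            continue
        forces.append(res.force)
        retained.append(i)
        if key is not None:
            cache[key] = res.force
        if progress and (i + 1) % 5000 == 0:
            print(f"  ensemble: {i + 1}/{samples.n_samples}")

    if cache_path is not None:
        np.savez_compressed(cache_path, **cache)

    return EnsembleResult(
        samples=samples, times=times, segments=protocol.segment_labels(),
        forces=np.array(forces) if forces else np.empty((0, times.size)),
        retained=np.array(retained, dtype=int), excluded=excluded,
        n_simulated=n_sim)


@dataclass
class CorrelationMatrix:
    """Per-parameter, per-time-point Pearson correlation with F_z."""

    values: np.ndarray  # (P, T)
    parameter_names: tuple[str, ...]
    time_labels: list[str]
    zero_variance: np.ndarray = field(default=None)  # per-parameter flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.parameter_names),
                            columns=self.time_labels)


def correlation_vectors(ensemble: EnsembleResult) -> CorrelationMatrix:
    """Pearson correlation between each parameter and F_z at each time.

    If either variance is zero at a time point the correlation is set to
    0 (documented convention for inert parameters / flat outputs).

    On a balanced full factorial design with no exclusions, each
    parameter column is replaced by its (affinely equivalent) integer
    level codes and the covariance is accumulated level by level; the
    balanced level subsets of an unused parameter then sum to
    bit-identical values, so its correlations are exactly zero.
    """
    if ensemble.n_retained < 3:
        raise ValueError("need at least 3 retained samples for correlations")
    X = ensemble.retained_matrix()  # (n, P)
    F = ensemble.forces  # (n, T)
    n, P = X.shape
    balanced = (ensemble.samples.kind == "factorial"
                and not ensemble.excluded
                and ensemble.n_retained == ensemble.samples.n_samples)
    Fc = F - F.mean(axis=0)
    sf = np.sqrt((Fc ** 2).sum(axis=0))
    if balanced:
        codes = np.empty_like(X)
        for j in range(P):
            _, codes[:, j] = np.unique(X[:, j], return_inverse=True)
        X = codes  # Pearson is invariant under the affine level map
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    if balanced:
        num = np.empty((P, F.shape[1]))
        for j in range(P):
            acc = np.zeros(F.shape[1])
            for c in np.unique(Xc[:, j]):
                if c != 0.0:
                    acc += c * Fc[Xc[:, j] == c].sum(axis=0)
            num[j] = acc
    else:
        num = Xc.T @ Fc  # (P, T)
    denom = np.outer(sx, sf)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, num / np.where(denom == 0, 1.0, denom), 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    labels = [f"{seg} t={t:.6g}" for seg, t in
              zip(ensemble.segments, ensemble.times)]
    zero_var = sx == 0
    return CorrelationMatrix(rho, ensemble.samples.names, labels, zero_var)


@dataclass
class ClusterTree:
    """UPGMA linkage over parameters (leaves are parameter names)."""

    linkage_matrix: np.ndarray  # scipy format
    leaf_names: tuple[str, ...]  # order passed to linkage (lexicographic)
    distances: np.ndarray  # condensed pairwise distances
    no_effect: tuple[str, ...] = ()  # parameters with zero-norm vectors

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        """Dendrogram leaf order (used to order heatmap rows)."""
        return [self.leaf_names[i] for i in leaves_list(self.linkage_matrix)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage_matrix,
                            columns=["left", "right", "height", "count"])


def unsigned_cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d(u, v) = 1 - |u . v| / (|u| |v|); sign-flipped effects coincide."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 1.0
    return float(1.0 - abs(np.dot(u, v)) / (nu * nv))


def cluster_parameters(corr: CorrelationMatrix) -> ClusterTree:
    """UPGMA (average linkage) over unsigned-cosine distances.

    Leaves are sorted lexicographically before linkage so that scipy's
    index-order tie-breaking realizes a deterministic lexicographic
    tie-break.  A parameter with a zero-norm correlation vector gets
    distance 1 to all others and is flagged as having no direct effect.
    """
    names = sorted(corr.parameter_names)
    idx = [corr.parameter_names.index(n) for n in names]
    V = corr.values[idx]
    P = len(names)
    D = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            D[i, j] = D[j, i] = unsigned_cosine_distance(V[i], V[j])
    Z = linkage(squareform(D, checks=False), method="average")
    no_effect = tuple(n for n, v in zip(names, V) if np.linalg.norm(v) == 0)
    return ClusterTree(Z, tuple(names), squareform(D, checks=False), no_effect)


def svd_identifiability(corr: CorrelationMatrix,
                        threshold_pct: float = 1.0,
                        *, use_squares: bool = True) -> EigenReport:
    """Count constrained parameter-space directions via SVD of rho.

    Eigenvalues are the squared singular values of the P x T correlation
    matrix (eigenvalues of rho rho^T), normalized to percent of their
    sum; eigenvectors are the left singular vectors.  `use_squares=False`
    switches to raw singular values for sensitivity checking.
    """
    rho = np.asarray(corr.values, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise ValueError("correlation matrix contains non-finite entries")
    U, s, _ = np.linalg.svd(rho, full_matrices=False)
    lam = s ** 2 if use_squares else s
    return EigenReport(lam, U, corr.parameter_names, threshold_pct, "percent")


@dataclass
class SensitivityResult:
    """First-order (S_i) and total (ST_i) sensitivity indices per time point."""

    first_order: np.ndarray  # (P, T)
    total: np.ndarray  # (P, T)
    parameter_names: tuple[str, ...]
    time_labels: list[str]
    unbalanced: bool  # True if exclusions broke the factorial balance

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = list(self.parameter_names)
        return (pd.DataFrame(self.first_order, index=idx, columns=self.time_labels),
                pd.DataFrame(self.total, index=idx, columns=self.time_labels))


def sensitivity_indices(ensemble: EnsembleResult) -> SensitivityResult:
    """Exact factorial ANOVA sensitivity indices on a (near-)balanced design.

    S_i(t) = Var_levels(mean F | level of i) / Var(F);
    ST_i(t) = 1 - Var(mean F | levels of all parameters except i) / Var(F).
    Level means are equally weighted; on a balanced full factorial this
    is the exact functional-ANOVA decomposition.  If exclusions broke
    the balance the indices are computed on the retained rows and the
    `unbalanced` flag is set (documented bias warning).
    """
    X = ensemble.retained_matrix()
    F = ensemble.forces
    n, P = X.shape
    codes = np.empty_like(X, dtype=int)
    n_levels = []
    for jp in range(P):
        uniq, inv = np.unique(X[:, jp], return_inverse=True)
        codes[:, jp] = inv
        n_levels.append(uniq.size)
    balanced = (ensemble.samples.kind == "factorial"
                and not ensemble.excluded
                and n == int(np.prod(n_levels)))

    Fc = F - F.mean(axis=0)
    V = (Fc ** 2).mean(axis=0)  # population variance per time point
    safeV = np.where(V > 0, V, 1.0)

    Si = np.zeros((P, len(ensemble.times)))
    STi = np.zeros_like(Si)
    for jp in range(P):
        L = n_levels[jp]
        # first order: equal-weight variance of level means
        means = np.stack([F[codes[:, jp] == l].mean(axis=0) for l in range(L)])
        grand = means.mean(axis=0)
        Si[jp] = ((means - grand) ** 2).mean(axis=0) / safeV
        # total: variance explained by everything not involving jp
        other = np.delete(codes, jp, axis=1)
        # group key: ravel multi-index over the remaining parameters
        dims = tuple(np.delete(n_levels, jp))
        keys = np.ravel_multi_index(tuple(other.T), dims)
        df = pd.DataFrame(F)
        gmeans = df.groupby(keys).mean().to_numpy()
        ggrand = gmeans.mean(axis=0)
        V_not = ((gmeans - ggrand) ** 2).mean(axis=0)
        STi[jp] = 1.0 - V_not / safeV
    Si[:, V == 0] = 0.0
    STi[:, V == 0] = 0.0
    labels = [f"{seg} t={t:.6g}" for seg, t in
              zip(ensemble.segments, ensemble.times)]
    return SensitivityResult(Si, STi, ensemble.samples.names, labels,
                             unbalanced=not balanced)
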