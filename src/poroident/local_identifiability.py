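"""Local identifiability analysis: curvature of the SSE cost at the truth.

The cost j(theta; theta*) = sum_i (f(theta)_i - f(theta*)_i)^2 is
evaluated in [0, 1]-scaled parameter coordinates with exactly rounded
(compensated) summation.  Its Hessian at theta* is estimated by central
finite differences with a fixed step (default 0.01 scaled units,
selectable via a step-size sweep over 1e-8..1e-2), and the
eigen-spectrum is read against a numerical-noise floor: by the
Bauer-Fike theorem an error of magnitude eps in the Hessian perturbs
its eigenvalues by at most a comparable magnitude, so eigenvalues below
the floor are indistinguishable from zero curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .constitutive import BiphasicParameters, Environment
from .eigen import EigenReport
from .exceptions import PoroidentError
from .parameters import ParameterSpace
from .simulator import Grid1D, Protocol, solve_confined_compression


def sse_cost(residuals: np.ndarray) -> float:
    """Sum of squared residuals with compensated (Shewchuk) summation.

    math.fsum performs Shewchuk's exactly rounded summation, so the
    result is the correctly rounded double nearest the exact sum of the
    squared terms.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    return math.fsum(float(x) * float(x) for x in r)


class CostFunction:
    """SSE cost j(theta_scaled; theta*) around a reference output.

    Parameters
    ----------
    forward : callable
        Maps a scaled parameter vector in [0, 1]^P to an output vector
        f(theta).  May raise or return non-finite values on failure.
    reference : ndarray
        f(theta*), the noise-free synthetic observation.
    """

    def __init__(self, forward: Callable[[np.ndarray], np.ndarray],
                 reference: np.ndarray):
        self.forward = forward
        self.reference = np.asarray(reference, dtype=float)
        self.n_eval = 0
        self.failures: list[tuple[np.ndarray, str]] = []

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        self.n_eval += 1
        try:
            out = np.asarray(self.forward(x), dtype=float)
        except (PoroidentError, ValueError) as exc:
            self.failures.append((x.copy(), str(exc)))
            return np.inf
        if out.shape != self.reference.shape or not np.all(np.isfinite(out)):
            self.failures.append((x.copy(), "non-finite or misshapen output"))
            return np.inf
        return sse_cost(out - self.reference)


def make_biphasic_cost(theta_star_scaled: np.ndarray,
                       space: ParameterSpace | None = None,
                       protocol: Protocol | None = None,
                       grid: Grid1D | None = None,
                       env: Environment | None = None,
                       *, substeps: int = 1) -> CostFunction:
    """Cost function whose forward model is the bundled 1-D simulator."""
    space = space or ParameterSpace.default()
    protocol = protocol or Protocol()
    grid = grid or Grid1D()
    env = env or Environment()

    def forward(x_scaled: np.ndarray) -> np.ndarray:
        theta = space.unscale(np.clip(x_scaled, 0.0, 1.0))
        res = solve_confined_compression(
            BiphasicParameters.from_array(theta), protocol, grid, env,
            substeps=substeps, store_fields=False)
        return res.force

    reference = forward(np.asarray(theta_star_scaled, dtype=float))
    return CostFunction(forward, reference)


@dataclass
class HessianReport:
    """Finite-difference Hessian of the SSE cost in scaled coordinates."""

    H: np.ndarray  # (P, P), symmetrized
    step: float  # scaled units
    n_evaluations: int  # distinct forward evaluations used
    one_sided: tuple[int, ...] = ()  # coordinates that fell back to one-sided
    masked: np.ndarray | None = None  # boolean mask of non-finite entries

    def to_frame(self, names=None) -> pd.DataFrame:
        names = list(names) if names is not None else list(range(self.H.shape[0]))
        return pd.DataFrame(self.H, index=names, columns=names)


def fd_hessian(cost: Callable[[np.ndarray], float],
               x0: np.ndarray, h: float = 0.01) -> HessianReport:
    """Central-difference Hessian with a shared-point evaluation cache.

    Diagonal entries use {x0, x0 +/- h e_i}; off-diagonal entries use
    the four-point cross stencil {x0 +/- h e_i +/- h e_j}.  Distinct
    stencil points number 1 + 2P + 2P(P-1) (201 for P = 10); the cache
    guarantees each is evaluated once.  Coordinates within h of the
    [0, 1] boundary fall back to a one-sided (forward/backward) stencil
    and are flagged.
    """
    x0 = np.asarray(x0, dtype=float)
    P = x0.size
    cache: dict[bytes, float] = {}

    def ev(x: np.ndarray) -> float:
        key = np.round(x, 12).tobytes()
        if key not in cache:
            cache[key] = float(cost(x))
        return cache[key]

    # per-coordinate one-sided fallback direction: +1, -1, or 0 (centered)
    side = np.zeros(P, dtype=int)
    for i in range(P):
        if x0[i] - h < 0.0:
            side[i] = +1
        elif x0[i] + h > 1.0:
            side[i] = -1

    def shift(i: int, s: int) -> np.ndarray:
        x = x0.copy()
        x[i] += s * h
        return x

    H = np.full((P, P), np.nan)
    f0 = ev(x0)
    for i in range(P):
        if side[i] == 0:
            fp, fm = ev(shift(i, +1)), ev(shift(i, -1))
            H[i, i] = (fp - 2.0 * f0 + fm) / h ** 2
        else:
            s = side[i]
            f1, f2 = ev(shift(i, s)), ev(shift(i, 2 * s))
            H[i, i] = (f2 - 2.0 * f1 + f0) / h ** 2
    for i in range(P):
        for j in range(i + 1, P):
            si = (side[i],) if side[i] else (+1, -1)
            sj = (side[j],) if side[j] else (+1, -1)
            if len(si) == 2 and len(sj) == 2:
                xpp = x0.copy(); xpp[i] += h; xpp[j] += h
                xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
                xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
                xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
                H[i, j] = (ev(xpp) - ev(xpm) - ev(xmp) + ev(xmm)) / (4 * h ** 2)
            else:
                a, b = si[0], sj[0]
                xij = x0.copy(); xij[i] += a * h; xij[j] += b * h
                xi = x0.copy(); xi[i] += a * h
                xj = x0.copy(); xj[j] += b * h
                H[i, j] = a * b * (ev(xij) - ev(xi) - ev(xj) + f0) / h ** 2
            H[j, i] = H[i, j]
    masked = ~np.isfinite(H)
    H = 0.5 * (H + H.T)
    return HessianReport(H, h, len(cache),
                         tuple(int(i) for i in np.nonzero(side)[0]),
                         masked if masked.any() else None)


@dataclass
class StepSweepResult:
    """Hessian estimates across finite-difference step sizes."""

    steps: np.ndarray
    hessians: list[np.ndarray]
    deviation: np.ndarray  # neighbour-disagreement metric per step
    recommended: float  # argmin-deviation step size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "h": self.steps,
            "frobenius_norm": [np.linalg.norm(H) for H in self.hessians],
            "deviation": self.deviation,
        })


def step_size_sweep(cost: Callable[[np.ndarray], float], x0: np.ndarray,
                    steps: np.ndarray | None = None) -> StepSweepResult:
    """Sweep the FD step to expose condition- and truncation-error regimes.

    For each step the Hessian is re-estimated; the deviation metric for
    step k is the mean relative Frobenius difference to its neighbouring
    steps' estimates (small h: condition error grows as h^-2; large h:
    truncation error).  The recommended step minimizes the deviation.
    """
    steps = np.asarray(steps if steps is not None
                       else np.logspace(-8, -2, 7), dtype=float)
    if steps.size < 2:
        raise ValueError("need at least 2 step sizes")
    hessians = [fd_hessian(cost, x0, h).H for h in steps]
    dev = np.empty(steps.size)
    for k in range(steps.size):
        neigh = [j for j in (k - 1, k + 1) if 0 <= j < steps.size]
        ds = []
        for j in neigh:
            scale = max(np.linalg.norm(hessians[k]), np.linalg.norm(hessians[j]))
            ds.append(np.linalg.norm(hessians[k] - hessians[j])
                      / (scale if scale > 0 else 1.0))
        dev[k] = float(np.mean(ds))
    return StepSweepResult(steps, hessians, dev,
                           float(steps[int(np.argmin(dev))]))


def hessian_eigen_report(H: np.ndarray | HessianReport,
                         noise_floor: float = 1e-2,
                         parameter_names: tuple[str, ...] | None = None
                         ) -> EigenReport:
    """Symmetric eigendecomposition with a Bauer-Fike noise threshold.

    Eigenvalues may be negative (saddle artefacts of numerical error in
    the cost); only eigenvalues above the noise floor count as
    constrained directions.  The input must be symmetric.
    """
    if isinstance(H, HessianReport):
        H = H.H
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, rtol=0, atol=1e-10 * max(1.0, np.abs(H).max())):
        raise ValueError("Hessian must be symmetric (symmetrize first)")
    Hs = 0.5 * (H + H.T)
    lam, vec = np.linalg.eigh(Hs)
    names = (parameter_names if parameter_names is not None
             else tuple(f"p{i}" for i in range(H.shape[0])))
    return EigenReport(lam, vec, names, noise_floor, "absolute")
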