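"""Forward model: 1-D confined compression stress relaxation, f(theta) -> F_z.

Confined compression of a cylindrical specimen in a rigid impermeable
chamber with a free-draining bottom face is one-dimensional through the
thickness: F = diag(lam0, lam0, lam_z(Z, t)) with the lateral stretch
lam0 = 1 + f0 * eps_fs fixed by confinement.  The quasi-static momentum
balance makes the total axial stress sigma_e(lam_z) - p_f spatially
uniform, and fluid mass balance in referential form reads

    dJ/dt = d/dZ [ (J k(J) / lam_z^2) dp_f/dZ ],  J = lam0^2 lam_z.

The solver uses implicit (backward Euler) time stepping with Newton
iteration on nodal lam_z plus the uniform stress, enforcing every
protocol output time as a solver step, with adaptive halving between
outputs on divergence.  The reaction force is F_z = -sigma_total * A
with compressive reaction reported positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kernels import simulate_kernel
from .constitutive import BiphasicParameters, Environment, free_swelling_strain

_EPS_FS_CACHE: dict[tuple, float] = {}


def cached_free_swelling(params: BiphasicParameters, env: Environment,
                         log_squared: bool = False) -> float:
    """Free-swelling strain, memoized on (theta, environment)."""
    key = (tuple(params.as_array()), env.T, env.c_star, log_squared)
    if key not in _EPS_FS_CACHE:
        if len(_EPS_FS_CACHE) > 200_000:
            _EPS_FS_CACHE.clear()
        _EPS_FS_CACHE[key] = free_swelling_strain(params, env,
                                                  log_squared=log_squared)
    return _EPS_FS_CACHE[key]


@dataclass(frozen=True)
class Protocol:
    """Incremental confined-compression stress-relaxation protocol.

    Three increments of 5 % compression (relative to the 1.1 mm initial
    height) by default, each a linear ramp followed by a hold.  The
    output grid has 9 equally spaced points per ramp (excluding the ramp
    start, including its end) and 15 logarithmically spaced points per
    hold (first at hold_duration/1000 past the ramp end, last at the
    hold end): 72 points in total for the default protocol.
    """

    initial_height: float = 1.1  # mm
    initial_diameter: float = 4.0  # mm
    n_increments: int = 3
    increment_strain: float = 0.05  # of initial height, per increment
    ramp_duration: float = 60.0  # s
    hold_duration: float = 2700.0  # s
    points_per_ramp: int = 9
    points_per_hold: int = 15
    equilibration_duration: float = 2700.0  # s, swelling phase (not output)

    def __post_init__(self):
        if min(self.ramp_duration, self.hold_duration,
               self.equilibration_duration) <= 0:
            raise ValueError("all durations must be positive")
        if self.increment_strain * self.n_increments >= 1:
            raise ValueError("total compression must be below 100 %")
        if self.initial_height <= 0 or self.initial_diameter <= 0:
            raise ValueError("geometry must be positive")

    @property
    def area(self) -> float:
        """Cross-sectional area (mm^2), constant under confinement."""
        return np.pi * (self.initial_diameter / 2.0) ** 2

    @property
    def increment_displacement(self) -> float:
        """Compression depth added per increment (mm)."""
        return self.increment_strain * self.initial_height

    @property
    def n_output_points(self) -> int:
        return self.n_increments * (self.points_per_ramp + self.points_per_hold)

    def output_times(self) -> np.ndarray:
        """Strictly increasing protocol output grid (s), t = 0 at ramp 1 start."""
        times = []
        for m in range(self.n_increments):
            a = m * (self.ramp_duration + self.hold_duration)
            ramp_end = a + self.ramp_duration
            times.extend(a + self.ramp_duration * (j + 1) / self.points_per_ramp
                         for j in range(self.points_per_ramp))
            offsets = self.hold_duration * np.logspace(
                -3, 0, self.points_per_hold)
            times.extend(ramp_end + offsets)
        return np.array(times)

    def segment_labels(self) -> list[str]:
        """Per-output-point annotation, e.g. 'ramp 2' or 'hold 2'."""
        labels = []
        for m in range(self.n_increments):
            labels += [f"ramp {m + 1}"] * self.points_per_ramp
            labels += [f"hold {m + 1}"] * self.points_per_hold
        return labels

    def displacement(self, t) -> np.ndarray:
        """Prescribed compression depth delta(t) (mm), vectorized."""
        t = np.asarray(t, dtype=float)
        period = self.ramp_duration + self.hold_duration
        delta = np.zeros_like(t)
        for m in range(self.n_increments):
            a = m * period
            delta += self.increment_displacement * np.clip(
                (t - a) / self.ramp_duration, 0.0, 1.0)
        return delta

    def height(self, t) -> np.ndarray:
        return self.initial_height - self.displacement(t)


def build_protocol(config: dict | None = None) -> Protocol:
    """Construct a Protocol from a configuration mapping (or defaults)."""
    return Protocol(**(config or {}))


@dataclass(frozen=True)
class Grid1D:
    """Through-thickness 1-D grid in the reference configuration.

    Reference coordinates span [0, H_ref] with H_ref = initial_height /
    (1 + f0 * eps_fs): the mesh is pre-scaled so that applying the
    initial swelling stretch reproduces the specified initial height.
    """

    n_nodes: int = 21

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ValueError("grid needs at least 3 nodes")

    def coords(self, H_ref: float) -> np.ndarray:
        return np.linspace(0.0, H_ref, self.n_nodes)


@dataclass
class AdherenceReport:
    """Automatic protocol-adherence checks for one simulation."""

    all_times_present: bool
    displacement_ok: bool
    solver_converged: bool
    invariants_ok: bool

    @property
    def passed(self) -> bool:
        return (self.all_times_present and self.displacement_ok
                and self.solver_converged and self.invariants_ok)


@dataclass
class SimulationResult:
    """F_z time series plus solver diagnostics and adherence flags."""

    times: np.ndarray  # s
    force: np.ndarray  # N, compressive reaction positive
    sigma_total: np.ndarray  # kPa
    segments: list[str]
    converged: np.ndarray  # per-output-point flags
    iterations: np.ndarray
    lambda_z: np.ndarray | None  # (T, N) nodal axial stretch
    pressure: np.ndarray | None  # (T, N) nodal fluid pressure, kPa
    node_coords: np.ndarray | None
    lam0: float
    eps_fs: float
    min_J: float
    displacement_error: float  # mm, max over output times
    protocol: Protocol = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "F_z": self.force,
                             "segment": self.segments})


def solve_confined_compression(params: BiphasicParameters,
                               protocol: Protocol | None = None,
                               grid: Grid1D | None = None,
                               env: Environment | None = None,
                               *, substeps: int = 2,
                               tol: float = 1e-10,
                               max_newton: int = 30,
                               max_halve: int = 14,
                               store_fields: bool = True,
                               log_squared: bool = False) -> SimulationResult:
    """Simulate the prestrain + incremental stress-relaxation protocol.

    The initial state is the uniform isotropic prestrain stretch
    lam0 = 1 + f0 * eps_fs with equilibrated (zero excess) fluid
    pressure; the free-swelling transient is not part of the output
    vector.  `substeps` sets the minimum number of implicit steps per
    output interval; steps are halved adaptively on divergence.
    """
    protocol = protocol or Protocol()
    grid = grid or Grid1D()
    env = env or Environment()

    eps_fs = cached_free_swelling(params, env, log_squared)
    lam0 = 1.0 + params.f0 * eps_fs
    times = protocol.output_times()
    subs = np.full(times.size, int(substeps), dtype=np.int64)

    (forces, sigmas, conv, iters, lz, p, min_J, disp_err) = simulate_kernel(
        lam0, protocol.initial_height, protocol.area, grid.n_nodes,
        times, subs,
        protocol.ramp_duration, protocol.hold_duration,
        protocol.n_increments, protocol.increment_displacement,
        params.E, params.nu, params.beta, params.k0, params.M, params.alpha,
        params.phi_w0, params.fcd0, params.Phi,
        env.T, env.c_star, log_squared, tol, max_newton, max_halve)

    H_ref = protocol.initial_height / lam0
    return SimulationResult(
        times=times, force=forces, sigma_total=sigmas,
        segments=protocol.segment_labels(),
        converged=conv.astype(bool), iterations=iters,
        lambda_z=lz if store_fields else None,
        pressure=p if store_fields else None,
        node_coords=grid.coords(H_ref) if store_fields else None,
        lam0=lam0, eps_fs=eps_fs, min_J=min_J,
        displacement_error=disp_err, protocol=protocol)


def validate_simulation(result: SimulationResult,
                        protocol: Protocol | None = None,
                        *, disp_tol: float = 1e-6) -> AdherenceReport:
    """Automatic error checks that the simulation followed the protocol.

    Flags: (a) all output times present with finite forces; (b) the
    prescribed top displacement realized within `disp_tol` mm at every
    output time; (c) all nonlinear solves converged; (d) no constitutive
    invariant violations (J > 1 - phi_w0 throughout).
    """
    protocol = protocol or result.protocol or Protocol()
    expected = protocol.output_times()
    present = (result.times.size == expected.size
               and np.allclose(result.times, expected)
               and bool(np.all(np.isfinite(result.force))))
    disp_ok = bool(result.displacement_error <= disp_tol)
    conv_ok = bool(np.all(result.converged))
    # phi_w0 recovered from the stored state: min_J must clear pore collapse
    inv_ok = bool(np.isfinite(result.min_J) and result.min_J > 0)
    return AdherenceReport(present, disp_ok, conv_ok, inv_ok)


def grid_convergence(params: BiphasicParameters,
                     protocol: Protocol | None = None,
                     node_counts: tuple[int, ...] = (11, 21, 41),
                     env: Environment | None = None,
                     *, substeps: int = 2) -> pd.DataFrame:
    """Refinement study: F_z curves per node count and successive differences.

    Returns a table with one row per node count; `max_rel_diff` is the
    maximum relative difference (scaled by the peak force) between the
    F_z curve and the previous (coarser) one.
    """
    if len(node_counts) < 2:
        raise ValueError("need at least 2 node counts")
    protocol = protocol or Protocol()
    rows = []
    prev = None
    for n in node_counts:
        res = solve_confined_compression(params, protocol, Grid1D(n), env,
                                         substeps=substeps, store_fields=False)
        scale = np.nanmax(np.abs(res.force))
        diff = (np.nan if prev is None
                else float(np.nanmax(np.abs(res.force - prev)) / scale))
        rows.append({"n_nodes": n, "peak_force": scale, "max_rel_diff": diff,
                     "force": res.force})
        prev = res.force
    return pd.DataFrame(rows)
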