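"""Parameter space for the 10-parameter nonlinear biphasic model.

The space Theta is an ordered list of named ranges in natural units.  The
canonical order and default ranges correspond to the plausible in-vivo
ranges for cartilaginous tissue (endplate-like) used throughout the
identifiability analyses:

====== ========== ========== =======================
name   min        max        units
====== ========== ========== =======================
E      130        470        kPa
nu     0          0.3        --
beta   0.04       0.5        --
k0     1e-4       20e-4      mm^4/(N s)
M      1.7        5.8        --
alpha  1          2          --
phi_w0 0.6        0.87       --
fcd0   120        315        mM
Phi    0.9        1.0        --
f0     0.0        0.5        --
====== ========== ========== =======================

All analyses work either in natural units or in the affinely scaled unit
cube, where 0 maps to a range's minimum and 1 to its maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import RangeViolationError

#: Canonical parameter order used by every module.
CANONICAL_ORDER = ("E", "nu", "beta", "k0", "M", "alpha", "phi_w0", "fcd0", "Phi", "f0")

_DEFAULT_RANGES = {
    "E": (130.0, 470.0, "kPa"),
    "nu": (0.0, 0.3, "-"),
    "beta": (0.04, 0.5, "-"),
    "k0": (1e-4, 20e-4, "mm^4/(N s)"),
    "M": (1.7, 5.8, "-"),
    "alpha": (1.0, 2.0, "-"),
    "phi_w0": (0.6, 0.87, "-"),
    "fcd0": (120.0, 315.0, "mM"),
    "Phi": (0.9, 1.0, "-"),
    "f0": (0.0, 0.5, "-"),
}


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered, named parameter ranges with [0, 1] scaling maps."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    units: tuple[str, ...]

    def __post_init__(self):
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        if len(set(self.names)) != len(self.names):
            raise ValueError("parameter names must be unique")
        if not (len(self.names) == mins.size == maxs.size == len(self.units)):
            raise ValueError("names, mins, maxs, units must have equal length")
        if not np.all(mins < maxs):
            bad = [n for n, lo, hi in zip(self.names, mins, maxs) if not lo < hi]
            raise ValueError(f"min must be < max for every parameter; violated by {bad}")

    # -- constructors ---------------------------------------------------
    @classmethod
    def default(cls) -> "ParameterSpace":
        """The canonical 10-parameter biphasic space (table above)."""
        names = CANONICAL_ORDER
        mins = np.array([_DEFAULT_RANGES[n][0] for n in names])
        maxs = np.array([_DEFAULT_RANGES[n][1] for n in names])
        units = tuple(_DEFAULT_RANGES[n][2] for n in names)
        return cls(names, mins, maxs, units)

    @classmethod
    def from_dict(cls, spec: list[dict]) -> "ParameterSpace":
        """Build from a configuration block: list of {name, min, max, units}."""
        names = tuple(d["name"] for d in spec)
        mins = np.array([float(d["min"]) for d in spec])
        maxs = np.array([float(d["max"]) for d in spec])
        units = tuple(str(d.get("units", "-")) for d in spec)
        return cls(names, mins, maxs, units)

    @classmethod
    def subset(cls, base: "ParameterSpace", names: list[str]) -> "ParameterSpace":
        idx = [base.names.index(n) for n in names]
        return cls(
            tuple(names),
            base.mins[idx],
            base.maxs[idx],
            tuple(base.units[i] for i in idx),
        )

    # -- basic info -----------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def spans(self) -> np.ndarray:
        return self.maxs - self.mins

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.mins + self.maxs)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.mins, "max": self.maxs, "units": list(self.units)},
            index=list(self.names),
        )

    # -- scaling --------------------------------------------------------
    def validate(self, theta: np.ndarray) -> None:
        """Raise :class:`RangeViolationError` naming the first offender."""
        theta = np.asarray(theta, dtype=float)
        for i, name in enumerate(self.names):
            v = theta[..., i]
            if np.any(v < self.mins[i]) or np.any(v > self.maxs[i]):
                bad = float(np.atleast_1d(v)[0])
                raise RangeViolationError(name, bad, self.mins[i], self.maxs[i])

    def scale(self, theta: np.ndarray, check: bool = True) -> np.ndarray:
        """Map natural units onto [0, 1]^P: 0 = min, 1 = max."""
        theta = np.asarray(theta, dtype=float)
        if check:
            self.validate(theta)
        return (theta - self.mins) / self.spans

    def unscale(self, x: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`scale` (exact affine inverse)."""
        x = np.asarray(x, dtype=float)
        return self.mins + x * self.spans


def scale(theta: np.ndarray, space: ParameterSpace) -> np.ndarray:
    """Functional alias for :meth:`ParameterSpace.scale`."""
    return space.scale(theta)


def unscale(x: np.ndarray, space: ParameterSpace) -> np.ndarray:
    return space.unscale(x)


@dataclass
class SampleSet:
    """A design matrix over a parameter space, in natural units."""

    data: np.ndarray  # (n_samples, P)
    names: tuple[str, ...]
    kind: str  # "factorial" | "uniform"
    levels: int | None = None
    seed: int | None = None
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.ids:
            width = max(1, len(str(self.n_samples - 1)))
            self.ids = [f"s{i:0{width}d}" for i in range(self.n_samples)]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_params(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=list(self.names), index=self.ids)

    # -- persistence: CSV + JSON sidecar --------------------------------
    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index_label="id")
        meta = {"kind": self.kind, "levels": self.levels, "seed": self.seed}
        csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "SampleSet":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path, index_col="id")
        sidecar = csv_path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            df.to_numpy(),
            tuple(df.columns),
            meta.get("kind", "unknown"),
            meta.get("levels"),
            meta.get("seed"),
            [str(i) for i in df.index],
        )


def full_factorial(space: ParameterSpace, levels: int = 3) -> SampleSet:
    """Full factorial design with `levels` equally spaced values per parameter.

    Levels include both range endpoints and are equally spaced in natural
    units.  The design has exactly ``levels ** P`` rows, ordered
    lexicographically over the canonical parameter order with the last
    parameter varying fastest.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    axes = [np.linspace(lo, hi, levels) for lo, hi in zip(space.mins, space.maxs)]
    grids = np.meshgrid(*axes, indexing="ij")
    data = np.stack([g.ravel() for g in grids], axis=1)
    return SampleSet(data, space.names, "factorial", levels=levels)


def sample_uniform(space: ParameterSpace, n: int, seed: int) -> SampleSet:
    """`n` independent uniform draws, each coordinate uniform on its range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, space.n_params))
    return SampleSet(space.unscale(u), space.names, "uniform", seed=seed)
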