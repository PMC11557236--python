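"""Material laws for the nonlinear biphasic mixture.

The solid is a Holmes-Mow hyperelastic matrix carrying a Donnan osmotic
swelling stress; the fluid transport is governed by the Holmes-Mow
strain-dependent permeability.  Together with the prestrain fraction f0
this gives the 10-parameter model

    theta = (E, nu, beta, k0, M, alpha, phi_w0, fcd0, Phi, f0).

Holmes-Mow strain energy (kPa), with Q = beta * [ ((3 nu - 1)/(nu - 1)) (I1 - 3)
+ (nu/(1 - nu)) (I2 - 3) - ln(J^2) ]:

    Psi = E (1 - nu) / (4 beta (1 + nu)(1 - 2 nu)) * (exp(Q) - 1)

The last term of Q is implemented as ln(J^2) = 2 ln J, the canonical
Holmes-Mow form; a squared-logarithm variant -(ln J)^2 is available via
``log_squared=True`` for sensitivity checking (it flips the sign of the
volumetric energy in compression and is not the default).

Donnan equilibrium pressure (kPa), with concentrations in mM = mol/m^3:

    p = Phi * R * T * (sqrt(FCD^2 + c*^2) - c*),
    FCD(J) = phi_w0 * FCD0 / (J - 1 + phi_w0)

Holmes-Mow permeability (mm^4 / (N s)):

    k(J) = k0 * ((J - 1 + phi_w0)/phi_w0)^alpha * exp(M (J^2 - 1)/2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from ._kernels import R_GAS
from .exceptions import ConvergenceError, InvalidDeformationError, PoreCollapseError
from .parameters import CANONICAL_ORDER, ParameterSpace


@dataclass(frozen=True)
class BiphasicParameters:
    """One point theta in the 10-dimensional parameter space, natural units."""

    E: float  # elastic modulus, kPa
    nu: float  # Poisson ratio
    beta: float  # elastic nonlinearity
    k0: float  # strain-free permeability, mm^4/(N s)
    M: float  # exponential permeability coefficient
    alpha: float  # power-law permeability exponent
    phi_w0: float  # strain-free porosity (fluid volume fraction)
    fcd0: float  # strain-free fixed charge density, mM
    Phi: float  # osmotic coefficient
    f0: float  # initial swelling fraction

    def __post_init__(self):
        checks = [
            (self.E > 0, "E > 0"),
            (0 <= self.nu < 0.5, "0 <= nu < 0.5"),
            (self.beta > 0, "beta > 0"),
            (self.k0 > 0, "k0 > 0"),
            (self.M >= 0, "M >= 0"),
            (self.alpha >= 0, "alpha >= 0"),
            (0 < self.phi_w0 < 1, "0 < phi_w0 < 1"),
            (self.fcd0 >= 0, "fcd0 >= 0"),
            (0 < self.Phi <= 1, "0 < Phi <= 1"),
            (0 <= self.f0 <= 1, "0 <= f0 <= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid biphasic parameters: requires {msg}")

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "BiphasicParameters":
        """Build from a vector in the canonical parameter order."""
        theta = np.asarray(theta, dtype=float)
        return cls(**dict(zip(CANONICAL_ORDER, theta)))

    @classmethod
    def midpoint(cls, space: ParameterSpace | None = None) -> "BiphasicParameters":
        space = space or ParameterSpace.default()
        return cls.from_array(space.midpoint)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CANONICAL_ORDER])

    def replace(self, **kw) -> "BiphasicParameters":
        d = dict(zip(CANONICAL_ORDER, self.as_array()))
        d.update(kw)
        return BiphasicParameters(**d)


@dataclass(frozen=True)
class Environment:
    """Test bath conditions: temperature and external osmolarity."""

    T: float = 294.0  # K (room temperature)
    c_star: float = 300.0  # mOsm == mol/m^3 (standard saline)
    R: float = R_GAS  # J/(mol K), fixed physical constant

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.c_star < 0:
            raise ValueError("bath osmolarity must be non-negative")


@dataclass(frozen=True)
class DeformationState:
    """Diagonal deformation gradient F = diag(lam_r, lam_r, lam_z)."""

    lam_r: float
    lam_z: float

    def __post_init__(self):
        if self.lam_r <= 0 or self.lam_z <= 0:
            raise InvalidDeformationError("principal stretches must be positive")

    @property
    def I1(self) -> float:
        return 2.0 * self.lam_r ** 2 + self.lam_z ** 2

    @property
    def I2(self) -> float:
        return self.lam_r ** 4 + 2.0 * self.lam_r ** 2 * self.lam_z ** 2

    @property
    def J(self) -> float:
        return self.lam_r ** 2 * self.lam_z

    @property
    def F(self) -> np.ndarray:
        return np.diag([self.lam_r, self.lam_r, self.lam_z])


def _check_J(J: float, phi_w0: float) -> None:
    if J <= 0:
        raise InvalidDeformationError(f"volume ratio J = {J} must be positive")
    # same association as the constitutive kernels (J - 1 + phi_w0)
    if J - 1.0 + phi_w0 <= 0:
        raise PoreCollapseError(
            f"J = {J} <= 1 - phi_w0 = {1 - phi_w0}: pore space closed"
        )


def hm_strain_energy(state: DeformationState, params: BiphasicParameters,
                     *, log_squared: bool = False) -> float:
    """Holmes-Mow strain energy density (kPa); zero in the reference state."""
    if state.J <= 0:
        raise InvalidDeformationError("J must be positive")
    return float(_kernels.psi_hm(state.lam_r, state.lam_z,
                                 params.E, params.nu, params.beta, log_squared))


def hm_cauchy_stress(state: DeformationState, params: BiphasicParameters,
                     *, log_squared: bool = False) -> np.ndarray:
    """Diagonal Cauchy stress (s_rr, s_rr, s_zz) of the solid, kPa, tension +."""
    if state.J <= 0:
        raise InvalidDeformationError("J must be positive")
    s_rr, s_zz = _kernels.sigma_hm_diag(state.lam_r, state.lam_z,
                                        params.E, params.nu, params.beta,
                                        log_squared)
    return np.array([s_rr, s_rr, s_zz])


def donnan_fcd(J: float, params: BiphasicParameters) -> float:
    """Fixed charge density (mM) at volume ratio J."""
    _check_J(J, params.phi_w0)
    return float(_kernels.fcd_of_J(J, params.phi_w0, params.fcd0))


def donnan_pressure(J: float, params: BiphasicParameters,
                    env: Environment | None = None) -> float:
    """Donnan equilibrium swelling pressure (kPa) at volume ratio J."""
    env = env or Environment()
    _check_J(J, params.phi_w0)
    return float(_kernels.donnan_pressure(J, params.phi_w0, params.fcd0,
                                          params.Phi, env.T, env.c_star))


def permeability(J: float, params: BiphasicParameters) -> float:
    """Strain-dependent permeability (mm^4/(N s)) at volume ratio J."""
    _check_J(J, params.phi_w0)
    return float(_kernels.permeability(J, params.k0, params.M, params.alpha,
                                       params.phi_w0))


def effective_axial_stress(lam_z: float, lam_r: float,
                           params: BiphasicParameters,
                           env: Environment | None = None,
                           *, log_squared: bool = False) -> float:
    """Total solid axial Cauchy stress: elastic sigma_zz minus Donnan p (kPa).

    The osmotic pressure acts as an isotropic solid-bound stress
    contribution; the excess fluid pressure is *not* included here.
    """
    env = env or Environment()
    _check_J(lam_r ** 2 * lam_z, params.phi_w0)
    return float(_kernels.sigma_e_zz(lam_r, lam_z, params.E, params.nu,
                                     params.beta, params.phi_w0, params.fcd0,
                                     params.Phi, env.T, env.c_star, log_squared))


def free_swelling_strain(params: BiphasicParameters,
                         env: Environment | None = None,
                         *, log_squared: bool = False,
                         lam_max: float = 8.0) -> float:
    """Free-swelling engineering strain eps_fs at equilibrium.

    Solves sigma_e(lam, lam) = 0 for the isotropic stretch lam (total
    stress zero against a zero-pressure bath) by bracketed root finding
    on lam in [1, lam_max], then returns eps_fs = lam - 1.
    """
    env = env or Environment()
    if params.fcd0 == 0.0:
        return 0.0

    def resid(lam: float) -> float:
        return _kernels.sigma_e_iso(lam, params.E, params.nu, params.beta,
                                    params.phi_w0, params.fcd0, params.Phi,
                                    env.T, env.c_star, log_squared)

    lo, hi = 1.0, 2.0
    flo = resid(lo)
    if flo == 0.0:
        return 0.0
    while resid(hi) < 0.0:
        hi *= 2.0
        if hi > lam_max:
            raise ConvergenceError(
                f"free swelling: no sign change on [1, {lam_max}] "
                f"(residual at 1: {flo:.3g} kPa)"
            )
    lam = brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16)
    if abs(resid(lam)) > 1e-6:
        raise ConvergenceError(
            f"free swelling root residual {resid(lam):.3g} kPa exceeds 1e-6"
        )
    return float(lam - 1.0)
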