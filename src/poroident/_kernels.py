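"""Scalar numerical kernels (numba-compiled).

Single source of truth for the constitutive laws and the 1-D confined
compression stepper.  The public modules (`constitutive`, `simulator`)
wrap these kernels with validation, unit handling and result containers.

Unit system: mechanics in kPa-mm-s (1 kPa * mm^2 = 1e-3 N); concentrations
in mM == mol/m^3; R*T*c evaluated in Pa and converted to kPa.  Stresses
are held in kPa while the permeability carries mm^4/(N s), so wherever
k multiplies a kPa stress gradient a factor KPA = 1e-3 N/(mm^2 kPa)
restores consistent units.
"""

import numpy as np
from numba import njit

#: Universal gas constant, J/(mol K).
R_GAS = 8.314462618

#: kPa expressed in N/mm^2 (converts kPa stress gradients for k in mm^4/(N s)).
KPA = 1e-3


# ----------------------------------------------------------------------
# Constitutive laws
# ----------------------------------------------------------------------
@njit(cache=True)
def psi_hm(lr, lz, E, nu, beta, log_squared):
    """Holmes-Mow strain energy density (kPa) for F = diag(lr, lr, lz)."""
    I1 = 2.0 * lr * lr + lz * lz
    I2 = lr ** 4 + 2.0 * lr * lr * lz * lz
    J = lr * lr * lz
    A = (3.0 * nu - 1.0) / (nu - 1.0)
    B = nu / (1.0 - nu)
    c0 = E * (1.0 - nu) / (4.0 * beta * (1.0 + nu) * (1.0 - 2.0 * nu))
    lnJ = np.log(J)
    w = lnJ * lnJ if log_squared else 2.0 * lnJ
    Q = beta * (A * (I1 - 3.0) + B * (I2 - 3.0) - w)
    return c0 * np.expm1(Q)  # expm1 keeps precision in the small-Q limit


@njit(cache=True)
def sigma_hm_diag(lr, lz, E, nu, beta, log_squared):
    """Principal Cauchy stresses (sigma_rr, sigma_zz) of the Holmes-Mow solid.

    sigma_ii = (2/J) [ (Psi_1 + I1 Psi_2) li^2 - Psi_2 li^4 ] + Psi_J,
    evaluated in closed form for diagonal F (tension positive, kPa).
    """
    I1 = 2.0 * lr * lr + lz * lz
    I2 = lr ** 4 + 2.0 * lr * lr * lz * lz
    J = lr * lr * lz
    A = (3.0 * nu - 1.0) / (nu - 1.0)
    B = nu / (1.0 - nu)
    c0 = E * (1.0 - nu) / (4.0 * beta * (1.0 + nu) * (1.0 - 2.0 * nu))
    lnJ = np.log(J)
    w = lnJ * lnJ if log_squared else 2.0 * lnJ
    Q = beta * (A * (I1 - 3.0) + B * (I2 - 3.0) - w)
    eQ = np.exp(Q)
    # dPsi/dJ through the -w(J) term
    dw_dJ = 2.0 * lnJ / J if log_squared else 2.0 / J
    psi_J = -c0 * eQ * beta * dw_dJ
    pref = 2.0 * c0 * beta * eQ / J
    s_rr = pref * ((A + I1 * B) * lr * lr - B * lr ** 4) + psi_J
    s_zz = pref * ((A + I1 * B) * lz * lz - B * lz ** 4) + psi_J
    return s_rr, s_zz


@njit(cache=True)
def fcd_of_J(J, phi_w0, fcd0):
    """Strain-dependent fixed charge density (mM)."""
    return phi_w0 * fcd0 / (J - 1.0 + phi_w0)


@njit(cache=True)
def donnan_pressure(J, phi_w0, fcd0, Phi, T, c_star):
    """Donnan equilibrium osmotic pressure (kPa), zero when fcd0 = 0."""
    c = fcd_of_J(J, phi_w0, fcd0)
    return Phi * R_GAS * T * (np.sqrt(c * c + c_star * c_star) - c_star) * 1e-3


@njit(cache=True)
def permeability(J, k0, M, alpha, phi_w0):
    """Holmes-Mow strain-dependent permeability (mm^4 / (N s))."""
    return k0 * ((J - 1.0 + phi_w0) / phi_w0) ** alpha * np.exp(M * (J * J - 1.0) / 2.0)


@njit(cache=True)
def sigma_e_zz(lr, lz, E, nu, beta, phi_w0, fcd0, Phi, T, c_star, log_squared):
    """Total solid axial stress: Holmes-Mow sigma_zz minus Donnan pressure."""
    J = lr * lr * lz
    _, s_zz = sigma_hm_diag(lr, lz, E, nu, beta, log_squared)
    return s_zz - donnan_pressure(J, phi_w0, fcd0, Phi, T, c_star)


@njit(cache=True)
def dsigma_e_dlz(lr, lz, E, nu, beta, phi_w0, fcd0, Phi, T, c_star, log_squared):
    """Analytic d(sigma_e_zz)/d(lz) at fixed lateral stretch (kPa per unit)."""
    I1 = 2.0 * lr * lr + lz * lz
    J = lr * lr * lz
    A = (3.0 * nu - 1.0) / (nu - 1.0)
    B = nu / (1.0 - nu)
    c0 = E * (1.0 - nu) / (4.0 * beta * (1.0 + nu) * (1.0 - 2.0 * nu))
    I2 = lr ** 4 + 2.0 * lr * lr * lz * lz
    lnJ = np.log(J)
    w = lnJ * lnJ if log_squared else 2.0 * lnJ
    Q = beta * (A * (I1 - 3.0) + B * (I2 - 3.0) - w)
    eQ = np.exp(Q)
    g = (A + I1 * B) * lz * lz - B * lz ** 4
    w2 = lnJ if log_squared else 1.0
    # sigma_solid = 2 c0 beta eQ (g - w2) / J
    dJ_over_J = 1.0 / lz  # (dJ/dlz)/J with lr fixed
    if log_squared:
        dQ = beta * (2.0 * A * lz + 4.0 * B * lr * lr * lz - 2.0 * lnJ / lz)
        dw2 = dJ_over_J
    else:
        dQ = beta * (2.0 * A * lz + 4.0 * B * lr * lr * lz - 2.0 / lz)
        dw2 = 0.0
    dg = 2.0 * lz * (A + I1 * B) - 2.0 * B * lz ** 3
    pref = 2.0 * c0 * beta * eQ / J
    ds_solid = pref * (dQ * (g - w2) + dg - dw2 - (g - w2) * dJ_over_J)
    # Donnan term: d p / d lz = (dp/dJ) * lr^2
    c = fcd_of_J(J, phi_w0, fcd0)
    dc_dJ = -c / (J - 1.0 + phi_w0)
    if c > 0.0:
        dp_dJ = Phi * R_GAS * T * (c / np.sqrt(c * c + c_star * c_star)) * dc_dJ * 1e-3
    else:
        dp_dJ = 0.0
    return ds_solid - dp_dJ * lr * lr


@njit(cache=True)
def sigma_e_iso(lam, E, nu, beta, phi_w0, fcd0, Phi, T, c_star, log_squared):
    """Total solid axial stress under isotropic stretch (free swelling)."""
    return sigma_e_zz(lam, lam, E, nu, beta, phi_w0, fcd0, Phi, T, c_star, log_squared)


# ----------------------------------------------------------------------
# Protocol helpers
# ----------------------------------------------------------------------
@njit(cache=True)
def height_at(t, H_init, n_inc, d_inc, ramp, hold):
    """Prescribed current specimen height (mm) at protocol time t (s)."""
    delta = 0.0
    for m in range(n_inc):
        a = m * (ramp + hold)
        if t <= a:
            break
        te = min(t, a + ramp)
        delta += d_inc * (te - a) / ramp
    return H_init - delta


# ----------------------------------------------------------------------
# Nonlinear 1-D biphasic stepper
# ----------------------------------------------------------------------
@njit(cache=True)
def _attempt_step(lz, lz_old, s_old, h_t, dt, dZ, H_ref, lam0,
                  E, nu, beta, k0, M, alpha, phi_w0, fcd0, Phi,
                  T, c_star, log_squared, tol, max_newton):
    """One backward-Euler step via Newton iteration.

    `lz` is modified in place (caller passes a scratch copy of `lz_old`).
    Returns (ok, iterations, sigma_total).
    """
    N = lz.shape[0]
    HA = E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))
    lam0sq = lam0 * lam0
    lzmin = (1.0 - phi_w0) / lam0sq * (1.0 + 1e-9)
    lzmax = 5.0
    s = s_old

    se = np.empty(N)
    dse = np.empty(N)
    kap = np.empty(N)
    R = np.empty(N + 1)
    sub = np.empty(N)
    dia = np.empty(N)
    sup = np.empty(N)
    u1 = np.empty(N)
    u2 = np.empty(N)
    cp = np.empty(N)
    d1 = np.empty(N)
    d2 = np.empty(N)

    for it in range(max_newton + 1):
        for i in range(N):
            se[i] = sigma_e_zz(lam0, lz[i], E, nu, beta, phi_w0, fcd0, Phi,
                               T, c_star, log_squared)
            dse[i] = dsigma_e_dlz(lam0, lz[i], E, nu, beta, phi_w0, fcd0, Phi,
                                  T, c_star, log_squared)
            J = lam0sq * lz[i]
            kap[i] = KPA * lam0sq * permeability(J, k0, M, alpha, phi_w0) / lz[i]

        # residuals
        R[0] = (se[0] - s) / HA
        integ = 0.5 * lz[0] + 0.5 * lz[N - 1]
        for i in range(1, N - 1):
            integ += lz[i]
        integ *= dZ
        R[N] = (integ - h_t) / H_ref
        for i in range(1, N):
            V = dZ if i < N - 1 else 0.5 * dZ
            fac = dt / (V * lam0sq * dZ)
            km = 0.5 * (kap[i - 1] + kap[i])
            Qm = km * (se[i] - se[i - 1])
            if i < N - 1:
                kp = 0.5 * (kap[i] + kap[i + 1])
                Qp = kp * (se[i + 1] - se[i])
            else:
                Qp = 0.0
            R[i] = (lz[i] - lz_old[i]) - fac * (Qp - Qm)

        res = 0.0
        for i in range(N + 1):
            a = abs(R[i])
            if a > res:
                res = a
        if res < tol:
            return True, it, s
        if it == max_newton:
            return False, it, s

        # tridiagonal Jacobian of rows 0..N-1 w.r.t. lz (kappa lagged)
        sub[0] = 0.0
        dia[0] = dse[0] / HA
        sup[0] = 0.0
        for i in range(1, N):
            V = dZ if i < N - 1 else 0.5 * dZ
            fac = dt / (V * lam0sq * dZ)
            km = 0.5 * (kap[i - 1] + kap[i])
            sub[i] = -fac * km * dse[i - 1]
            if i < N - 1:
                kp = 0.5 * (kap[i] + kap[i + 1])
                dia[i] = 1.0 + fac * (kp + km) * dse[i]
                sup[i] = -fac * kp * dse[i + 1]
            else:
                dia[i] = 1.0 + fac * km * dse[i]
                sup[i] = 0.0

        # two simultaneous Thomas solves: A u1 = -R[0:N], A u2 = e0 / HA
        cp[0] = sup[0] / dia[0]
        d1[0] = -R[0] / dia[0]
        d2[0] = (1.0 / HA) / dia[0]
        for i in range(1, N):
            m = dia[i] - sub[i] * cp[i - 1]
            if m == 0.0:
                return False, it, s
            cp[i] = sup[i] / m
            d1[i] = (-R[i] - sub[i] * d1[i - 1]) / m
            d2[i] = (0.0 - sub[i] * d2[i - 1]) / m
        u1[N - 1] = d1[N - 1]
        u2[N - 1] = d2[N - 1]
        for i in range(N - 2, -1, -1):
            u1[i] = d1[i] - cp[i] * u1[i + 1]
            u2[i] = d2[i] - cp[i] * u2[i + 1]

        # constraint row (trapezoid weights / H_ref), corner zero
        cu1 = 0.5 * u1[0] + 0.5 * u1[N - 1]
        cu2 = 0.5 * u2[0] + 0.5 * u2[N - 1]
        for i in range(1, N - 1):
            cu1 += u1[i]
            cu2 += u2[i]
        cu1 *= dZ / H_ref
        cu2 *= dZ / H_ref
        if cu2 == 0.0:
            return False, it, s
        ds = (-R[N] - cu1) / cu2
        # damped update keeping the pore space open
        step = 1.0
        for i in range(N):
            du = u1[i] + ds * u2[i]
            if du < 0.0:
                lim = 0.9 * (lz[i] - lzmin)
                if -du * step > lim:
                    step = lim / (-du)
            elif du > 0.0:
                lim = 0.9 * (lzmax - lz[i])
                if du * step > lim:
                    step = lim / du
        for i in range(N):
            lz[i] += step * (u1[i] + ds * u2[i])
        s += step * ds
    return False, max_newton, s


@njit(cache=True)
def simulate_kernel(lam0, H_init, area, n_nodes, times, subs,
                    ramp, hold, n_inc, d_inc,
                    E, nu, beta, k0, M, alpha, phi_w0, fcd0, Phi,
                    T_env, c_star, log_squared, tol, max_newton, max_halve):
    """Run the full confined-compression protocol for one parameter set.

    Returns (forces, sigma_total, converged, iterations, lz_fields,
    p_fields, min_J, max_disp_err).  Forces are in N with compressive
    reaction positive; fields are nodal values at each output time.
    """
    T = times.shape[0]
    N = n_nodes
    H_ref = H_init / lam0
    dZ = H_ref / (N - 1)
    lam0sq = lam0 * lam0

    forces = np.full(T, np.nan)
    sigmas = np.full(T, np.nan)
    conv = np.zeros(T, np.uint8)
    iters = np.zeros(T, np.int64)
    lz_out = np.full((T, N), np.nan)
    p_out = np.full((T, N), np.nan)

    lz = np.full(N, lam0)
    s = sigma_e_zz(lam0, lam0, E, nu, beta, phi_w0, fcd0, Phi,
                   T_env, c_star, log_squared)
    min_J = lam0sq * lam0
    max_disp_err = 0.0

    t_prev = 0.0
    failed = False
    for k in range(T):
        tk = times[k]
        dt0 = (tk - t_prev) / subs[k]
        t = t_prev
        dt = dt0
        nh = 0
        nit = 0
        while t < tk - 1e-12 * (1.0 + tk):
            dtt = min(dt, tk - t)
            h_t = height_at(t + dtt, H_init, n_inc, d_inc, ramp, hold)
            lz_try = lz.copy()
            ok, its, s_new = _attempt_step(
                lz_try, lz, s, h_t, dtt, dZ, H_ref, lam0,
                E, nu, beta, k0, M, alpha, phi_w0, fcd0, Phi,
                T_env, c_star, log_squared, tol, max_newton)
            nit += its
            if ok:
                lz = lz_try
                s = s_new
                t = t + dtt
                dt = min(dt * 2.0, dt0)
            else:
                nh += 1
                if nh > max_halve:
                    failed = True
                    break
                dt = dtt * 0.5
        iters[k] = nit
        if failed:
            break
        forces[k] = -s * area * 1e-3
        sigmas[k] = s
        conv[k] = 1
        integ = 0.5 * lz[0] + 0.5 * lz[N - 1]
        for i in range(1, N - 1):
            integ += lz[i]
        integ *= dZ
        h_t = height_at(tk, H_init, n_inc, d_inc, ramp, hold)
        err = abs(integ - h_t)
        if err > max_disp_err:
            max_disp_err = err
        for i in range(N):
            Ji = lam0sq * lz[i]
            if Ji < min_J:
                min_J = Ji
            lz_out[k, i] = lz[i]
            p_out[k, i] = sigma_e_zz(lam0, lz[i], E, nu, beta, phi_w0, fcd0,
                                     Phi, T_env, c_star, log_squared) - s
        t_prev = tk

    return forces, sigmas, conv, iters, lz_out, p_out, min_J, max_disp_err
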