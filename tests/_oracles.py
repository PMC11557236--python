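"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (series
solutions, naive algorithms, exact arithmetic) and never calls into the
code paths it is used to check.
"""

from fractions import Fraction

import numpy as np


def linear_confined_compression_force(times, *, HA_kPa, k0, area, height,
                                      increment_disp, ramp, hold, n_inc,
                                      n_terms=500):
    """Classical linear biphasic series solution for ramp-hold loading.

    Consolidation of a linear biphasic layer (aggregate modulus HA,
    constant permeability k0), drained at the bottom, impermeable moving
    platen on top.  For a single ramp at compression rate V0 starting at
    t = 0 the surface stress magnitude is

        G(t) = HA V0 [ t/h + (h/c)(1/3 - 2 sum_n exp(-n^2 pi^2 c t/h^2)
                                           / (n^2 pi^2)) ],

    with consolidation coefficient c = HA k0 (HA in N/mm^2).  The
    ramp-hold-ramp... protocol response follows by linear superposition
    of ramp starts and stops.  Returns force in N (compression
    positive).
    """
    c = (HA_kPa * 1e-3) * k0  # mm^2/s
    V0 = increment_disp / ramp
    h = height

    def G(t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        m = t > 0
        tau = c * t[m] / h ** 2
        n = np.arange(1, n_terms + 1)[:, None]
        S = (np.exp(-(n ** 2) * np.pi ** 2 * tau) / (n ** 2 * np.pi ** 2)).sum(axis=0)
        out[m] = HA_kPa * V0 * (t[m] / h + (h / c) * (1.0 / 3.0 - 2.0 * S))
        return out

    F = np.zeros_like(np.asarray(times, dtype=float))
    for m in range(n_inc):
        a = m * (ramp + hold)
        F += G(times - a) - G(times - a - ramp)
    return F * area * 1e-3  # kPa mm^2 -> N


def pearson_two_pass(x, y):
    """Textbook two-pass Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return 0.0 if den == 0 else num / den


def naive_upgma_heights(D):
    """Average-linkage agglomeration on a dense distance matrix.

    Returns the sorted list of merge heights.  Naive O(n^3) textbook
    implementation: repeatedly merge the closest pair of clusters, with
    the distance between clusters the arithmetic mean of the pairwise
    member distances.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []

    def cdist(a, b):
        return np.mean([D[i, j] for i in a for j in b])

    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = cdist(clusters[i], clusters[j])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters = ([c for k, c in enumerate(clusters) if k not in (i, j)]
                    + [clusters[i] + clusters[j]])
    return sorted(heights)


def jacobi_eigenvalues(A, sweeps=100, tol=1e-14):
    """Eigenvalues of a symmetric matrix by cyclic Jacobi rotations."""
    A = np.array(A, dtype=float)
    n = A.shape[0]
    for _ in range(sweeps):
        off = np.sqrt(sum(A[i, j] ** 2 for i in range(n)
                          for j in range(n) if i != j))
        if off < tol * max(1.0, np.abs(np.diag(A)).max()):
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if A[p, q] == 0.0:
                    continue
                theta = (A[q, q] - A[p, p]) / (2.0 * A[p, q])
                t = np.sign(theta) / (abs(theta) + np.sqrt(theta ** 2 + 1.0)) \
                    if theta != 0 else 1.0
                cth = 1.0 / np.sqrt(t ** 2 + 1.0)
                sth = t * cth
                J = np.eye(n)
                J[p, p] = J[q, q] = cth
                J[p, q] = sth
                J[q, p] = -sth
                A = J.T @ A @ J
    return np.sort(np.diag(A))[::-1]


def exact_sum_of_squares(residuals):
    """Correctly rounded sum of squares via exact rational arithmetic."""
    total = Fraction(0)
    for r in residuals:
        total += Fraction(float(r)) ** 2
    return float(total)


def bisect_root(f, lo, hi, iters=80):
    """Plain bisection; assumes f(lo) <= 0 <= f(hi)."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if (fm <= 0) == (flo <= 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)
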