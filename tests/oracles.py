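"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library:
nested 2-D bracketing instead of the 1-D elimination, scipy brentq instead
of hand-rolled bisection, and explicit per-injection mixing instead of the
closed-form displacement expressions.
"""

import numpy as np
from scipy.optimize import brentq


def one_site_heat_oracle(Mt, Xt, kd, dH_kcal, V0_l):
    """1:1 total heat via root solving of the mass balance in free ligand."""
    if Xt == 0:
        return 0.0
    x = brentq(lambda x: x + Mt * x / (x + kd) - Xt, 0.0, Xt,
               xtol=1e-30, rtol=8.9e-16)
    mx = Mt * x / (x + kd)
    return V0_l * mx * dH_kcal * 1e3


def two_site_free_oracle(Mt, Xt, kd1, kd2, n_iter=70):
    """Two-site free concentrations by nested (2-D) bisection.

    Outer bisection on free macromolecule m in (0, Mt]; for each m the free
    ligand x is found by inner bisection of the ligand balance (monotone in
    x), then the macromolecule balance residual decides the outer move.
    Vectorized over array inputs.
    """
    Mt, Xt, kd1, kd2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (Mt, Xt, kd1, kd2)))

    def x_of_m(m):
        lo = np.zeros_like(Xt)
        hi = np.array(Xt, copy=True)
        for _ in range(n_iter):
            mid = 0.5 * (lo + hi)
            lig = mid + 2 * mid * m / kd1 + 2 * mid ** 2 * m / (kd1 * kd2)
            high = lig > Xt
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        return 0.5 * (lo + hi)

    lo_m = np.zeros_like(Mt)
    hi_m = np.array(Mt, copy=True)
    for _ in range(n_iter):
        mid = 0.5 * (lo_m + hi_m)
        x = x_of_m(mid)
        resid = mid * (1 + 2 * x / kd1 + x ** 2 / (kd1 * kd2)) - Mt
        high = resid > 0
        hi_m = np.where(high, mid, hi_m)
        lo_m = np.where(high, lo_m, mid)
    m = 0.5 * (lo_m + hi_m)
    return m, x_of_m(m)


def stepwise_mixing_oracle(volumes_l, v0_l, m0, x0):
    """Per-injection perfect-mixing finite-difference dilution.

    Amount bookkeeping with the displaced volume carrying the average of the
    pre- and post-injection concentrations (the same convention as the
    displaced-volume heat correction): for each injection v,
    ``c_new (v0 + v/2) = c_old (v0 - v/2) + c_syringe v``.
    """
    mt, xt = [], []
    m, x = m0, 0.0
    for v in volumes_l:
        m = m * (v0_l - v / 2) / (v0_l + v / 2)
        x = (x * (v0_l - v / 2) + x0 * v) / (v0_l + v / 2)
        mt.append(m)
        xt.append(x)
    return np.array(mt), np.array(xt)


def injection_heats_oracle(q_cal, vols_l, v0_l, dh0_ucal):
    """Plain-loop recomputation of the per-injection heat bookkeeping."""
    out = []
    qprev = 0.0
    for q, v in zip(q_cal, vols_l):
        dq = q + (v / v0_l) * (q + qprev) / 2.0 - qprev
        out.append(dq * 1e6 + dh0_ucal)
        qprev = q
    return np.array(out)
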