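"""Batched adaptive Runge-Kutta integration of the nonlinear models.

The two-lesion kinetic (TLK) system has no closed-form solution once the
pairwise DSB-interaction terms are active, so likelihood evaluation during
fitting requires one numerical solve per data point.  SciPy's generic
solver carries per-call overhead that dominates at the ~10^5 likelihood
evaluations of a multistart fit, so the hot path uses a Dormand-Prince
5(4) embedded pair compiled with numba and looped over all protocols of a
dataset.  Correctness of this stepper is established against
``scipy.integrate.solve_ivp`` in the test suite; the public single-protocol
prediction functions in :mod:`dsbkin.models` use SciPy directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tlk_batch_totals", "lpl_to_tlk"]

_MAX_STEPS = 2_000_000


@njit(cache=True)
def _tlk_rhs(y, r, p, out):
    c1, c2, c3, l1, l2, e1, e2, n1, n2, n12 = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9],
    )
    x1, x2 = y[0], y[1]
    out[0] = c1 * r - (e1 + l1) * x1 - (n1 * x1 + n12 * x2) * x1
    out[1] = c2 * r - (e2 + l2) * x2 - (n2 * x2 + n12 * x1) * x2
    out[2] = c3 * r + e1 * x1 + e2 * x2


@njit(cache=True)
def _integrate_segment(y, r, p, t_end, rtol, atol):
    """Dormand-Prince 5(4) with PI-free standard step control; in place."""
    k1 = np.empty(3)
    k2 = np.empty(3)
    k3 = np.empty(3)
    k4 = np.empty(3)
    k5 = np.empty(3)
    k6 = np.empty(3)
    k7 = np.empty(3)
    yt = np.empty(3)
    ynew = np.empty(3)

    t = 0.0
    h = t_end * 1e-2
    if h <= 0.0:
        return True
    steps = 0
    while t < t_end:
        if steps > _MAX_STEPS:
            return False
        steps += 1
        if t + h > t_end:
            h = t_end - t
        _tlk_rhs(y, r, p, k1)
        for i in range(3):
            yt[i] = y[i] + h * (0.2 * k1[i])
        _tlk_rhs(yt, r, p, k2)
        for i in range(3):
            yt[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _tlk_rhs(yt, r, p, k3)
        for i in range(3):
            yt[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i])
        _tlk_rhs(yt, r, p, k4)
        for i in range(3):
            yt[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _tlk_rhs(yt, r, p, k5)
        for i in range(3):
            yt[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _tlk_rhs(yt, r, p, k6)
        for i in range(3):
            ynew[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _tlk_rhs(ynew, r, p, k7)
        err = 0.0
        for i in range(3):
            e = h * (
                71.0 / 57600.0 * k1[i]
                - 71.0 / 16695.0 * k3[i]
                + 71.0 / 1920.0 * k4[i]
                - 17253.0 / 339200.0 * k5[i]
                + 22.0 / 525.0 * k6[i]
                - 1.0 / 40.0 * k7[i]
            )
            scale = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            q = e / scale
            err += q * q
        err = (err / 3.0) ** 0.5
        if err <= 1.0 or h <= t_end * 1e-14:
            t += h
            for i in range(3):
                y[i] = ynew[i]
        if err == 0.0:
            factor = 5.0
        else:
            factor = 0.9 * err ** (-0.2)
            if factor < 0.2:
                factor = 0.2
            elif factor > 5.0:
                factor = 5.0
        h *= factor
        if not np.isfinite(h) or h <= 0.0:
            return False
    return True


@njit(cache=True)
def _batch_totals(p, rates, durations, rtol, atol, out):
    n, s = rates.shape
    y = np.empty(3)
    for i in range(n):
        y[0] = 0.0
        y[1] = 0.0
        y[2] = 0.0
        ok = True
        for j in range(s):
            if durations[i, j] <= 0.0:
                continue
            ok = _integrate_segment(y, rates[i, j], p, durations[i, j], rtol, atol)
            if not ok:
                break
        out[i] = (y[0] + y[1] + y[2]) if ok else np.nan
    return out


def tlk_batch_totals(params, rates, durations, rtol=1e-8, atol=1e-10):
    """Total unrejoined DSBs/cell for a batch of padded protocols.

    ``params`` is the 10-vector (c1, c2, c3, lambda1, lambda2, epsilon1,
    epsilon2, eta1, eta2, eta12); ``rates``/``durations`` come from
    :func:`dsbkin._linear.protocol_arrays`.  Failed integrations yield NaN.
    """
    p = np.ascontiguousarray(np.asarray(params, dtype=float))
    out = np.empty(rates.shape[0])
    return _batch_totals(p, np.ascontiguousarray(rates),
                         np.ascontiguousarray(durations), rtol, atol, out)


def lpl_to_tlk(params):
    """Embed the 4-parameter one-rejoinable-class model in the TLK system.

    The rejoinable class maps onto class 1 (linear rate lambda, quadratic
    self-interaction eta) and the unrejoinable yield onto the direct
    class-3 yield; class 2 stays identically zero.
    """
    cr, cu, lam, eta = params
    return np.array([cr, 0.0, cu, lam, 0.0, 0.0, 0.0, eta, 0.0, 0.0])
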