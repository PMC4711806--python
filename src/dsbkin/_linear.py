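"""Closed-form propagation of the linear DSB cascade.

The three-class systems solved here all have the lower-triangular form

    x1' = g1 - a*x1
    x2' = g2 - b*x2 + c12*x1
    x3' = g3        + c23*x2

with constant coefficients within one exposure segment (the dose rate is
piecewise constant).  The solution over a segment of length ``t`` is an
exponential cascade; every term is evaluated through numerically stable
primitives so that coincident or vanishing decay constants (a == b,
a -> 0, b -> 0, and products a*t or (a-b)*t far below machine scale) are
handled as removable singularities rather than 0/0 cancellations.  Each
primitive switches to a truncated power series when its argument is small
enough that the closed form would lose more than ~1e-9 relative accuracy;
the series are truncated so their own error is below that level at the
switch point.

All functions are vectorized over a leading "protocol" axis, which is what
makes maximum-likelihood fitting with hundreds of data points and many
random starts affordable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["segment_step", "propagate", "protocol_arrays"]

# Switch points between closed forms and series expansions.
_X_SMALL = 0.1       # for the scalar phi-type primitives below
_DIFF_SMALL = 1e-4   # for the (a-b) divided difference
_A_SMALL = 1e-6      # for the /a divided differences W, Wint


def _e1(x):
    """(1 - exp(-x))/x with the x -> 0 limit 1.  Stable via expm1."""
    xs = np.where(x > 0.0, x, 1.0)
    return np.where(x > 0.0, -np.expm1(-xs) / xs, 1.0)


def _series(x, coeffs):
    """Evaluate sum_m coeffs[m] * (-x)^m by Horner's rule."""
    acc = np.zeros_like(x) + coeffs[-1]
    for c in coeffs[-2::-1]:
        acc = c - x * acc
    return acc


def _h2a(x):
    """(x - 1 + exp(-x))/x^2; equals sum (-x)^m/(m+2)!; limit 1/2."""
    small = x < _X_SMALL
    xs = np.where(small, 1.0, x)
    direct = (xs - 1.0 + np.exp(-xs)) / xs**2
    ser = _series(x, [1 / 2, 1 / 6, 1 / 24, 1 / 120, 1 / 720, 1 / 5040])
    return np.where(small, ser, direct)


def _h2b(x):
    """(1 - (1+x) exp(-x))/x^2 = int_0^1 u e^{-xu} du * ...; limit 1/2."""
    small = x < _X_SMALL
    xs = np.where(small, 1.0, x)
    direct = (1.0 - (1.0 + xs) * np.exp(-xs)) / xs**2
    ser = _series(x, [1 / 2, 1 / 3, 1 / 8, 1 / 30, 1 / 144, 1 / 840])
    return np.where(small, ser, direct)


def _h3(x):
    """(2 - (2 + 2x + x^2) exp(-x))/x^3; limit 1/3."""
    small = x < _X_SMALL
    xs = np.where(small, 1.0, x)
    direct = (2.0 - (2.0 + 2.0 * xs + xs**2) * np.exp(-xs)) / xs**3
    ser = _series(x, [1 / 3, 1 / 4, 1 / 10, 1 / 36, 1 / 168, 1 / 960])
    return np.where(small, ser, direct)


def _r3(x):
    """(x^2/2 - x + 1 - exp(-x))/x^3 = sum (-x)^m/(m+3)!; limit 1/6."""
    small = x < _X_SMALL
    xs = np.where(small, 1.0, x)
    direct = (xs**2 / 2.0 - xs + 1.0 - np.exp(-xs)) / xs**3
    ser = _series(x, [1 / 6, 1 / 24, 1 / 120, 1 / 720, 1 / 5040, 1 / 40320])
    return np.where(small, ser, direct)


def _n2(x, t):
    """N2 = int_0^t int_0^s u^2 e^{-b(s-u)} du ds with x = b*t; ~t^4/12."""
    small = x < _X_SMALL
    xs = np.where(small, 1.0, x)
    b = xs / np.where(t > 0.0, t, 1.0)
    i1 = t * _e1(xs)
    direct = (b**2 * t**3 / 3.0 - b * t**2 + 2.0 * t - 2.0 * i1) / b**3
    ser = t**4 * _series(x, [1 / 12, 1 / 60, 1 / 360, 1 / 2520])
    return np.where(small, ser, direct)


def _psi(a, b, t):
    """int_0^t e^{-b(t-s)} e^{-a s} ds = (e^{-at} - e^{-bt})/(b-a)."""
    u = (b - a) * t
    small = np.abs(u) < 0.5
    us = np.where(small, u, 1.0)
    f = np.where(us != 0.0, np.expm1(us) / np.where(us != 0.0, us, 1.0), 1.0)
    near = np.exp(-b * t) * t * f
    denom = np.where(small, 1.0, b - a)
    far = (np.exp(-a * t) - np.exp(-b * t)) / denom
    return np.where(small, near, far)


def _psi_int(a, b, t):
    """int_0^t psi(a,b,s) ds = (I1(a,t) - I1(b,t))/(b-a).

    Near a == b this is the removable-singularity limit
    int_0^t s e^{-ms} ds at the midpoint m = (a+b)/2; the midpoint form has
    relative error <= ((a-b)t)^2/24 at the switch point.
    """
    d = np.abs(b - a) * t
    small = d < _DIFF_SMALL
    m = 0.5 * (a + b)
    near = t**2 * _h2b(m * t)
    denom = np.where(small, 1.0, b - a)
    far = (t * _e1(a * t) - t * _e1(b * t)) / denom
    return np.where(small, near, far)


def _w(a, b, t):
    """int_0^t e^{-b(t-s)} I1(a,s) ds, the x1 -> x2 transfer kernel."""
    small = a * t < _A_SMALL
    i1b = t * _e1(b * t)
    denom = np.where(small, 1.0, a)
    far = (i1b - _psi(a, b, t)) / denom
    # a -> 0: M1 - (a/2) M2 with Mk = int_0^t s^k e^{-b(t-s)} ds
    phi2 = t**2 * _h2b(b * t)
    m1 = t * i1b - phi2
    m2 = t**2 * i1b - 2.0 * t * phi2 + t**3 * _h3(b * t)
    near = m1 - 0.5 * a * m2
    return np.where(small, near, far)


def _w_int(a, b, t):
    """int_0^t w(a,b,s) ds, the x1 -> x2 -> x3 double-transfer kernel."""
    small = a * t < _A_SMALL
    denom = np.where(small, 1.0, a)
    far = (t**2 * _h2a(b * t) - _psi_int(a, b, t)) / denom
    n1 = t**3 * _r3(b * t)
    near = n1 - 0.5 * a * _n2(b * t, t)
    return np.where(small, near, far)


def segment_step(state, coeffs, t, with_integrals=False):
    """Advance the cascade through one constant-coefficient segment.

    Parameters
    ----------
    state : tuple of arrays (x1, x2, x3)
        Class contents at the start of the segment.
    coeffs : tuple of arrays (g1, g2, g3, a, b, c12, c23)
        Induction rates (per h), total loss rates of the first two classes
        (per h) and class-conversion rates (per h) for this segment.
    t : array
        Segment duration (h); entries with t == 0 return the state
        unchanged.
    with_integrals : bool
        Also return (int x1 dt, int x2 dt) over the segment, needed to
        accumulate rejoined-DSB fluxes.
    """
    x1, x2, x3 = state
    g1, g2, g3, a, b, c12, c23 = [np.asarray(c, dtype=float) for c in coeffs]
    t = np.asarray(t, dtype=float)

    ea = np.exp(-a * t)
    eb = np.exp(-b * t)
    i1a = t * _e1(a * t)
    i1b = t * _e1(b * t)

    x1_new = x1 * ea + g1 * i1a
    x2_new = x2 * eb + g2 * i1b + c12 * (x1 * _psi(a, b, t) + g1 * _w(a, b, t))
    ix2 = x2 * i1b + g2 * t**2 * _h2a(b * t) + c12 * (x1 * _psi_int(a, b, t) + g1 * _w_int(a, b, t))
    x3_new = x3 + g3 * t + c23 * ix2
    if not with_integrals:
        return (x1_new, x2_new, x3_new)
    ix1 = x1 * i1a + g1 * t**2 * _h2a(a * t)
    return (x1_new, x2_new, x3_new), (ix1, ix2)


def propagate(coeff_fn, rates, durations, rejoin_rates=None):
    """Propagate a batch of protocols from the zero state.

    Parameters
    ----------
    coeff_fn : callable
        Maps an array of dose rates (Gy/h) to the segment coefficient
        tuple ``(g1, g2, g3, a, b, c12, c23)``.
    rates, durations : (P, S) arrays
        Dose rate and duration of each segment, zero-padded; the
        measurement rest interval must already be appended as a final
        zero-dose-rate segment.
    rejoin_rates : tuple (v1, v2), optional
        First-class and second-class rejoining rates; when given, the
        cumulative rejoined fluxes are accumulated and returned.

    Returns
    -------
    (x1, x2, x3) arrays of shape (P,), plus (rejoined1, rejoined2) when
    ``rejoin_rates`` is given.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    durations = np.atleast_2d(np.asarray(durations, dtype=float))
    n = rates.shape[0]
    zeros = np.zeros(n)
    state = (zeros.copy(), zeros.copy(), zeros.copy())
    r1 = np.zeros(n)
    r2 = np.zeros(n)
    for s in range(rates.shape[1]):
        coeffs = coeff_fn(rates[:, s])
        if rejoin_rates is None:
            state = segment_step(state, coeffs, durations[:, s])
        else:
            state, (ix1, ix2) = segment_step(state, coeffs, durations[:, s], with_integrals=True)
            r1 += rejoin_rates[0] * ix1
            r2 += rejoin_rates[1] * ix2
    if rejoin_rates is None:
        return state
    return state, (r1, r2)


def protocol_arrays(protocols):
    """Pack protocols into padded (P, S) rate/duration arrays.

    The measurement rest interval of each protocol is appended as a final
    zero-dose-rate segment, so propagating the returned arrays yields the
    state at assay time.  Zero-duration padding segments are no-ops.
    """
    n_seg = [len(p.segments) + 1 for p in protocols]
    s_max = max(n_seg) if n_seg else 1
    rates = np.zeros((len(protocols), s_max))
    durations = np.zeros((len(protocols), s_max))
    for i, p in enumerate(protocols):
        for j, seg in enumerate(p.segments):
            rates[i, j] = seg.dose_rate
            durations[i, j] = seg.duration
        durations[i, len(p.segments)] = p.measurement_time
    return rates, durations
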