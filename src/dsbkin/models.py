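"""Compartmental kinetic models of DSB rejoining.

Three formalisms are implemented, all tracking the mean number of DSBs per
cell in up to three classes (quickly-rejoinable, slowly-rejoinable,
unrejoinable) during and after irradiation at piecewise-constant dose
rate R (Gy/h):

* **RD** (radiation-dependent conversion): induction k_i*R per class,
  first-order rejoining v1, v2 of the first two classes, and
  radiation-driven conversion 1 -> 2 and 2 -> 3 at rates q1*R and q2*R.
  The system is linear with constant coefficients on each segment and is
  solved in closed form (exponential cascade, see :mod:`dsbkin._linear`).

* **TLK** (two-lesion kinetic): induction c_i*R, first-order rejoining
  lambda1, lambda2, radiation-independent fixation epsilon1, epsilon2 into
  the unrejoinable class, and pairwise (quadratic) interactions eta1,
  eta2, eta12 that remove both participating DSBs from the measured pool.
  Solved numerically.

* **LPL**-type reduction: one rejoinable class (linear rate lambda,
  quadratic rate eta) plus an unrejoinable class; 4 adjustable parameters.
  Quadratic events are counted as removal of the interacting DSBs from
  the measured total.

The observable in all cases is the total unrejoined DSBs per cell,
``dsb1 + dsb2 + dsb3``, evaluated ``measurement_time`` hours after the end
of the last exposure segment, starting from the zero state.
"""

from __future__ import annotations

import math
from dataclasses import astuple, dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _linear
from ._ode import lpl_to_tlk, tlk_batch_totals
from .exceptions import NumericalError, ValidationError
from .protocols import ExposureProtocol

__all__ = [
    "RDParams",
    "TLKParams",
    "LPLParams",
    "DSBState",
    "rd_propagate_segment",
    "rd_solve",
    "rd_predict",
    "tlk_solve",
    "tlk_predict",
    "lpl_solve",
    "lpl_predict",
    "rd_residual_lq",
    "predict",
]


def _check_nonneg(obj) -> None:
    for name, value in obj.__dict__.items():
        if not (math.isfinite(value) and value >= 0):
            raise ValidationError(
                f"{type(obj).__name__}.{name} must be finite and >= 0, got {value}"
            )


@dataclass(frozen=True)
class RDParams:
    """Radiation-dependent conversion model parameters.

    k1, k2, k3 : DSB yields per Gy of the three classes.
    v1, v2 : rejoining rates (1/h) of the quickly/slowly-rejoinable classes.
    q1, q2 : conversion coefficients (1/Gy); conversion proceeds at q*R (1/h).
    """

    k1: float
    k2: float
    k3: float
    v1: float
    v2: float
    q1: float
    q2: float

    def __post_init__(self) -> None:
        _check_nonneg(self)

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)


@dataclass(frozen=True)
class TLKParams:
    """Two-lesion kinetic model parameters.

    c1, c2, c3 : yields per Gy; lambda1, lambda2 : rejoining rates (1/h);
    epsilon1, epsilon2 : fixation rates (1/h); eta1, eta2, eta12 :
    pairwise interaction rates (1/h per DSB).
    """

    c1: float
    c2: float
    c3: float
    lambda1: float
    lambda2: float
    epsilon1: float = 0.0
    epsilon2: float = 0.0
    eta1: float = 0.0
    eta2: float = 0.0
    eta12: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg(self)

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)


@dataclass(frozen=True)
class LPLParams:
    """One rejoinable plus one unrejoinable DSB class; 4 parameters.

    cr, cu : yields per Gy of the rejoinable/unrejoinable classes;
    lam : linear rejoining rate (1/h); eta : quadratic rate (1/h per DSB).
    """

    cr: float
    cu: float
    lam: float
    eta: float

    def __post_init__(self) -> None:
        _check_nonneg(self)

    def as_array(self) -> np.ndarray:
        return np.array(astuple(self), dtype=float)


@dataclass(frozen=True)
class DSBState:
    """Per-class DSB contents plus cumulative flux accumulators.

    ``rejoined1``/``rejoined2`` integrate the first-order rejoining fluxes;
    ``removed_quadratic`` integrates pairwise-interaction removals (TLK and
    LPL only).  Together they make total DSB production an invariant:
    class contents plus accumulated fluxes equal (sum of yields) x dose.
    """

    dsb1: float = 0.0
    dsb2: float = 0.0
    dsb3: float = 0.0
    rejoined1: float = 0.0
    rejoined2: float = 0.0
    removed_quadratic: float = 0.0

    def __post_init__(self) -> None:
        _check_nonneg(self)

    @property
    def total_dsb(self) -> float:
        return self.dsb1 + self.dsb2 + self.dsb3

    @property
    def total_accounted(self) -> float:
        return self.total_dsb + self.rejoined1 + self.rejoined2 + self.removed_quadratic


def _rd_coeff_fn(p: RDParams):
    def coeffs(r):
        return (
            p.k1 * r,
            p.k2 * r,
            p.k3 * r,
            p.v1 + p.q1 * r,
            p.v2 + p.q2 * r,
            p.q1 * r,
            p.q2 * r,
        )

    return coeffs


def rd_propagate_segment(
    state: DSBState, params: RDParams, dose_rate: float, duration: float
) -> DSBState:
    """Advance the RD system through one constant-dose-rate segment.

    Uses the exact closed-form solution of the linear cascade; the
    rejoined-flux accumulators are advanced consistently
    (rejoinedN += vN * integral of dsbN over the segment).
    """
    if not (math.isfinite(dose_rate) and dose_rate >= 0):
        raise ValidationError(f"dose_rate must be finite and >= 0, got {dose_rate}")
    if not (math.isfinite(duration) and duration >= 0):
        raise ValidationError(f"duration must be finite and >= 0, got {duration}")
    coeffs = _rd_coeff_fn(params)(np.array([dose_rate]))
    x = (np.array([state.dsb1]), np.array([state.dsb2]), np.array([state.dsb3]))
    (x1, x2, x3), (ix1, ix2) = _linear.segment_step(
        x, coeffs, np.array([duration]), with_integrals=True
    )
    return DSBState(
        dsb1=float(x1[0]),
        dsb2=float(x2[0]),
        dsb3=float(x3[0]),
        rejoined1=state.rejoined1 + params.v1 * float(ix1[0]),
        rejoined2=state.rejoined2 + params.v2 * float(ix2[0]),
        removed_quadratic=state.removed_quadratic,
    )


def rd_solve(params: RDParams, protocol: ExposureProtocol) -> DSBState:
    """State at assay time, from the zero state, for a full protocol."""
    state = DSBState()
    for seg in protocol.segments:
        state = rd_propagate_segment(state, params, seg.dose_rate, seg.duration)
    if protocol.measurement_time > 0:
        state = rd_propagate_segment(state, params, 0.0, protocol.measurement_time)
    return state


def rd_predict(params: RDParams, protocol: ExposureProtocol) -> float:
    """Predicted total unrejoined DSBs/cell at assay time (RD model)."""
    return rd_solve(params, protocol).total_dsb


def _check_tolerance(tol: float) -> None:
    if not (0.0 < tol <= 1e-4):
        raise ValidationError(f"solver_tolerance must be in (0, 1e-4], got {tol}")


def _integrate_protocol(rhs, n_state: int, protocol: ExposureProtocol, args0, tol: float):
    """Integrate across segments plus the rest interval; restart at each
    dose-rate discontinuity."""
    y = np.zeros(n_state)
    pieces = [(s.dose_rate, s.duration) for s in protocol.segments]
    if protocol.measurement_time > 0:
        pieces.append((0.0, protocol.measurement_time))
    for dose_rate, duration in pieces:
        sol = solve_ivp(
            rhs,
            (0.0, duration),
            y,
            args=(dose_rate, *args0),
            method="LSODA",
            rtol=tol,
            atol=tol * 1e-2,
        )
        if not sol.success:
            raise NumericalError(f"ODE integration failed: {sol.message}")
        y = sol.y[:, -1]
    return y


def _tlk_rhs_full(t, y, r, p: TLKParams):
    x1, x2, _x3, _r1, _r2, _rq = y
    quad1 = (p.eta1 * x1 + p.eta12 * x2) * x1
    quad2 = (p.eta2 * x2 + p.eta12 * x1) * x2
    return [
        p.c1 * r - (p.epsilon1 + p.lambda1) * x1 - quad1,
        p.c2 * r - (p.epsilon2 + p.lambda2) * x2 - quad2,
        p.c3 * r + p.epsilon1 * x1 + p.epsilon2 * x2,
        p.lambda1 * x1,
        p.lambda2 * x2,
        quad1 + quad2,
    ]


def tlk_solve(
    params: TLKParams, protocol: ExposureProtocol, solver_tolerance: float = 1e-8
) -> DSBState:
    """Numerically integrate the TLK system across a protocol."""
    _check_tolerance(solver_tolerance)
    y = _integrate_protocol(_tlk_rhs_full, 6, protocol, (params,), solver_tolerance)
    return DSBState(*(max(v, 0.0) for v in y))


def tlk_predict(
    params: TLKParams, protocol: ExposureProtocol, solver_tolerance: float = 1e-8
) -> float:
    """Predicted total unrejoined DSBs/cell at assay time (TLK model)."""
    return tlk_solve(params, protocol, solver_tolerance).total_dsb


def _lpl_rhs_full(t, y, r, p: LPLParams):
    n, _u, _rl, _rq = y
    quad = p.eta * n * n
    return [p.cr * r - p.lam * n - quad, p.cu * r, p.lam * n, quad]


def lpl_solve(
    params: LPLParams, protocol: ExposureProtocol, solver_tolerance: float = 1e-8
) -> DSBState:
    """Integrate the one-rejoinable-class system across a protocol.

    The rejoinable class is reported as ``dsb1`` and the unrejoinable
    class as ``dsb3``; ``dsb2`` is identically zero.
    """
    _check_tolerance(solver_tolerance)
    n, u, rl, rq = _integrate_protocol(_lpl_rhs_full, 4, protocol, (params,), solver_tolerance)
    return DSBState(
        dsb1=max(n, 0.0),
        dsb3=max(u, 0.0),
        rejoined1=max(rl, 0.0),
        removed_quadratic=max(rq, 0.0),
    )


def lpl_predict(
    params: LPLParams, protocol: ExposureProtocol, solver_tolerance: float = 1e-8
) -> float:
    """Predicted total unrejoined DSBs/cell at assay time (LPL reduction)."""
    return lpl_solve(params, protocol, solver_tolerance).total_dsb


def _rd_acute_state(params: RDParams, dose: float):
    """End-of-irradiation state in the instantaneous-exposure limit.

    As R -> infinity at fixed dose the time-domain system reduces to a
    dose-domain cascade dx1/dD = k1 - q1 x1, dx2/dD = k2 - q2 x2 + q1 x1,
    dx3/dD = k3 + q2 x2 (rejoining is negligible during delivery).
    """
    coeffs = tuple(
        np.array([c])
        for c in (params.k1, params.k2, params.k3, params.q1, params.q2, params.q1, params.q2)
    )
    zeros = (np.zeros(1), np.zeros(1), np.zeros(1))
    x1, x2, x3 = _linear.segment_step(zeros, coeffs, np.array([dose]))
    return float(x1[0]), float(x2[0]), float(x3[0])


def rd_residual_lq(
    params: RDParams, dose: float, dose_rate: float
) -> tuple[float, float, float]:
    """Long-time residual of unrejoined DSBs and its linear-quadratic split.

    Returns ``(residual, alpha, beta)`` where ``residual`` is the
    infinite-rejoining-time limit of the RD prediction (the unrejoinable
    class content at the end of irradiation, since the rejoinable classes
    decay to zero), ``alpha = k3`` is the linear dose-response
    coefficient, and ``beta = (residual - k3*dose)/dose**2`` is the
    effective quadratic coefficient at this dose and dose rate.  In the
    acute limit (``dose_rate = inf``) beta tends to k2*q2/2 at small
    doses; it vanishes as the dose rate tends to zero because
    quickly-rejoinable DSBs are rejoined before radiation can convert
    them.
    """
    if not (math.isfinite(dose) and dose > 0):
        raise ValidationError(f"dose must be finite and > 0, got {dose}")
    if not dose_rate > 0:
        raise ValidationError(f"dose_rate must be > 0 (or inf), got {dose_rate}")
    if math.isinf(dose_rate):
        x1, x2, x3 = _rd_acute_state(params, dose)
    else:
        state = rd_solve(params, ExposureProtocol.single_dose(dose, dose_rate, 0.0))
        x1, x2, x3 = state.dsb1, state.dsb2, state.dsb3
    tiny = 1e-12 * max(1.0, dose)
    if x1 > tiny and params.v1 == 0:
        raise NumericalError("no finite residual: v1 = 0 with nonzero quickly-rejoinable content")
    if x2 > tiny and params.v2 == 0:
        raise NumericalError("no finite residual: v2 = 0 with nonzero slowly-rejoinable content")
    residual = x3
    alpha = params.k3
    beta = (residual - params.k3 * dose) / dose**2
    return residual, alpha, beta


#: Registry of model labels to (parameter class, predict function).
MODEL_PREDICTORS = {
    "rd": (RDParams, rd_predict),
    "tlk": (TLKParams, tlk_predict),
    "lpl": (LPLParams, lpl_predict),
}


def predict(model: str, params, protocol: ExposureProtocol) -> float:
    """Dispatch a single-protocol prediction by model label.

    ``params`` may be the model's parameter dataclass or a plain sequence
    in field order.  The dose-independent-conversion variant of the RD
    model (label ``rd_const_conversion``) is also accepted; see
    :mod:`dsbkin.inference`.
    """
    if model == "rd_const_conversion":
        from .inference import predictions_for  # local import to avoid a cycle

        return float(predictions_for(model, params, [protocol])[0])
    try:
        cls, fn = MODEL_PREDICTORS[model]
    except KeyError:
        raise ValidationError(f"unknown model label {model!r}") from None
    if not isinstance(params, cls):
        params = cls(*np.asarray(params, dtype=float))
    return fn(params, protocol)
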