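"""Maximum-likelihood fitting and profile-likelihood uncertainty.

The measurement error is modelled as Gaussian.  With constant variance the
error scale sigma can be profiled out analytically, giving the profiled
log-likelihood

    LL = -(N/2) * ( ln(SSE/N) + ln(2*pi) + 1 )

where SSE is the sum of squared prediction residuals; sigma is therefore
not an adjustable parameter and is not counted in K for AICc.  An
alternative error model with magnitudes proportional to the observations
replaces each squared residual by residual^2 / observation^2.

Fitting maximizes LL over non-negative parameters by running a
derivative-based constrained local optimizer (SLSQP) from many random
initial points, which guards against local maxima of these multi-modal
kinetic likelihoods.  Parameters are internally rescaled to order one so
that finite-difference gradients are well conditioned across the several
decades separating yields, rates and conversion coefficients.

Confidence intervals use the profile-likelihood criterion: parameter
vectors are Monte-Carlo sampled around the best fit and those whose
log-likelihood lies within chi2_1(0.95)/2 = 1.9207 of the maximum define
the 95% confidence region; per-parameter intervals are the extent of that
retained cloud.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from . import _linear
from ._ode import lpl_to_tlk, tlk_batch_totals
from .exceptions import FitError, NumericalError, ValidationError
from .protocols import Dataset

__all__ = [
    "CHI2_1_95_HALF",
    "FitConfig",
    "FitResult",
    "loglik",
    "fit",
    "profile_ci",
    "predictions_for",
    "MODELS",
]

#: chi-square(1 dof) 95% quantile halved: the profile-likelihood drop
#: defining a 95% confidence region.
CHI2_1_95_HALF = 1.9207

_LOG_2PI = math.log(2.0 * math.pi)

# Random-start sampling ranges (log-uniform) and optimizer caps by
# parameter kind; the ranges bracket the magnitudes seen in published
# joint fits by at least two decades on each side.
_KIND_RANGES = {
    "yield": (1e-4, 1.0),   # Gy^-1
    "rate": (1e-3, 10.0),   # h^-1
    "conv": (1e-6, 1e-2),   # Gy^-1
    "eta": (1e-7, 1e-3),    # (h * DSB)^-1
}
_KIND_CAPS = {"yield": 10.0, "rate": 100.0, "conv": 0.1, "eta": 1.0}


@dataclass(frozen=True)
class _ModelDef:
    name: str
    param_names: tuple[str, ...]
    kinds: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


MODELS: dict[str, _ModelDef] = {
    "rd": _ModelDef(
        "rd",
        ("k1", "k2", "k3", "v1", "v2", "q1", "q2"),
        ("yield", "yield", "yield", "rate", "rate", "conv", "conv"),
    ),
    # Variant of the RD model in which class conversion proceeds at a
    # constant (dose-rate-independent) rate q (h^-1) instead of q*R.
    "rd_const_conversion": _ModelDef(
        "rd_const_conversion",
        ("k1", "k2", "k3", "v1", "v2", "q1", "q2"),
        ("yield", "yield", "yield", "rate", "rate", "rate", "rate"),
    ),
    "tlk": _ModelDef(
        "tlk",
        ("c1", "c2", "c3", "lambda1", "lambda2",
         "epsilon1", "epsilon2", "eta1", "eta2", "eta12"),
        ("yield", "yield", "yield", "rate", "rate", "rate", "rate", "eta", "eta", "eta"),
    ),
    "lpl": _ModelDef(
        "lpl",
        ("cr", "cu", "lam", "eta"),
        ("yield", "yield", "rate", "eta"),
    ),
}


def _batch_predictor(
    model: str, rates: np.ndarray, durations: np.ndarray, solver_tolerance: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized predictions for all protocols of a packed design."""
    if model == "rd":

        def predictor(theta: np.ndarray) -> np.ndarray:
            k1, k2, k3, v1, v2, q1, q2 = theta

            def coeffs(r):
                return (k1 * r, k2 * r, k3 * r, v1 + q1 * r, v2 + q2 * r, q1 * r, q2 * r)

            x1, x2, x3 = _linear.propagate(coeffs, rates, durations)
            return x1 + x2 + x3

    elif model == "rd_const_conversion":

        def predictor(theta: np.ndarray) -> np.ndarray:
            k1, k2, k3, v1, v2, q1, q2 = theta

            def coeffs(r):
                one = np.ones_like(r)
                return (k1 * r, k2 * r, k3 * r, (v1 + q1) * one, (v2 + q2) * one,
                        q1 * one, q2 * one)

            x1, x2, x3 = _linear.propagate(coeffs, rates, durations)
            return x1 + x2 + x3

    elif model == "tlk":

        def predictor(theta: np.ndarray) -> np.ndarray:
            return tlk_batch_totals(theta, rates, durations,
                                    rtol=solver_tolerance, atol=solver_tolerance * 1e-2)

    elif model == "lpl":

        def predictor(theta: np.ndarray) -> np.ndarray:
            return tlk_batch_totals(lpl_to_tlk(theta), rates, durations,
                                    rtol=solver_tolerance, atol=solver_tolerance * 1e-2)

    else:
        raise ValidationError(f"unknown model label {model!r}")
    return predictor


def predictions_for(
    model: str, params, protocols: Sequence, solver_tolerance: float = 1e-8
) -> np.ndarray:
    """Model predictions for a list of protocols via the batch engine."""
    theta = params.as_array() if hasattr(params, "as_array") else np.asarray(params, dtype=float)
    rates, durations = _linear.protocol_arrays(list(protocols))
    return _batch_predictor(model, rates, durations, solver_tolerance)(theta)


def loglik(predictions, observations, error_model: str = "constant_variance") -> float:
    """Profiled Gaussian log-likelihood of predictions given observations.

    ``constant_variance`` profiles out a common sigma; ``proportional``
    assumes error magnitudes proportional to the observed values, i.e.
    squared residuals are divided by the squared observations.  Larger is
    better.
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValidationError("predictions and observations must be 1-d and equal length")
    n = p.size
    if n < 2:
        raise ValidationError(f"need at least 2 data points, got {n}")
    if error_model == "constant_variance":
        q = float(np.sum((p - o) ** 2))
    elif error_model == "proportional":
        if np.any(o == 0):
            raise ValidationError("proportional error model undefined for zero observations")
        q = float(np.sum(((p - o) / o) ** 2))
    else:
        raise ValidationError(f"unknown error model {error_model!r}")
    if q == 0.0:
        raise NumericalError("degenerate perfect fit: zero residual sum of squares")
    return -0.5 * n * (math.log(q / n) + _LOG_2PI + 1.0)


@dataclass
class FitConfig:
    """Configuration of a multistart maximum-likelihood fit."""

    n_starts: int = 100
    seed: int = 0
    error_model: str = "constant_variance"
    solver_tolerance: float = 1e-6  # ODE tolerance used inside fitting loops
    ll_tol: float = 1e-10           # convergence tolerance on the log-likelihood
    max_iter: int = 300
    #: optional per-parameter upper bounds (by name); lower bounds are 0
    upper_bounds: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError(f"n_starts must be >= 1, got {self.n_starts}")
        if self.error_model not in ("constant_variance", "proportional"):
            raise ValidationError(f"unknown error model {self.error_model!r}")
        if self.upper_bounds is not None and any(v <= 0 for v in self.upper_bounds.values()):
            raise ValidationError("upper bounds must be positive")


@dataclass
class FitResult:
    """Outcome of a multistart fit.

    ``trace`` records (start index, converged log-likelihood, converged
    flag) for every start; ``max_loglik`` is the maximum over converged
    starts.  ``ci95`` is filled by :func:`profile_ci`.
    """

    model: str
    param_names: tuple[str, ...]
    params: np.ndarray
    max_loglik: float
    n_points: int
    k: int
    trace: list[tuple[int, float, bool]] = field(default_factory=list)
    seed: int = 0
    error_model: str = "constant_variance"
    ci95: dict[str, tuple[float, float]] | None = None

    def params_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, self.params)}

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "params": self.params_dict(),
            "max_loglik": self.max_loglik,
            "n_points": self.n_points,
            "k": self.k,
            "seed": self.seed,
            "error_model": self.error_model,
            "ci95": self.ci95,
            "trace": [
                {"start": i, "loglik": ll, "converged": ok} for i, ll, ok in self.trace
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        names = tuple(d["params"].keys())
        ci = d.get("ci95")
        if ci is not None:
            ci = {k: tuple(v) for k, v in ci.items()}
        return cls(
            model=d["model"],
            param_names=names,
            params=np.array([d["params"][n] for n in names], dtype=float),
            max_loglik=d["max_loglik"],
            n_points=d["n_points"],
            k=d["k"],
            trace=[(t["start"], t["loglik"], t["converged"]) for t in d.get("trace", [])],
            seed=d.get("seed", 0),
            error_model=d.get("error_model", "constant_variance"),
            ci95=ci,
        )


def _dataset_design(dataset: Dataset):
    classes = {m.radiation_class for m in dataset.measurements}
    if len(classes) > 1:
        raise ValidationError(
            "dataset mixes radiation classes; fit each class separately "
            f"(got {sorted(classes)})"
        )
    protocols = [m.protocol for m in dataset.measurements]
    return _linear.protocol_arrays(protocols), dataset.observations


def _weighted_sse(pred: np.ndarray, obs: np.ndarray, error_model: str) -> float:
    if error_model == "proportional":
        r = (pred - obs) / obs
    else:
        r = pred - obs
    return float(np.sum(r * r))


def fit(model: str, dataset: Dataset, config: FitConfig | None = None) -> FitResult:
    """Multistart constrained maximum-likelihood fit of one model.

    Initial points are drawn log-uniformly from ranges bracketing the
    plausible magnitude of each parameter kind; every start is refined by
    SLSQP under non-negativity bounds.  Deterministic given
    ``config.seed``.
    """
    config = config or FitConfig()
    mdef = MODELS.get(model)
    if mdef is None:
        raise ValidationError(f"unknown model label {model!r}")
    (rates, durations), obs = _dataset_design(dataset)
    n = obs.size
    if n < 2:
        raise ValidationError(f"need at least 2 data points to fit, got {n}")
    if config.error_model == "proportional" and np.any(obs == 0):
        raise ValidationError("proportional error model undefined for zero observations")
    predictor = _batch_predictor(model, rates, durations, config.solver_tolerance)

    lo = np.array([_KIND_RANGES[k][0] for k in mdef.kinds])
    hi = np.array([_KIND_RANGES[k][1] for k in mdef.kinds])
    caps = np.array([_KIND_CAPS[k] for k in mdef.kinds])
    if config.upper_bounds:
        for name, cap in config.upper_bounds.items():
            if name not in mdef.param_names:
                raise ValidationError(f"unknown parameter {name!r} for model {model!r}")
            j = mdef.param_names.index(name)
            caps[j] = cap
            hi[j] = min(hi[j], cap)
            lo[j] = min(lo[j], hi[j])
    scale = np.sqrt(lo * hi)  # geometric mid-range; brings variables to O(1)

    def objective(z: np.ndarray) -> float:
        pred = predictor(z * scale)
        if not np.all(np.isfinite(pred)):
            return 1e9
        q = _weighted_sse(pred, obs, config.error_model)
        return 0.5 * n * math.log(q / n + 1e-300)

    rng = np.random.default_rng(config.seed)
    draws = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=(config.n_starts, mdef.k))
    bounds = [(0.0, c / s) for c, s in zip(caps, scale)]

    trace: list[tuple[int, float, bool]] = []
    best_z = None
    best_obj = math.inf
    for i in range(config.n_starts):
        res = minimize(
            objective,
            draws[i] / scale,
            method="SLSQP",
            bounds=bounds,
            options={"ftol": config.ll_tol, "maxiter": config.max_iter},
        )
        ll_i = -res.fun - 0.5 * n * (_LOG_2PI + 1.0)
        trace.append((i, float(ll_i), bool(res.success)))
        if res.success and res.fun < best_obj:
            best_obj = res.fun
            best_z = res.x
    if best_z is None:
        raise FitError(
            f"no start converged for model {model!r}; trace: "
            + ", ".join(f"#{i}: LL={ll:.4g} ok={ok}" for i, ll, ok in trace)
        )
    # snap parameters the optimizer left within rounding error of the
    # non-negativity boundary onto it, provided the likelihood agrees
    snapped = np.where(best_z < 1e-10, 0.0, best_z)
    if np.any(snapped != best_z) and objective(snapped) <= best_obj + 10 * config.ll_tol:
        best_z = snapped
        best_obj = min(best_obj, objective(snapped))
    theta = best_z * scale
    max_ll = -best_obj - 0.5 * n * (_LOG_2PI + 1.0)
    return FitResult(
        model=model,
        param_names=mdef.param_names,
        params=theta,
        max_loglik=float(max_ll),
        n_points=n,
        k=mdef.k,
        trace=trace,
        seed=config.seed,
        error_model=config.error_model,
    )


def _curvature_sampler(ll_of, best: np.ndarray, scale: np.ndarray):
    """Gaussian vicinity sampler from the local likelihood curvature.

    The Hessian of -LL at the best fit is estimated by finite differences
    in rescaled coordinates (stepped inward at the non-negativity
    boundary), repaired to positive definite by eigenvalue clipping, and
    inverted to give the sampling covariance.  Returns ``(draw, sd)``
    where ``draw(rng, m, widen)`` yields m parameter vectors clipped at
    zero and ``sd`` is the per-parameter marginal standard error.
    """
    d = best.size
    z0 = best / scale

    def f(z: np.ndarray) -> float:
        return ll_of(z * scale)

    h = np.maximum(np.abs(z0) * 1e-3, 1e-4)
    zc = np.maximum(z0, h)  # step inward from the boundary
    f0 = f(zc)
    hess = np.empty((d, d))
    f_plus = np.empty(d)
    for j in range(d):
        zp = zc.copy()
        zp[j] += h[j]
        zm = zc.copy()
        zm[j] -= h[j]
        f_plus[j] = f(zp)
        hess[j, j] = -(f_plus[j] - 2.0 * f0 + f(zm)) / h[j] ** 2
    for j in range(d):
        for k in range(j + 1, d):
            zpp = zc.copy()
            zpp[j] += h[j]
            zpp[k] += h[k]
            mixed = (f(zpp) - f_plus[j] - f_plus[k] + f0) / (h[j] * h[k])
            hess[j, k] = hess[k, j] = -mixed
    evals, evecs = np.linalg.eigh(0.5 * (hess + hess.T))
    # flat/negative directions get a variance cap instead of blowing up
    floor = 1.0 / (2.0 * max(float(np.linalg.norm(z0)), 0.1)) ** 2
    evals = np.maximum(evals, max(floor, float(evals.max()) * 1e-10))
    cov = evecs @ np.diag(1.0 / evals) @ evecs.T
    chol = evecs @ np.diag(1.0 / np.sqrt(evals))
    sd = np.sqrt(cov.diagonal()) * scale

    def draw(rng: np.random.Generator, m: int, widen: float) -> np.ndarray:
        z = z0[None, :] + widen * rng.standard_normal((m, d)) @ chol.T
        return np.clip(z * scale[None, :], 0.0, None)

    def draw_ridge(rng: np.random.Generator, m: int, widen: float) -> np.ndarray:
        """Draws stretched along each parameter's profile direction.

        For each coordinate in turn, the coordinate is swept uniformly
        across the contour width while the others follow their
        conditional Gaussian (shrunk toward the conditional mean), which
        concentrates samples near the profile ridge where the
        per-parameter interval endpoints live.
        """
        rows = []
        for j in range(d):
            mj = m // d + (1 if j < m % d else 0)
            if mj == 0:
                continue
            sj = math.sqrt(cov[j, j])
            w = rng.uniform(-2.4, 2.4, mj) * widen
            zj = z0[j] + w * sj
            cond_gain = cov[:, j] / cov[j, j]
            cond_cov = cov - np.outer(cov[:, j], cov[:, j]) / cov[j, j]
            ev, evec = np.linalg.eigh(cond_cov)
            ev = np.maximum(ev, 0.0)
            lc = evec @ np.diag(np.sqrt(ev))
            z = (
                z0[None, :]
                + np.outer(zj - z0[j], cond_gain)
                + 0.4 * rng.standard_normal((mj, d)) @ lc.T
            )
            z[:, j] = zj
            rows.append(z)
        return np.clip(np.vstack(rows) * scale[None, :], 0.0, None)

    return draw, draw_ridge, sd


def profile_ci(
    fit_result: FitResult,
    dataset: Dataset,
    n_samples: int = 10_000,
    seed: int = 0,
    solver_tolerance: float = 1e-6,
) -> dict[str, tuple[float, float]]:
    """Monte-Carlo profile-likelihood 95% confidence intervals.

    Parameter vectors are Monte-Carlo sampled in the vicinity of the best
    fit from a Gaussian cloud whose covariance comes from the inverse
    Hessian of the log-likelihood at the maximum (a mixture of one- and
    two-sigma-scaled clouds populates both the contour interior and its
    tails); draws are clipped at the non-negativity boundary.  Vectors
    with LL >= LLmax - chi2_1(0.95)/2 are retained and each parameter's
    95% interval is the min/max of the retained cloud.  If an interval
    appears truncated by the sampling cloud itself, one adaptive widening
    pass re-samples with tripled scales.  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    mdef = MODELS[fit_result.model]
    (rates, durations), obs = _dataset_design(dataset)
    predictor = _batch_predictor(fit_result.model, rates, durations, solver_tolerance)
    n = obs.size
    best = np.asarray(fit_result.params, dtype=float)
    ll_max = fit_result.max_loglik

    def ll_of(theta: np.ndarray) -> float:
        pred = predictor(theta)
        if not np.all(np.isfinite(pred)):
            return -math.inf
        q = _weighted_sse(pred, obs, fit_result.error_model)
        return -0.5 * n * (math.log(q / n + 1e-300) + _LOG_2PI + 1.0)

    rng = np.random.default_rng(seed)
    scale = np.array(
        [math.sqrt(_KIND_RANGES[k][0] * _KIND_RANGES[k][1]) for k in mdef.kinds]
    )
    draw, draw_ridge, sd = _curvature_sampler(ll_of, best, scale)

    def retained_of(widen: float) -> np.ndarray:
        # a general cloud at one and two curvature scales plus draws
        # concentrated along each parameter's profile ridge
        m = n_samples // 4
        cloud = np.vstack(
            [
                draw(rng, m, widen),
                draw(rng, m, 2.0 * widen),
                draw_ridge(rng, n_samples - 2 * m, widen),
            ]
        )
        lls = np.array([ll_of(row) for row in cloud])
        keep = cloud[lls >= ll_max - CHI2_1_95_HALF]
        return np.vstack([keep, best[None, :]])

    retained = retained_of(1.0)
    if retained.shape[0] == 1 and n_samples >= 10:
        retained = retained_of(3.0)
        if retained.shape[0] == 1:
            raise FitError("profile sampling retained no points near the best fit")
    lo_cloud = retained.min(axis=0)
    hi_cloud = retained.max(axis=0)
    # widen once if any interval endpoint sits at the edge of the sampled cloud
    touch = (
        ((best - lo_cloud) > 0.9 * 4.0 * sd) & (lo_cloud > 0)
    ) | ((hi_cloud - best) > 0.9 * 4.0 * sd)
    if touch.any():
        retained = np.vstack([retained, retained_of(3.0)])
        lo_cloud = retained.min(axis=0)
        hi_cloud = retained.max(axis=0)

    ci = {
        name: (float(lo_cloud[j]), float(hi_cloud[j]))
        for j, name in enumerate(fit_result.param_names)
    }
    fit_result.ci95 = ci
    return ci
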