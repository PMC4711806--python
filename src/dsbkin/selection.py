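"""Information-theoretic model selection and absolute goodness of fit.

Models are ranked by the small-sample-corrected Akaike information
criterion

    AICc = -2*LL + 2*K + 2*K*(K+1)/(N-K-1)

where K counts adjustable kinetic parameters (the profiled error scale is
not counted) and N is the number of data points.  Differences
DeltaAICc = AICc - min(AICc) translate into evidence ratios
ER = exp(-DeltaAICc/2); DeltaAICc > 6 (ER < 0.05) marks a model with much
poorer support.  BIC and F-tests are deliberately not offered: AICc is
the sole ranking criterion here because it compares structurally distinct
non-nested models on an interpretable scale.

Absolute goodness of fit is assessed per exposure subset (high-dose-rate
single doses, high-dose-rate split doses, low-dose-rate single doses) by
the coefficient of determination and by ordinary least-squares regression
of model predictions on the observations: a fit is free of gross
systematic deviation when the 95% CI of the intercept contains 0 and that
of the slope contains 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .exceptions import ValidationError
from .inference import FitResult, predictions_for
from .protocols import Dataset, Measurement

__all__ = [
    "aicc",
    "evidence_ratio",
    "gof",
    "GofResult",
    "SelectionReport",
    "compare",
    "exposure_subset",
]

#: Dose-rate threshold (Gy/h) separating low- from high-dose-rate exposures.
LDR_THRESHOLD = 100.0


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n <= k + 1:
        raise ValidationError(f"sample too small for AICc: N={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def evidence_ratio(delta_aicc: float) -> float:
    """Relative likelihood exp(-DeltaAICc/2) of a model vs the best one."""
    if delta_aicc < 0:
        raise ValidationError(f"delta AICc must be >= 0, got {delta_aicc}")
    return math.exp(-0.5 * delta_aicc)


@dataclass(frozen=True)
class GofResult:
    """Goodness-of-fit diagnostics for one model on one data subset."""

    r2: float
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    passed: bool
    n: int


def gof(predictions, observations) -> GofResult:
    """R-squared and predictions-vs-observations regression diagnostics.

    R^2 = 1 - SSE/SStot with SSE the squared prediction residuals and
    SStot the squared deviations of the observations about their mean.
    The regression takes predictions as the response and observations as
    the predictor; the orientation matters for the slope and follows the
    convention "model predictions vs. data".
    """
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValidationError("predictions and observations must be 1-d and equal length")
    n = p.size
    if n < 3:
        raise ValidationError(f"need at least 3 points for GOF, got {n}")
    sstot = float(np.sum((o - o.mean()) ** 2))
    if sstot == 0.0:
        raise ValidationError("R^2 undefined: observations have zero variance")
    r2 = 1.0 - float(np.sum((o - p) ** 2)) / sstot
    res = sm.OLS(p, sm.add_constant(o)).fit()
    ci = res.conf_int(alpha=0.05)
    icpt_ci = (float(ci[0, 0]), float(ci[0, 1]))
    slope_ci = (float(ci[1, 0]), float(ci[1, 1]))
    passed = (icpt_ci[0] <= 0.0 <= icpt_ci[1]) and (slope_ci[0] <= 1.0 <= slope_ci[1])
    return GofResult(
        r2=r2,
        intercept=float(res.params[0]),
        intercept_ci=icpt_ci,
        slope=float(res.params[1]),
        slope_ci=slope_ci,
        passed=passed,
        n=n,
    )


def exposure_subset(measurement: Measurement) -> str:
    """Classify a measurement as hdr_single / hdr_split / ldr_single."""
    irr = measurement.protocol.irradiation_segments
    if len(irr) > 1:
        return "hdr_split"
    rate = irr[0].dose_rate if irr else math.inf
    return "ldr_single" if rate < LDR_THRESHOLD else "hdr_single"


@dataclass
class SelectionReport:
    """AICc ranking plus per-subset GOF for a set of fitted models."""

    n_points: int
    entries: list[dict] = field(default_factory=list)
    gof_by_subset: dict[str, dict[str, GofResult]] = field(default_factory=dict)

    @property
    def best_model(self) -> str:
        return min(self.entries, key=lambda e: e["aicc"])["model"]

    def delta_aicc(self, model: str) -> float:
        for e in self.entries:
            if e["model"] == model:
                return e["delta_aicc"]
        raise ValidationError(f"model {model!r} not in report")

    def to_json(self) -> str:
        payload = {
            "n_points": self.n_points,
            "models": self.entries,
            "gof": {
                model: {subset: vars(g) for subset, g in by_subset.items()}
                for model, by_subset in self.gof_by_subset.items()
            },
        }
        return json.dumps(payload, indent=2, default=float)

    def to_text(self) -> str:
        lines = [f"{'model':<22}{'K':>4}{'N':>6}{'LL':>12}{'AICc':>12}{'dAICc':>10}{'ER':>12}"]
        for e in self.entries:
            lines.append(
                f"{e['model']:<22}{e['k']:>4}{e['n']:>6}{e['loglik']:>12.3f}"
                f"{e['aicc']:>12.3f}{e['delta_aicc']:>10.2f}{e['evidence_ratio']:>12.3g}"
            )
        for model, by_subset in self.gof_by_subset.items():
            for subset, g in by_subset.items():
                flag = "ok" if g.passed else "SYSTEMATIC DEVIATION"
                lines.append(
                    f"{model} / {subset}: R2={g.r2:.3f} "
                    f"i={g.intercept:.2f} ({g.intercept_ci[0]:.2f},{g.intercept_ci[1]:.2f}) "
                    f"s={g.slope:.2f} ({g.slope_ci[0]:.2f},{g.slope_ci[1]:.2f}) [{flag}]"
                )
        return "\n".join(lines)


def compare(
    fits: list[FitResult], dataset: Dataset, solver_tolerance: float = 1e-8
) -> SelectionReport:
    """Assemble the AICc ranking and per-subset GOF for fitted models.

    All fits must refer to the given dataset (checked through N); model
    predictions are recomputed at the best-fit parameters to evaluate the
    per-subset diagnostics.
    """
    n = len(dataset)
    for f in fits:
        if f.n_points != n:
            raise ValidationError(
                f"fit for {f.model!r} used N={f.n_points} but dataset has N={n}"
            )
    aiccs = [aicc(f.max_loglik, f.k, f.n_points) for f in fits]
    best = min(aiccs)
    report = SelectionReport(n_points=n)
    for f, a in zip(fits, aiccs):
        delta = a - best
        report.entries.append(
            {
                "model": f.model,
                "k": f.k,
                "n": f.n_points,
                "loglik": f.max_loglik,
                "aicc": a,
                "delta_aicc": delta,
                "evidence_ratio": evidence_ratio(delta),
            }
        )

    subsets: dict[str, list[int]] = {}
    for i, m in enumerate(dataset.measurements):
        subsets.setdefault(exposure_subset(m), []).append(i)
    obs = dataset.observations
    protocols = [m.protocol for m in dataset.measurements]
    for f in fits:
        preds = predictions_for(f.model, f.params, protocols, solver_tolerance)
        by_subset: dict[str, GofResult] = {}
        for subset, idx in sorted(subsets.items()):
            if len(idx) < 3 or np.ptp(obs[idx]) == 0:
                continue
            by_subset[subset] = gof(preds[idx], obs[idx])
        report.gof_by_subset[f.model] = by_subset
    return report
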