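# Methods

## Models and conventions

All three models track the mean number of DSBs per cell in up to three
classes during and after irradiation. Units are fixed throughout: dose
in Gy, dose rate R in Gy/h, time in h, yields in Gy⁻¹, first-order rates
in h⁻¹, pairwise interaction rates in (h·DSB)⁻¹.

An exposure protocol is an ordered list of piecewise-constant dose-rate
segments. A single dose D at rate R is one segment of duration D/R — the
delivery time is modelled explicitly, which matters at low dose rate
(protracted 1250–2400 Gy γ exposures last 38–73 h, during which
rejoining competes with induction). A split exposure is irradiation /
rest / irradiation with equal fractions; rejoining proceeds during the
rest. The measurement clock starts at the end of the last segment, so a
rejoining time of 0 means "assayed immediately after irradiation".
Observations are net radiation-induced DSBs per cell; the unirradiated
background is taken as zero. These conventions reproduce all six
published worked-example predictions, which is the strongest available
check that they match how the original measurements were taken.

The observable is always DSB₁+DSB₂+DSB₃ at assay time, from the zero
initial state.

## Closed-form solution of the linear cascade

The RD system (and the TLK system when all ε and η vanish, and the
dose-independent-conversion RD variant) has the lower-triangular form
x₁′ = g₁ − a·x₁; x₂′ = g₂ − b·x₂ + c₁₂·x₁; x₃′ = g₃ + c₂₃·x₂ with
constant coefficients on each segment. The solution is an exponential
cascade whose terms contain removable singularities at a = b, a → 0 and
b → 0. Rather than switching between branch formulas per case, every
term is built from numerically stable primitives: expm1-based forms such
as (1−e^{−x})/x, and divided differences such as
(e^{−at}−e^{−bt})/(b−a), each of which switches to a truncated power
series when its argument is small enough that the closed form would lose
more than ~1e−9 relative accuracy (switch points 0.1 for the scalar
primitives, 1e−4·t for the rate divided difference, 1e−6·t for the
double-transfer kernels; series are truncated so their own error at the
switch point is below ~1e−9). The propagation therefore meets a uniform
~1e−8 relative accuracy target against adaptive ODE integration,
including exactly coincident decay rates and structurally zero
parameters (the α-particle parameter set has k₁ = v₁ = q₁ = 0). The
engine is vectorized over protocols, which is what makes multistart
likelihood maximization with hundreds of data points affordable.

Flux accumulators (cumulative rejoined DSBs per class, cumulative
quadratic removals) are propagated alongside the class contents so that
total DSB production, (Σ yields)·dose, is a conserved bookkeeping
invariant for all three models; the test suite checks it on randomized
protocols.

## Numerical integration of the nonlinear models

The TLK equations with active interaction terms have no closed form.
Public single-protocol predictions integrate with scipy's LSODA at
relative tolerance 1e−8 / absolute 1e−10 (callers may pass any tolerance
in (0, 1e−4]); dose-rate discontinuities at segment boundaries are
integrator restart points. Inside fitting loops, where a 100-start fit
evaluates the likelihood ~10⁵ times, per-call overhead of the generic
solver dominates; the hot path therefore uses a Dormand–Prince 5(4)
adaptive stepper compiled with numba and looped over all protocols of a
dataset (relative tolerance 1e−6 during fitting). The stepper is
validated against the scipy path to ~1e−6 relative in the unit tests.
The LPL-type model is embedded in the TLK integrator exactly (one
rejoinable class with λ and η; the unrejoinable yield enters as the
direct class-3 yield).

Quadratic interaction events remove both participating DSBs from the
measured pool (they are accumulated as `removed_quadratic`). An
alternative reading — interactions converting DSBs into a different
measured class — would change the TLK equations' interpretation but not
the linear limit that the yeast data actually select (all η → 0).

## Long-time residual and its linear-quadratic split

The number of DSBs left unrejoined at effectively infinite rejoining
time equals the unrejoinable-class content at the end of irradiation
(the rejoinable classes decay to zero whenever v₁, v₂ > 0; if a
rejoinable class has zero rate and nonzero content the residual is
undefined and an error is raised). `rd_residual_lq` returns this
residual together with its linear coefficient α = k₃ and the effective
quadratic coefficient β(D, R) = (residual − k₃D)/D². In the acute limit
(supported as `dose_rate = inf`, solved exactly in the dose domain)
β → k₂q₂/2 at small doses; β → 0 as R → 0 because quickly-rejoinable
DSBs are rejoined before radiation can convert them — the mechanistic
signature that distinguishes this model family from interaction-based
explanations of the dose-rate effect.

## Likelihood, fitting, uncertainty

Measurement error is Gaussian with constant variance; the error scale is
profiled out analytically, giving LL = −(N/2)(ln(SSE/N) + ln 2π + 1).
σ is consequently not counted in K (K = 7 for RD and the
constant-conversion variant, 10 for TLK, 4 for LPL). A proportional-error
variant divides squared residuals by squared observations; it is exposed
but not the default, since it lets low-yield points dominate.

Fitting draws `n_starts` (default 100) initial vectors log-uniformly
from ranges bracketing the plausible magnitude of each parameter kind by
at least two decades each way — yields 1e−4–1 Gy⁻¹, rates 1e−3–10 h⁻¹,
conversion coefficients 1e−6–1e−2 Gy⁻¹, interaction rates 1e−7–1e−3
(h·DSB)⁻¹ — and refines each by SLSQP under non-negativity bounds
(upper caps 10 Gy⁻¹ / 100 h⁻¹ / 0.1 Gy⁻¹ / 1 (h·DSB)⁻¹), with
convergence tolerance 1e−10 on the log-likelihood. Parameters are
internally rescaled to order one (geometric mid-range of their kind) so
finite-difference gradients are well conditioned; parameters the
optimizer leaves within rounding error of zero are snapped onto the
boundary when the likelihood is indifferent. Everything is deterministic
given the seed, and the start sequence is prefix-stable, so increasing
`n_starts` can only improve the best likelihood.

95% confidence intervals use the Monte-Carlo profile-likelihood
criterion: parameter vectors sampled around the best fit are retained if
their log-likelihood lies within χ²₁(0.95)/2 = 1.9207 of the maximum
(1 degree of freedom for per-parameter intervals), and each parameter's
interval is the extent of the retained cloud. The vicinity distribution
is the design choice that the published description leaves open. A naive
axis-aligned box (e.g. ±1 decade per parameter) has essentially zero
overlap with the 7-dimensional likelihood contour — 0 of 10,000 samples
retained in trials — so the sampler instead uses a Gaussian cloud with
covariance from the inverse Hessian of the log-likelihood at the maximum
(finite differences in rescaled coordinates, eigenvalue-clipped to
positive definite), mixing one- and two-sigma scales, plus draws swept
along each parameter's profile ridge (the coordinate swept across the
contour width, the others following a shrunk conditional Gaussian).
Draws are clipped at the non-negativity boundary, so a parameter whose
best fit is 0 gets a lower limit of exactly 0. One adaptive widening
pass (tripled scales) triggers if an interval appears truncated by the
sampling cloud. On synthetic data at the published design this yields
~93% empirical coverage for the six identifiable parameters, consistent
with the slight undercoverage expected from taking extremes of a finite
retained cloud.

## Model selection

AICc (with the small-sample correction) is the sole ranking criterion;
evidence ratios exp(−ΔAICc/2) express relative support, with ΔAICc > 6
(ER < 0.05) read as much poorer support. BIC and F-tests are deliberately
omitted: they either ignore sample size or require arbitrary test-design
choices, and AICc compares non-nested mechanistic models directly.
Absolute goodness of fit is computed per exposure subset (HDR single,
HDR split, LDR single; threshold 100 Gy/h) as R² = 1 − SSE/SStot and an
OLS regression of predictions on observations — predictions as the
response, since the reverse orientation changes the slope — passing when
the 95% CIs contain 0 (intercept) and 1 (slope).

## Synthetic data

The generator emulates the three published exposure designs with grids
inside the printed ranges: sparsely ionizing — single doses {300, 600,
1200, 1800, 2400} Gy at 7800 Gy/h × rejoining times {0, 2, 4, 8, 24, 48,
72} h; split doses {900, 1200, 2400} Gy/fraction × intervals {16, 24,
48} h × times {0, 4, 24} h; LDR {1250, 1650, 2400} Gy at 33 Gy/h × times
{0, 6, 22, 36} h — and densely ionizing {100, 200, 400, 600} Gy at
1400 Gy/h × times {0, 4, 24, 48, 72} h. Observations are model
prediction plus additive Gaussian noise of constant sd (default
2 DSBs/cell, three replicates per condition — sized to resemble the
spread of the published replicate ranges, e.g. a mean of 30.2 with range
24.7–35.6). Negative draws are truncated to zero by default (affecting
~2% of points at the default noise; a redraw mode is available). This
generator realizes exactly the error structure the likelihood assumes —
so passing recovery and selection tests demonstrates the correctness and
power of the machinery under its own assumptions, not robustness to the
digitization error, replicate heterogeneity or non-Gaussian tails real
measurements carry.

Where summaries report a mean with standard error instead of raw
replicates, `expand_mean_se` reconstructs three pseudo-replicates
{m−δ, m, m+δ} with δ = se·√3, which reproduces the reported mean and SE
exactly; `expand_mean_range` does the analogue for reported ranges using
the half-width of the range.

## Problem sizes in the test suite

The acceptance-style tests run the full pipeline at sizes chosen to keep
the default suite fast while leaving the scientific conclusions
unambiguous: solver-vs-oracle agreement on 1000 randomized cases;
parameter recovery and CI coverage on 20 replicate datasets at the full
design (×3 replication, 222 points) with 6-start fits and 10,000 CI
samples; model-selection margins on 20 single-replicate datasets
(74 points) with 4-start fits per model — the observed ΔAICc margins
(~140–320 units) are two orders of magnitude above the >6 decision
threshold, so modest start counts do not affect the outcome.

## Known limitations

* Re-analysis of the original yeast measurements requires the journal
  supplement (no public accession); the corresponding check in the test
  suite reports that the data are unavailable rather than silently
  passing. Published ΔAICc values (217 and 14) are therefore anchored by
  synthetic-data analogues, not recomputed from the source data.
* The exact closed-form expressions for the LQ protraction behaviour at
  intermediate dose rates are not part of the public record; only the
  acute and low-dose-rate limits are treated as contractual and tested.
* Profile intervals from cloud extremes undercover slightly relative to
  the asymptotic 95% target; this is inherent to the published
  Monte-Carlo contour method.
* The multistart optimizer can in principle miss the global maximum for
  the 10-parameter TLK model at small start counts; production fits
  should use the default 100 starts.
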