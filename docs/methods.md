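# Methods

## Decision framework

`voival` addresses a single, concrete decision problem: a risk prediction
model for a binary outcome has been applied to an external validation
sample of `n` subjects, and at a context-specific risk threshold `z` one of
three strategies must be recommended — use the model, treat everyone, or
treat no one. The measure of clinical utility is net benefit (NB) in net
true-positive units per decision,

    NB = P(TP) − P(FP) · z/(1−z),

where the weight `z/(1−z)` encodes the decision maker's harm/benefit
trade-off: a patient whose risk equals `z` is the point of indifference,
so each false positive costs `z/(1−z)` of a true positive. The threshold is
always user-supplied; the package offers no clinical default because none
exists — `z` belongs to the decision context, not to the data.

Ties `π_i = z` are classified positive (the estimator's indicator is `≥`),
and thresholds live in `[0, 1)`; `z = 1` is rejected because the weight is
undefined there. Predicted risks of exactly 0 or 1 are accepted — they
arise from degenerate models and leave every NB formula well defined.

The recommendation under current information goes to the strategy with the
highest *expected* NB (risk neutrality; no irrecoverable switching costs).
Uncertainty does not change that recommendation; it changes the value of
collecting more validation data, and that value is what the package
computes.

## Posterior draws of the net benefits

Both bootstrap flavours are implemented as random observation weights
applied to the per-subject NB contributions:

- ordinary: weights `multinomial(n, uniform)/n` (classic resampling);
- Bayesian: weights from a flat Dirichlet, generated as normalized
  unit-rate exponentials (numerically stable at any `n`).

Under the Bayesian scheme a weighted statistic is a draw from the posterior
of its population counterpart given the sample and a noninformative prior;
the ordinary bootstrap is given the same reading, as is common practice.
Each weight is marginally `Beta(1, n−1)` under the flat Dirichlet — the
test suite checks this, along with the agreement of the two schemes' means.

Two reproducibility choices are fixed and documented rather than left to
chance:

- **Seed contract.** One user seed drives a `SeedSequence`; iteration `b`
  always consumes child stream `b`, regardless of scheme, so a single
  iteration can be re-created in isolation.
- **Shared weights across thresholds.** When a curve over several
  thresholds is requested, iteration `b` reuses the same weight vector at
  every threshold — one bootstrap sample, NBs computed at all thresholds of
  interest — preserving cross-threshold correlation. An
  `share_weights=False` switch draws independently per threshold instead.

Percentile intervals use linear-interpolation quantiles (numpy's default
rule), stated here once so interval dialects are never a source of
irreproducibility.

## EVPI from draws

With draws `(NB_model_b, NB_all_b)`:

    ENB_perfect = mean_b max(0, NB_model_b, NB_all_b)
    ENB_current = max(0, mean_b NB_model_b, mean_b NB_all_b)
    EVPI        = ENB_perfect − ENB_current

The current-information term uses the bootstrap means rather than the
original-sample estimators. This has three consequences: the EVPI is
nonnegative by construction (Jensen's inequality on the same draws, so no
clamping is needed); stochastic components upstream of the predictions
(e.g. imputation) propagate automatically; and prior information could be
folded in by reweighting draws. An `enb_current_from="sample"` option
switches to the original-sample estimators, in which case small negative
EVPIs caused by Monte Carlo noise are clamped to zero with a warning.

`P(useful)` is the fraction of draws in which the model strictly beats
`max(0, NB_all_b)`. Ties count against the model — a conservative reading
("higher than") that also fixes the winner label when expected NBs tie
exactly (treat-none over treat-all over model). The relative EVPI,

    rEVPI = (ENB_perfect − max(0, E NB_all)) / (ENB_current − max(0, E NB_all)),

is reported only when the model is the current winner and the denominator
is positive; otherwise it is `None` rather than a number with no
interpretation.

**Degenerate samples.** At extreme thresholds in small samples the
incremental-NB draws can have zero variance (e.g. no events below the
threshold), yielding EVPI 0 and `P(useful)` 0 or 1. The package emits a
`DegenerateSampleWarning` in this situation: such certainty reflects an
uninformative sample, not strong evidence, and the suitability of the
sample should be reconsidered rather than the output taken at face value.

## Asymptotic method

The estimator pair is approximated as bivariate normal with mean
`(NB̂_model, NB̂_all)` and covariance assembled from the sample proportions
`p0`, `p_tp = P(π ≥ z, Y=1)`, `p_fp = P(π ≥ z, Y=0)` (with `w = z/(1−z)`):

    var(NB_model) = { p_tp(1−p_tp) + w² p_fp(1−p_fp) + 2w p_tp p_fp } / n
    var(NB_all)   = p0(1−p0) / (n (1−z)²)
    cov           = { (1−p0) p_tp + w p0 p_fp } / (n (1−z))

These are exactly the multinomial variances of the two sample means with
plug-in proportions — derivable in two lines from the per-subject
contributions — and the test suite verifies them against the empirical
covariance of ordinary-bootstrap draws (n ∈ {250, 1000}, z ∈ {0.1, 0.2},
3 Monte Carlo SEs). In particular `var(NB_all)` scales as `1/n`, the
sampling variance of a mean of n i.i.d. terms.

The perfect-information term `E[max(0, N1, N2)]` is a bivariate-normal loss
integral, computed two ways that must agree to 1e-9:

- **Reference path:** condition on the wider component; the inner
  `E[max(c, Normal)]` is closed-form, leaving a smooth one-dimensional
  integral evaluated by adaptive quadrature on `[−40, 40]` (the normal
  weight vanishes beyond) with the kink of `max(0, ·)` passed as an
  explicit breakpoint. Forcing breakpoints matters: an adaptive rule on a
  long interval can otherwise step entirely over the integrand's support
  when a truncation point sits far in a tail.
- **Fast path:** a closed form from first moments of rectangle-truncated
  bivariate normals, `E[max(0,N1,N2)] = E[N1; N1≥0, N1≥N2] +
  E[N2; N2≥0, N2>N1]` (note the strict inequality in the second term, which
  prevents double counting when the components are perfectly correlated).
  Zero-variance margins and rank-deficient covariances reduce to analytic
  limits; no jitter is ever added.

Both are cross-checked against a 1e7-draw Monte Carlo oracle and the
analytic value `1/√(2π) + 1/(2√π) ≈ 0.68103` for independent standard
normals. The asymptotic EVPI subtracts `max(0, μ1, μ2)`; a result below
−1e-9 raises an internal-consistency error instead of being silently
clamped, and smaller negatives (pure floating error) are floored at zero.

The asymptotic `P(useful)` — `P(N1 > max(0, N2))` under the fitted normal —
is provided for symmetry with the bootstrap output; it is an extension of
the draw-counting definition to the asymptotic approximation.

Only one candidate model is supported. With M competing models the
perfect-information term becomes an (M+1)-variate truncated-normal
integral with no closed form; the API takes a single risk vector by
construction, so the limitation is structural rather than a runtime check.

## Synthetic data and ground truths

The simulation module emulates a deliberately simple validation scenario:
one standard-normal covariate X, outcomes from
`logit P(Y=1|X) = a + bX` with defaults `a = −1.55`, `b = 0.77` — chosen so
the implied prevalence is 20% and the correct model's c-statistic is 0.70,
values typical of validation studies. The candidate model predicts with
linear predictor `a + shift + bX + ε`, `ε ~ N(0, sd)`: the intercept
`shift` degrades calibration without touching the outcomes, the noise `sd`
degrades discrimination. Both default to zero (the correct-model scenario).
Perturbation magnitudes for miscalibration/noise experiments are free
configuration parameters, not a hard-coded grid.

What the generator does **not** emulate: multiple correlated predictors,
case-mix differences between development and validation populations,
nonlinear effects, missing data, or any model-fitting step. Passing tests
therefore demonstrate the correctness of the VoI machinery under a known
mechanism — not the field behaviour of any particular clinical model.

Population truths are computed by adaptive Gauss–Kronrod quadrature
(absolute tolerance 1e-12 for prevalence and NB, ~1e-9 for the
c-statistic's nested integral) rather than Gauss–Hermite rules, because the
NB integrand lives on a truncated half-line where Hermite nodes are
unsuitable; `p(x) ≥ z` is solved analytically (monotonicity in x) so the
integration region is exact. Degenerate slopes (`b = 0`) are handled in
closed form. Reference values for the default mechanism: prevalence 0.1999…
(20%), c-statistic 0.6987 (0.70), true NB 0.1176 / 0.0574 / 0.0249 at
z = 0.1 / 0.2 / 0.3 — each confirmed by an independent large-sample Monte
Carlo in the tests.

Replicate seeding splits one experiment seed by replicate index
(`SeedSequence(seed, spawn_key=(rep,))`), so any replicate is independently
re-creatable. The EVPI-versus-n experiment reports, per (n, threshold,
method), the mean EVPI across replicates and its Monte Carlo standard
error. The default experiment scale — 200 replicates over
n ∈ {250, 500, 1000, 2000} with B = 1000 bootstrap draws per replicate — is
the package's standard proof-of-concept size; it resolves the decline of
EVPI with n and its diminishing returns well beyond the Monte Carlo noise.
A subsampling variant (`subsample_evpi_experiment`) applies the same design
to an arbitrary user-supplied validation sample, drawing without
replacement on a doubling n-grid; no patient-level dataset ships with the
package.

## Known limitations

- Validation-phase VoI only: no expected value of sample information, no
  development-phase EVPI, no hierarchical/multicenter extensions.
- One candidate model per analysis (see above).
- BCa or studentized bootstrap intervals are out of scope; percentile only.
- The asymptotic method inherits the usual CLT caveats: very small samples
  or thresholds in the extreme tail of the risk distribution push it away
  from the bootstrap answer; the cross-method agreement tests quantify the
  typical gap (within 20% relative, or 1e-4 NB absolute, at n = 500).
- In near-tied regimes (threshold far from prevalence so that model and
  treat-all nearly coincide), EVPI need not vanish even for very large n —
  the decision is genuinely close, and the package reports that honestly
  rather than treating large n as a guarantee of zero value.
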