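# Methods

This note documents the statistical procedures implemented in `cordrbe`,
their assumptions, the defaults and why, and the choices made where the
design was genuinely open.

## Endpoint and data model

The endpoint is radiation-induced myelopathy (paresis grade II, both
forelimbs) within a 300-day follow-up horizon.  An animal record carries
its total physical dose (Gy, over all fractions), an event indicator and
a time in days: onset day for responders, last observation day otherwise.
Excluded animals (intercurrent tumours, deaths unrelated to the
endpoint) are retained in the file model for audit but removed from the
analysable counts.  Dose groups are formed by exact dose match — these
studies use distinct listed dose levels, so no tolerance binning is
applied.  Control (0 Gy) groups are permitted and simply contribute a
zero-dose binomial term to the likelihood.

## Actuarial correction (effective sample sizes)

Animals censored before the horizon (death or sacrifice without paresis)
carry partial information.  The survivor function of the toxicity event
is estimated by the product-limit (Kaplan–Meier) method with responders
as events at onset and everything else censored at last observation; the
actuarial response probability is `p = 1 − S(300 d)` with Greenwood's
variance, which is identical for `p` and `S`.  Raw counts are then
replaced by

    n_eff = p(1 − p)/Var[p],   r_eff = n_eff · p,

capped at `n_eff ≤ n_raw`: the correction models information loss, never
gain.  With complete follow-up the Greenwood variance equals the
binomial variance and the correction is exactly the identity, a property
the tests verify end-to-end against the simulator.  Degenerate rates
(p = 0 or 1) and zero-variance cases fall back to raw counts.  Greenwood
is the variance estimator throughout; the product-limit estimate at the
horizon is flagged "immature" when the largest observation is a
censoring time before 300 d.

Competing risks and interval censoring are out of scope: non-toxicity
deaths are treated as independent censoring, the standard actuarial
convention for toxicity endpoints.

## Dose-response fitting

Grouped binomial maximum likelihood with a logistic link (probit
available as an option; TD50 = −b0/b1 under either, and near the 50%
point the choice is immaterial).  Real-valued effective counts enter the
likelihood directly as weights — the fit is solved by iteratively
reweighted least squares, which is deterministic and needs no starting
values.  The TD50 standard error uses the delta method with the full
(b0, b1) covariance; 90% confidence limits apply Fieller's theorem to
the ratio −b0/b1 with a z-quantile (1.645).  A z rather than t quantile
is used because the effective-sample-size correction leaves no
well-defined degrees of freedom.

Degenerate response patterns are handled explicitly:

- **Complete separation** (every group at 0% or 100%, zeros strictly
  below fulls): the slope is unbounded; TD50 is reported as the midpoint
  of the bracketing doses and the SE by the fallback rule below.
- **Quasi-separation** (one partial group inside an otherwise pure
  pattern): the fit converges but the slope likelihood is nearly flat
  and the delta-method SE loses meaning.  When the SE exceeds the
  experiment's whole dose range, the fallback SE is reported instead,
  flagged `se_estimated`, with no confidence limits.
- **All-responder / all-nonresponder data**: unidentifiable, an error.

The **fallback SE rule** is 25% of the dose difference between the
neighbouring 0% and 100% observed response levels; if those levels
overlap in dose, the adjacent pair of doses where the observed response
crosses 50% is used instead; equal adjacent doses are a degenerate error.

`fieller_cl(num, se_num, den, se_den, cov, level)` implements the exact
normal-theory limits for a ratio, including the correlated case used for
TD50.  When `g = (z·se_den/den)² ≥ 1` the denominator is compatible with
zero and the sentinel `(−inf, +inf)` is returned.  The limits match the
Monte-Carlo quantiles of a simulated ratio of correlated normals to
better than 0.005 (tested at 10⁶ draws).

## Linear-quadratic isoeffect analysis

TD50s at several fraction numbers jointly determine the fractionation
parameter α/β and the biologically effective dose at 50% complication
probability, BED50.  The fit minimises weighted residuals on the TD50
(dose) scale: for trial (BED50, α/β) the predicted tolerance dose at n
fractions is n times the positive root of `d(1 + d/(α/β)) = BED50/n`
(computed in rationalized form for numerical stability at large α/β),
with weights 1/SE².  Fitting on the dose scale — rather than the
reciprocal-dose Fe-plot scale — uses the reported TD50 errors directly
as weights; the reciprocal fit is provided as a cross-check option and
agrees exactly on noiseless inputs, where both recover the generating
parameters to better than six significant digits (the Fe-plot regression
also supplies the starting values, so the noiseless start is already the
optimum).

The parameter covariance is `(JᵀJ)⁻¹` at the optimum, treating the
weights as true inverse variances (no residual rescaling — with two
schedules the system is exactly determined and the SEs are pure error
propagation).  90% limits for α/β and BED50 use a log-scale delta
construction, giving the right-skewed asymmetric intervals these
positive parameters require.  BED50 SEs therefore come from the joint
fit's covariance, consistent with propagating correlated parameters
downstream.  Complete repair between daily fractions is assumed; no
repopulation or incomplete-repair extensions.

## RBE estimation

RBE at fixed fraction number is the photon/carbon TD50 ratio; RBE_max is
the photon/carbon BED50 ratio.  Photon and carbon arms are independent
cohorts and beams, so the cross-covariance is zero; the *within*-fit
correlations (b0 with b1, α/β with BED50) are what the delta method
propagates.  SEs use first-order propagation; confidence limits use
Fieller.  The dose dependence interpolates by per-fraction isoeffect:
the photon fraction matching `RBE_max · d_C (1 + d_C/(α/β)_C)` is the
positive root of the photon LQ quadratic, and RBE(d) = d_x/d_C, which
tends to RBE_max at vanishing dose and to
`sqrt(RBE_max · (α/β)_x/(α/β)_C)` at large doses.  A helper computes the
model-side RBE_max as the ratio of LQ α coefficients, the convention
model tables report.

## Model benchmarking

Percent deviation is `100·(RBE_model − RBE_exp)/RBE_exp` at matched
(LET, fraction-number) keys — the experimental value is the denominator
because the model is benchmarked against measurement, and an
underestimating model yields negative deviations.  Region averages are
the arithmetic mean ± sample SD (n−1) over the entrance (16, 21 keV/μm)
or SOBP (36, 45, 66, 99 keV/μm) points; the aggregation axis (over LET
at fixed fraction number, or over fraction numbers at fixed LET) is a
parameter.  A single-point region reports SD 0.

The RBE-vs-LET slope ratio defaults to straight-line OLS slopes over the
four SOBP points with the ratio SE by propagation; a second-order
polynomial derivative and an endpoint difference quotient are provided
as alternatives, since the defining construction is ambiguous — none of
the three is asserted as the canonical one.  α/β versus LET is a
weighted (inverse-variance) straight-line regression.

## Synthetic cohorts

The generator emulates the study design: per-animal Bernoulli response
with logistic probability `1/(1+exp(−b1(D − TD50)))`, lognormal onset
latency with log-median decreasing linearly in (dose + LET) —
`median_days = 230·exp(−0.002·(D + LET))`, σ_log = 0.30, giving medians
of roughly 150–250 days — truncated by resampling to the 300-day
horizon; non-responders censored at the horizon; independent dropout
with probability 0.02 censored uniformly over follow-up.  Each
experiment draws from its own RNG stream keyed on (seed, experiment id),
so adding experiments never perturbs existing ones and equal seeds give
byte-identical cohort files.

`make_study_replica` instantiates the full six-fraction design: six
carbon arms with the published dose grids, LETs, depths and animal
totals (37/30/20/30/55/32, distributing the extra animals beyond groups
of five to the lowest dose levels), with the published TD50s as ground
truth and logistic slope 1.8 Gy⁻¹ (steep enough that the listed grids
span roughly 1–99% response, as the designs intend), plus a photon
reference arm (TD50 57.0 Gy) on a 50–65 Gy grid in 3-Gy steps with a
shallower slope of 0.6 Gy⁻¹, reflecting the wider photon dose range.
The replica reproduces the *statistical* structure the inference
assumes — binomial dose response, right-skewed latencies, sporadic
censoring.  It does not emulate biology the analysis never touches
(acute skin toxicity, weight loss, histology) nor any deviation from
the logistic form, so passing recovery tests demonstrate correctness of
the inference chain under its own model, not the model's adequacy for
real cords.

Problem sizes used in the recovery tests — 100 seeded replicas of the
relevant arms, cohorts of 20–55 animals — match the study's own scale,
which is the regime of interest for the small-sample behaviour
(quasi-separation, fallback SEs) the tests exercise.

## Numerical choices

- Quadratic roots for the LQ inversions use the rationalized form
  `2b/(1 + sqrt(1 + 4b/ab))` to avoid cancellation at small doses/large
  α/β.
- Cohort CSVs are parsed with round-trip float precision so
  read → write → read is byte-exact.
- Identical doses across groups are pooled before fitting; group doses
  within an experiment must otherwise be strictly increasing.
- Greenwood variance is capped at 0.25, the Bernoulli maximum.
- JSON output carries full-precision values plus a display block rounded
  to two decimals; non-finite numbers serialize as null with an explicit
  `se_estimated` flag distinguishing "estimated by rule" from "absent".

## Known limitations

- The actuarial variance follows Greenwood; the historical
  effective-sample-size literature does not pin down the estimator, and
  a different choice would shift n_eff slightly in censored groups.
- Log-scale delta intervals for α/β and BED50 are first-order; profile
  likelihood would be preferable very close to unidentifiability.
- The latency model affects only censoring patterns, not the fitted
  dose-response parameters, and is calibrated qualitatively (decreasing
  trend, right-skewed) rather than to any latency dataset.
- LEM-style RBE prediction itself is out of scope: model predictions
  enter only as user-supplied tables.
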