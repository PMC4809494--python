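# Methods

## Scope and model

`fdperf` models objective performance under forced desynchrony (FD) as a
nonlinear function of four explanatory variables measured at each paired
testing session: subjective alertness `A` (VAS, 0–100), circadian phase `C`
(degrees, 0° at the fitted melatonin maximum, increasing with time), wake
duration `T` (hours since scheduled wake), and sleep debt `W` (hours). The
response `P` is the natural log of the PVT session mean reaction time in
ms, or the untransformed ADD/DSST correct count. The composite drive is
`X = A + b6·cos(C + b7) + b8·T`, and the three forms (linear, exponential,
logistic in `X`, each gated by the gain `b2·W + b3`) are as printed in the
README. The log transform uses the natural logarithm; any base change is
absorbed by the coefficients.

Key modelling assumptions: Gaussian residuals on the `P` scale; the
alertness term enters `X` with a coefficient fixed at 1 when included and 0
when excluded, so excluding a variable means pinning its coefficient at
zero, never re-estimating a free alertness weight; sleep debt is computed
from *scheduled* sleep opportunity (time in bed), not realized sleep,
because field deployments can observe opportunities but rarely true sleep.

## Protocol accounting

Time is decimal hours since FD start; wake/sleep episodes are half-open
`[start, end)`. Sleep debt is piecewise linear: slope `1 − 16/24` during
scheduled wake and `−16/24` during scheduled sleep, giving
`k·(wake_per_day − (2/3)·day_length)` at day boundary `k` — ≈ 0 for the
Control schedule (28.57/14.28) and +4.283 h per day for CSR (32.85/10),
51.4 h after twelve days. Adverse/optimal windows are closed intervals as
conventionally defined (phase −30°–90° / 150°–270°; time awake 20–28 h /
2–10 h); boundary values classify into the named window. Test batteries
are timestamped at battery start; the first battery falls 2 h after
scheduled wake, ADD/DSST repeat every 2 h, PVT every 2 h (Control) or 4 h
(CSR), VAS every 30 min, melatonin hourly around the clock. Baseline
(pre-FD) days contribute no events or debt. The Control protocol runs 14 FD
days in the lab but only 12 are analysed, so its spec carries `n_days=12`
for parity with CSR.

## Phase estimation

The reference method for melatonin phase/period in these protocols is a
non-orthogonal spectral decomposition; this package deliberately replaces
it with a grid-search cosinor, because the downstream pipeline needs only
(i) the free-running period and (ii) the time of the fitted maximum. For
each period on a grid (default 23.5–25.0 h, step 0.01 h — the step bounds
the attainable precision) a linear harmonic regression with the fundamental
plus two higher harmonics is fitted; the minimum-RSS period wins, and the
fitted curve's maximum nearest the series start (located on a 0.002-h grid
with quadratic refinement) anchors 0°. The two extra harmonics matter
because the synthetic melatonin waveform is a *rectified* cosine, which has
substantial harmonic content. Fewer than 3 cycles of data, or a flat
series, raise errors rather than returning a degenerate fit. With 12 FD
days of hourly samples and noise at 20% of amplitude, the period error
never exceeded 0.05 h across 100 seeded replicates (median 0.01 h).

## Pairing and binning

Each objective test takes the single VAS rating within 45 min that
minimizes the separation; ties go to the *earlier* rating, on the view that
the rating preceding a test better reflects pre-test self-assessment (the
choice is ours; nothing downstream is sensitive to it at the generator's
cadences, where ratings coincide exactly with battery starts). One rating
may serve PVT, ADD and DSST from the same battery, since the battery is a
single 25-min session. Alertness bins use empirical quantiles with linear
interpolation; values tied with an interior edge fall to the lower bin.
Published quintile cut-offs are data-dependent and are not reproduced;
quintile-level statistics on the reference table merge adjacent decile rows
(rows 1–2 vs 9–10).

## Fitting

Fixed-effects fits are nonlinear least squares with a Gaussian likelihood
(`σ²` at its MLE). Two numerical choices do most of the work:

* **Variable projection.** `b1`, `b2`, `b3` enter linearly given the link
  values, so they are profiled out by least squares at every objective
  evaluation; the optimizer searches only the genuinely nonlinear
  parameters (at most five).
* **Linear circadian parameterization.** `b6·cos(C + b7)` is fitted as
  `bc·cos C + bs·sin C` and converted back to amplitude/phase with
  `b6 ≥ 0`, `b7 ∈ [0, 360)`, removing the (b6, b7) sign ambiguity and the
  wrap-around boundary.

Multi-start uses two data-driven initial points (sign-matched to the
response/drive correlation) plus Latin-hypercube draws over documented
boxes; 20 starts by default, fewer in the large simulation sweeps where the
profiled objective is benign (the suite's oracle test checks the optimizer
against an iteratively refined brute-force grid on a reduced 3-parameter
problem, agreeing to 1e-6). The exponential link's exponent is clipped at
±50. When alertness is excluded, the scale of `X` is unidentified against
the gain/link, so one parameter is pinned (linear: `b3 = 1`; exponential:
`b4 = 1`; logistic: `b5 = 1`) and only genuinely free parameters are
counted in `k`. When `X` has no terms at all the model collapses to an
intercept (plus a `W` slope for the exponential/logistic forms when sleep
debt is included) and is fitted in that reduced form. Phase-only subsets
remain weakly identifiable by construction; non-convergence is reported
honestly (`converged=False`, `AIC = +∞`) rather than forced.

Mixed-effects fits place subject offsets on `b1` and `b3` by default
(configurable among `b1`, `b2`, `b3`, whose random-effect columns are
analytic). The algorithm alternates a first-order linearization of the mean
function around the current fixed-effect estimates with a linear
mixed-model step (statsmodels `MixedLM`, ML), in the spirit of
Lindstrom–Bates; the reported log-likelihood is the marginal likelihood of
the final linearized model — a first-order approximation, which is the
same order of approximation classical nonlinear mixed-effects software
uses. Conditional (BLUP-corrected) residuals feed the adjusted R². A
near-singular random-effect variance triggers a warning and a fall back to
the fixed-effects fit.

`AIC = 2k − 2·log L` with `k` counting free mean parameters, the residual
variance, and (for mixed fits) the random-effect covariance parameters.
Adjusted R² is `1 − (1 − R²)(n − 1)/(n − p − 1)` with `p` the number of
mean parameters beyond the intercept, so an intercept-only model scores ≈ 0
and a perfect fit scores 1. Whether the mixed-model AIC should use a
marginal or conditional likelihood is genuinely open; we use marginal (ML)
and note that subset rankings, not absolute AIC values, are the quantity of
interest.

## Synthetic cohort

The generator's defaults are the study conditions: 8 Control + 9 CSR
participants, intrinsic periods ~N(24.2, 0.1²) truncated to (23.5, 25),
initial phase ~N(60°, 20°) — the melatonin maximum ≈ 4 h before the first
scheduled wake, matching a ~3 am peak for habitual 11 pm–7 am sleepers.
Melatonin is a rectified cosine (amplitude 10, noise SD 2, i.e. 20%);
alertness is built from circadian (amplitude 10, trough at the melatonin
maximum), wake-duration (−0.7/h) and sleep-debt (−0.35/h) terms around a
baseline of 85, with 5-point subject and residual SDs, clipped to [0, 100]
— rested means in the 70s–80s, worst-case adverse sessions in the 20s–40s,
mirroring the descriptive pattern of such protocols. Performance comes
from the logistic model with generating values `b1=5.7` (log 300 ms floor),
`b2=0.02`, `b3=1.0`, `b4=5`, `b5=−0.08` (sigmoid switching across the
alertness range), `b6=10`, `b7=180°` (performance worst at the melatonin
maximum), `b8=−0.5`, residual SD 0.2 on `P`, and subject SDs 0.15 on `b1`
and `b3`. PVT sessions expose `exp(P)` ms as the session mean plus a
90-trial lognormal reaction-time stream (shape 0.35) that supplies the
session SD and the >500 ms lapse count from one source; ADD/DSST counts are
Poisson with mean `max(0, 130 − 12·P)`. One master seed drives everything;
per-participant substreams derive from `SeedSequence.spawn`.

What the generator does *not* emulate: light-driven melatonin suppression,
sleep inertia, practice effects, missing data, and any guarantee that the
authors' real data-generating process looked like this. Passing tests
therefore demonstrate that the pipeline recovers what this structure puts
in — identifiability, selection consistency, estimator accuracy — not that
the published real-data coefficients are correct.

For simulation studies the generator also offers a fast path
(`sample_design` / `simulate_paired_dataset`) that draws battery-like
design points directly (uniform over wake episodes on a 0.5-h grid, 2 h
after wake onward) instead of walking the full event schedule; the
simulation studies in the test suite use it with 17 subjects × 300
observations (parameter recovery) and × 100 observations (AIC sweeps),
sizes chosen to match the paired-session volume such protocols produce
while keeping 100-replicate studies comfortably fast.

## Lapse and mean–SD analytics

Contingency expected cells are always recomputed from marginals
(`row·col/N`), never taken from rounded sources; χ² is the Pearson sum with
`(r−1)(c−1)` degrees of freedom. The relative-risk interval is the Katz
log-normal interval; on the packaged reference counts it gives
(1.545, 1.751), wider than the interval published alongside those counts
(1.56–1.72) — the published method is unstated, so we print ours and flag
the difference rather than reverse-engineer theirs. The lapse threshold is
a strict `RT > 500 ms`. The mean–SD cubic is linear in its coefficients, so
ordinary least squares replaces iterative least-squares with an identical
minimum; over the narrow observed log(ms) range the raw-power coefficients
are highly collinear, so the package's guarantee (and test) is recovery of
the fitted *curve*, not of individual coefficients. The reference table's
last two row labels overlap in their printed alertness ranges; bins are
defined by the percentile labels.

## Known limitations

* The cosinor stand-in is not the spectral method used on real data;
  equivalence cannot be asserted, only that both deliver a period and a
  peak.
* The first-order linearized mixed likelihood can bias variance components
  at small subject counts; recovery tests show subject-intercept SDs within
  ~25% at 17 subjects.
* Phase-only model subsets are weakly identified; treat their AIC entries
  as diagnostics, not estimates.
* Real-data descriptive statistics (published adjusted R², AIC magnitudes,
  ms means) are not reproducible without the undeposited raw data and are
  deliberately not targets of the test suite.
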