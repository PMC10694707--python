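# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `cpdomains`.

## The power–duration model

For constant work rates above critical power, time to exhaustion is
modelled as the two-parameter hyperbola

    t = W' / (P − CP)

with CP (W) the asymptote — the highest work rate with an attainable
physiological steady state — and W' (J) the finite work capacity above
CP.  Four estimators of (CP, W') are provided:

| method         | form                         | estimator |
|----------------|------------------------------|-----------|
| `work_time`    | W = CP·t + W'                | OLS of total work on time |
| `inverse_time` | P = CP + W'·(1/t)            | OLS of power on 1/time |
| `hyperbolic`   | t = W'/(P − CP)              | nonlinear least squares, time-domain residuals |
| `two_point`    | exact 2×2 solve (work–time)  | lowest- and highest-power trials |

Design choices:

* **Residual axis of the hyperbolic fit.** Trials fix power and measure
  time, so time is treated as the response.  `residual_axis="power"` is
  available; note that power-domain residuals are linear in 1/t, so that
  option coincides with the inverse-time OLS solution.
* **Initialisation and convergence.** The NLS starts from the work–time
  OLS estimate (exact on noiseless data), uses a trust-region reflective
  solver with `xtol = ftol = gtol = 1e-14`, and constrains
  CP ≤ min(P) − 1 W (the asymptote must sit below every observed work
  rate).  A solution on that bound is flagged (`constraint_active`).
  There are no random restarts; fits are deterministic.
* **Parameter uncertainty.** Standard errors come from the usual OLS
  formulas for the linear forms and from the local curvature
  (J'J)⁻¹·RSS/(n−2) at the NLS optimum.  "SEE" is reported as the SE of
  each parameter as a percentage of its estimate, separately for CP and
  W'; the two-point solve has no residual degrees of freedom and reports
  none.  With the standard three-trial protocol the residual degrees of
  freedom are 1, so individual SEE values are themselves very noisy —
  see Calibration below.
* **Singularity.** All trials sharing one Tlim (linear forms) or one
  power (hyperbola) raises a singular-fit error; two trials raise an
  error directing to the two-point model.

Predicted Tlim at a supra-CP work rate is always W'/(P − CP), whichever
estimator produced the pair; prediction at or below CP is an error
(exhaustion time is unbounded there).

## Gas exchange and the domain boundary

Breath-by-breath VO2 is averaged into 5-s bins anchored at exercise
onset (empty interior bins are filled by linear interpolation; empty
leading/trailing bins dropped), and the 15-s peak is the maximum mean of
three consecutive bins.  Windows start at bin boundaries; arbitrary
offsets can be emulated by shrinking the bin width.  Incremental-test
PPO credits a partial final stage pro rata:
PPO = P_prev + ΔP · t_final/180 s.

The severe/extreme boundary is operationalised by VO2max attainment.
The composite VO2max reference is the mean of the highest VO2 peaks
from the incremental and the three predictive trials; its sample SD
(n − 1 — conventional for small repeated measures) is the
intraindividual SD.  A bout attains VO2max when its 15-s peak is at or
above mean − SD (inclusive; a 1e-9 relative tolerance absorbs
floating-point round-off in the bin averaging).  The protocol starts at
125% PPO and steps ±5 percentage points of PPO after an
attained/non-attained bout until an adjacent pair brackets the
boundary; I_HIGH is the highest attained power and I_HIGH+5% the
smallest tested power above it.  Attainment uses the trial-wide peak
("reached", not "maintained"); non-monotone attainment patterns are
flagged, not rejected.  Whether the first extreme intensity should be
1.05 × I_HIGH or I_HIGH + 5% of PPO is not settled by the protocol
definition; the grid anchor and step are configuration, and the
grid-step convention (+5 points of PPO) is the default.

## Agreement analysis

Differences are predicted − actual (positive bias = overestimated
tolerance).  Limits of agreement use the fixed 1.96 multiplier on the
sample SD of differences, not a t-quantile.  Percent mode divides each
difference by its pair mean (the Bland–Altman convention) before
summarising.  Heteroscedasticity is assessed by regressing raw
differences on raw pair means: Pearson r with a Fisher-z 95% CI and a
two-sided p, classified heteroscedastic at p < 0.05, with |r| bands
0.3/0.7 labelling small/moderate/large.  Zero variance on either axis
gives a degenerate (r = 0, p = 1) result rather than an error.

A caution inherent to this regression: if the two measurements have
unequal error variances, difference and mean correlate even without any
true dispersion trend.  In the synthetic pipeline the prediction error
(≈8–10%) exceeds the trial-to-trial error (CV 5%), which measurably
inflates the null flag rate to ~7.5% at n = 19 (600-replicate
measurement).  Interpret lone borderline p-values accordingly.

## Group statistics

One-way within-subject ANOVA uses the classical sums-of-squares
decomposition with the Greenhouse–Geisser epsilon computed from the
double-centered condition covariance; corrected (fractional) degrees of
freedom are ε(k−1) and ε(k−1)(n−1).  Huynh–Feldt is available behind a
flag; the correction itself is verified against an independent
implementation in the test suite.  Under a true spherical null at the
study-like 19 × 5 shape the GG-corrected test rejects at ~4.1%
(10,000-table measurement) — mildly conservative, as expected.

Post hocs are paired contrasts whose SEs come from each contrast's own
difference scores (robust to sphericity violations).  Tukey adjustment
maps q = √2·|t| through the studentized-range distribution with k
groups and n − 1 df.  Dunnett many-to-one adjustment evaluates
P(max|T| ≥ |t|) by seeded Monte Carlo (default 10⁵ draws) over a
multivariate-t null with the contrast correlation estimated from the
data; a single comparison uses the exact paired-t p, and adjusted p is
floored at the unadjusted p.  The seed is recorded in the output.

## The synthetic cohort generator

The generator reproduces the data *structure* of a 19-cyclist study:
CP 213 ± 38 W, W' 19.4 ± 5.4 kJ, VO2max 3.75 ± 0.41 L·min⁻¹, body mass
77.8 ± 6.2 kg (independent truncated normals), incremental stages of
0.5 W·kg⁻¹ every 180 s, predictive trials at 95/100/110% PPO, boundary
search from 125% PPO in 5-point steps on a 100–160% grid.

Mechanisms and defaults:

* **Exhaustion times.** t = usable W'/(P − CP) × lognormal(1, CV).
  Multiplicative lognormal noise (default CV 5%, a realistic day-to-day
  variability for exhaustion tests) keeps times positive and roughly
  proportional.  Above the true boundary, usable W' falls short
  linearly: usable = W'·max(0, 1 − k(P − i_high_true)/i_high_true),
  default k = 0.5.  This is an explicit minimal modelling choice that
  produces overestimation of extreme-domain tolerance by severe-domain
  estimates; it is not a measured physiological law.  Because the
  shortfall fraction depends on the grid offset and not on the
  athlete's exhaustion time, it produces only a weak difference-vs-mean
  correlation (r ≈ 0.05 at k = 0.5) — far weaker heteroscedasticity
  than real extreme-domain data display.
* **VO2 traces.** VO2(t) = baseline + A_p(1 − e^(−t/τ)) + SC(t), with
  A_p = min(0.0103·P, 0.92·(VO2max − baseline)) and a slow component
  rising linearly after a delay at rate sc_gain·(P − CP)/60, capped at
  the attainable plateau.  τ defaults to 25 ± 4 s, delay 60 ± 10 s.
  The attainable plateau varies between bouts with CV 4% (`vo2_day_cv`,
  matching the reported intraindividual SD of VO2 peaks); additive
  Gaussian noise (SD 0.2 L·min⁻¹) models breath scatter at ~1.5-s
  sampling.  For severe bouts the SC slope is raised, when needed, so
  the trace reaches the day's plateau ≥ ~20 s before exhaustion; for
  extreme bouts the trace is capped 0.25 L·min⁻¹ below it (the reported
  VO2 gap at the first extreme intensity).  These construction
  guarantees make the attainment criterion exact on noiseless traces;
  with `sc_gain = 0` the trace is the pure mono-exponential and no
  guarantee applies.
* **Incremental test.** A W'-balance drains at (P − CP) during supra-CP
  stages; exhaustion occurs at zero balance and PPO interpolates the
  partial final stage.  For the mean athlete this yields PPO ≈ 283 W
  and predictive-trial times of ≈ 347/275/196 s — a somewhat faster
  cohort profile (CP/PPO ≈ 0.75) than typical published groups
  (≈ 0.78), a direct consequence of full-W'-depletion accounting with
  long stages.  Because the predictive powers sit close to CP, CP
  sampling error is quite sensitive to this ratio: at CV 5% the pooled
  median |CP error| is ≈ 6 W here versus ≈ 4.8 W for a 0.78-ratio
  cohort.
* **True boundary.** i_high_true = ratio × PPO with ratio ~ N(1.27,
  0.03) truncated to [1.10, 1.50], matching the reported I_HIGH/PPO of
  ≈ 1.26.
* **Randomness.** Everything flows from one seed; per-athlete
  substreams are spawned from (seed, athlete index), so cohorts are
  reproducible and studies byte-identical across runs.

What the generator does **not** emulate: correlated physiology (CP, W',
VO2max and mass are drawn independently), pacing or cadence effects,
plateau-detection subtleties, heart rate, ventilation, lactate, W'
reconstitution kinetics, or any duration-dependent component of the
extreme-domain shortfall.  Passing tests on this cohort therefore
demonstrate correctness of the estimators, protocol logic and
statistics under the stated mechanisms — not physiological fidelity
beyond them.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run (sizes chosen to keep
Monte-Carlo error small against the quantity of interest):

* exact recovery and two-point equivalence (1000 random pairs, 1e-9);
* hyperbolic NLS versus a 0.01-W CP grid search with closed-form W';
* parameter recovery over 200 cohorts of n = 19 at CV 5% (pooled median
  |CP error|), and SE calibration over 500 refits at a fixed design —
  where the mean reported SE understates the empirical SD by ~30%, the
  expected behaviour of a 1-df residual variance estimate
  (E[s] ≈ 0.80σ) on heavy-tailed estimates; the root-mean-square SE is
  within ~10–20%;
* shortfall-mechanism detection and null calibration over 200 replicate
  studies per condition;
* GG null calibration over 3000 (test) / 1000 (script) tables of 19×5;
* exact boundary recovery on a noiseless 50-athlete cohort.

## Known limitations

* Only complete-case repeated-measures tables; no mixed models or
  between-subject factors.
* No three-parameter or exponential power-duration models, no
  time-trial CP, no W'-balance reconstitution.
* With day-to-day VO2 variability enabled, boundary placement is noisy:
  I_HIGH occasionally lands one grid step off the true boundary, and a
  bout above the true boundary can be misclassified severe on a
  high-plateau day (this also lets single-study biases at I_HIGH come
  out positive even though the cohort-average bias there is near zero).
* Report rounding (integer W, 0.1 s, 0.1 kJ) applies to the summary
  tables only; machine-precision values are preserved in the CSV
  outputs.
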