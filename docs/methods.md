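# Methods

This note documents the models, conventions and design choices behind
`temprhythm`, in the spirit of a model-description appendix: what is
assumed, what the defaults mean, and what the tests do and do not show.

## Data model and preprocessing

A channel is a regular-grid `EpochSeries`: strictly increasing timestamps
whose spacings are integer multiples of the epoch length (whole-day gaps
are allowed after exclusion), values, and a per-epoch wear flag. Days are
calendar days, midnight to midnight; the day convention matters because
non-wear exclusion operates on whole calendar days.

Temperature arrives at 30-s epochs and is aggregated into 15-min bins by
arithmetic means; a bin containing any non-wear epoch is flagged non-wear,
and a trailing partial bin is dropped. Any day containing a non-wear epoch
is excluded in full — wrist devices read unreliably low for a stretch
after they are put back on, and day-level exclusion is the robust way to
keep such stretches out of the rhythm estimates. Partial first/last days
(device started or stopped mid-day) are treated as incomplete and dropped
before the inclusion rule. Subjects need at least 2 complete days
(`min_days=2`); a 5-day rule is available for sensitivity analyses.
"Complete" means every epoch of the day present and worn; the stricter
reading was chosen over tolerating missing bins because the folded-profile
metrics (M5/L10, IS) silently change meaning on ragged days.

Non-wear *detection* is out of scope: wear flags arrive on input, from the
generator or an upstream device pipeline. A naive heuristic
(`flag_low_temperature`: ≥ 3 consecutive bins below 20 °C) is provided for
data without flags but is off by default.

The folded 24-h profile averages values across days at each bin of the
day, on the 15-min grid. No interpolation to finer grids is performed —
moving windows use whole bins (20 bins = 5 h, 40 bins = 10 h) — so the
profile never pretends to resolution the aggregated data does not have.

## Cosinor

The single-cosinor model `Y(t) = M + A·cos(2πt/24 + φ)` is fit by ordinary
least squares on the linearization `Y = M + β·cos(ωt) + γ·sin(ωt)`,
`ω = 2π/24`, with `A = √(β² + γ²)` and `φ = atan2(−γ, β)`. The period is
fixed at 24 h; no harmonic terms and no period estimation.

Phase conventions: φ is wrapped to (−2π, 0], so a peak after midnight has
negative phase (φ = −1.45 rad pairs with a ~05:33 peak); the boundary is
snapped so that a midnight peak reports φ = 0, not −2π. Acrotime is
`((−φ) mod 2π)·24/(2π) ∈ [0, 24)`. When the fitted amplitude is below
1e-8 the phase is undefined and reported as NaN rather than 0 — averaging
spurious zero phases would bias group summaries. Where subject-level
acrophases are summarized per group, clock times are averaged circularly
(vector mean), never arithmetically.

Per-subject parameters are estimated from the day-averaged 15-min profile;
fitting the raw multi-day series instead gives identical estimates on
complete days (same projection) and both entry points are exposed.
Goodness of fit (R² = 1 − SSres/SStot, RMSE, MAE in °C) is reported
against the multi-day 15-min series, which is the honest scale — the
profile fit alone looks deceptively clean because day-averaging has
already removed most noise.

The group model adds group-specific (M, β, γ) and a subject random
intercept, fit by REML (statsmodels MixedLM):

    Y_ij(t) = Σ_g 1[g(i)=g]·(M_g + β_g cos ωt + γ_g sin ωt) + u_i + ε_ij

Only a random intercept is modeled (no random amplitude/phase); with
richer subject heterogeneity the fixed-effect SEs for amplitude and phase
are therefore conditional, not population-level — a known limitation.
Derived per-group amplitude/acrophase and pairwise contrasts carry
delta-method standard errors. The pipeline feeds the mixed model the
per-subject folded profiles (one balanced 96-bin curve per subject), which
keeps the random-intercept structure honest and the fit fast; fitting all
epochs is possible through the same entry point. The L-BFGS optimizer
degenerates when the random-effect variance collapses to zero (infinite
restricted likelihood), so the fit falls back through BFGS and Powell and
accepts the first finite solution.

## Non-parametric metrics

With p bins per day (hourly by default; the bin width is configurable and
logged), `x̄_h` the across-day mean at bin-of-day h and `x̄` the grand mean:

    IS = ( Σ_h (x̄_h − x̄)² / p ) / ( Σ_i (x_i − x̄)² / n )

IS is the fraction of variance explained by the average 24-h pattern:
1 for perfectly replicated days, undefined (NaN) for a constant series.

IV is the normalized mean squared successive difference. Differences are
taken within each contiguous block of retained days — transitions across
an excluded day are skipped, since such a jump is an artifact of exclusion
— and each block is **closed circularly** (its last bin is also differenced
against its first, which is clock-adjacent when blocks are whole days):

    IV = ( Σ_pairs Δx² / m ) / ( Σ_i (x_i − x̄)² / n )

The circular closure is this package's convention: it makes IV exactly
unbiased on periodic signals — a noiseless hourly 24-h cosine gives
IV = 4·sin²(π/24) ≈ 0.068 exactly, an alternating series exactly 4 —
where the open-ended sum carries an O(1/n) finite-sample distortion.
White noise still gives IV → 2. Note IV is not mathematically bounded by
2; the familiar 0–2 range is empirical.

M5/L10 are the extreme 5-h/10-h circular moving means of the folded
profile (wrap-around midnight enabled); ties are broken at the earliest
clock start, and window midpoints are reported as clock hours.
RA = (M5 − L10)/(M5 + L10) is scale-invariant but *not* offset-invariant —
it is meaningful on the °C scale it is computed on and is undefined
(NaN) when M5 + L10 ≤ 0.

## Sleep-wake metrics

Efficiency = 100 × (asleep epochs / in-window epochs), averaged over
nights. Duration is mean asleep hours per night; the midpoint is the
circular mean of nightly window midpoints (23:00 and 01:00 average to
midnight, not noon — the convention here, since an arithmetic mean is
simply wrong across midnight).

SRI = −100 + 200·P̂, with P̂ the fraction of epoch pairs exactly 24 h
apart in the same sleep/wake state, on the input state grid (1-min
default). Pairs spanning a missing day are skipped, and the metric is
withheld (with a reason, never silently zeroed) below 5 overlapping days.

M10 onset is the start clock time of the most active 10-h circular window
of the folded activity profile, earliest-onset tie-break — consistent with
the M5/L10 treatment of temperature. MVPA counts 1-min epochs strictly
above 100 mg ("larger than", so exactly 100 mg does not count), per day.
Total activity is the per-day sum over complete days.

Phase angle = acrotime − sleep midpoint, wrapped to (−12, +12] h and
converted to radians (×2π/24): positive means the temperature peak follows
mid-sleep. An undefined acrotime propagates as NaN.

## Group statistics

Each metric is compared with ANCOVA: `outcome ~ group + age + sex`, sex a
two-level factor, main effects only. The group factor is tested with a
type-II F test. Estimated marginal means are predictive margins (every
subject's covariates, group set counterfactually, predictions averaged)
with SEs from the coefficient covariance. Post hoc pairwise contrasts are
Bonferroni-adjusted (`p_adj = min(1, m·p)`).

Normality screening: Shapiro-Wilk on the model residuals at α = 0.05
(configurable) triggers a Box-Cox transform of the outcome — maximum
likelihood λ, with a positive shift (recorded) when the outcome contains
non-positive values, applied across all subjects rather than within
groups. Box-Cox is monotone, so contrast directions survive the
transform; transformed-scale estimated means are reported alongside raw
group means. Constant outcomes skip the transform with a flag.

Bland-Altman agreement: differences d = a − b, bias = mean(d), limits
bias ± 1.96·SD(d) (sample SD). Demographic tests (Mann-Whitney,
Kruskal-Wallis, Dunn) are thin pass-throughs provided for convenience.

## Synthetic cohorts

The generator emulates the study conditions the analysis is designed for:

| knob | default | controls |
|---|---|---|
| `n_days` | drawn 5–24 | recording length (median ~2 weeks) |
| `mesor`, `amplitude`, `acrophase` | 30 °C, 2 °C, −1.45 rad | rhythm level/size/phase |
| `phase_jitter_sd` | 0.30 rad/day | IS (day-to-day phase consistency) |
| `frag_noise_sd` | 2.0 °C/epoch | IV (fragmentation) |
| `quantization` | 0.25 °C | sensor resolution |
| `nonwear_rate`, `nonwear_dropout` | 0.35/day, 3 °C | exclusion pressure, post-rewear artifact |
| `sleep_midpoint`, `sleep_duration` | 04:09, 8.7 h | schedule (≈ 7.35 h asleep at 84.5% efficiency) |
| `sleep_jitter_sd` | 1.0 h/day | SRI |
| `sleep_frag_prob` | 0.155 | efficiency |
| `activity_day_mean`, `mvpa_blocks` | 25 mg, 3 × 27 min | TAC ≈ 35k counts/day, MVPA ≈ 80 min/day |

Temperature: `y(t) = mesor + amplitude·cos(2πt/24 + acrophase + δ_d) + ε`,
`δ_d ~ N(0, phase_jitter_sd)` per day, `ε ~ N(0, frag_noise_sd)` per 30-s
epoch, quantized to 0.25 °C. Non-wear episodes arrive as a Poisson
process; durations are exponential (mean 45 min) and the 30 min after
each episode read `nonwear_dropout` °C low while flagged as worn — the
magnitude and duration of the real post-rewear artifact are not
well-characterized, so both are exposed in the config rather than
hard-coded. Activity is a two-state rest/wake profile with MVPA blocks
inserted above 100 mg; only threshold and sum behavior matters
downstream, so no richer accelerometry is simulated. Ages are uniform
18–30 and sex Bernoulli(0.6 female) by default. Identical seed + config
is bit-identical; all randomness flows through one `numpy` generator in a
fixed draw order.

The two-arm `mood_cohort_preset` injects the group deltas the analysis is
meant to detect: case − control of −1.1 °C mesor, −0.52 rad acrophase,
≈ −0.08 IS and ≈ +0.14 IV, with equal amplitudes (so the amplitude
contrast is a built-in negative control), plus less regular sleep and
lower activity in cases. The IS/IV deltas are realized through the jitter
and noise knobs (0.30 → 0.34 rad; 2.0 → 4.8 °C), calibrated from the
closed-form expectations under the generative model,
`E[IS] ≈ e^{−σφ²} + (1 − e^{−σφ²})/n_days` and
`E[IV] ≈ (4·sin²(π/24)·S + 2v)/(S + v)` with `S = A²/2` and `v` the
hourly-bin noise variance. Between-subject heterogeneity (mesor SD
0.5 °C, acrophase SD 0.25 rad, amplitude SD 0.15 °C) sets realistic
subject-level spread while keeping the injected contrasts detectable at
n = 50/group.

**What the generator does not emulate.** White epoch noise averages down
by √120 at hourly bins, so with physically plausible °C noise the
*absolute* IS/IV levels of synthetic data (IS ≈ 0.8–0.9, IV ≈ 0.1–0.25)
are cleaner than wrist recordings of free-living humans, whose
slow behavioral/environmental fluctuations (showers, ambient temperature,
posture) produce IS ≈ 0.5 and IV ≈ 1.5. The same applies to SRI: real
irregularity includes naps and skipped nights, not just Gaussian midpoint
jitter. Passing tests therefore demonstrate the estimators and the
detection of *injected differences* under controlled conditions — not
that real cohorts would show effects of these magnitudes.

## Problem sizes in the test suite

Unit tests use scaled-down Monte-Carlo sizes (tens of seeds, ~10 subjects
per arm, ~5–7 days) chosen so each ordering/calibration check still has
negligible error probability at its threshold; the acceptance suite runs
the full-size experiments (500-replicate estimator bias, 1000-replicate
ANCOVA type-I calibration at n = 50/group, and a 100-seed end-to-end
direction-recovery study at n = 50/group with recording lengths drawn
5–24 days). The ANCOVA calibration simulates subject-level outcome tables
directly — the calibration property belongs to the ANCOVA, and per-epoch
simulation would add runtime, not information.

## Known limitations

- Sleep/wake state estimation from raw acceleration is out of scope;
  states and windows are inputs.
- The mixed cosinor's random structure (intercept only) understates
  uncertainty for amplitude/phase contrasts when subjects differ in those
  parameters; the subject-level ANCOVA route is the primary inference.
- ANCOVA on acrophase is linear, appropriate while group phases sit well
  inside one wrap interval; cohorts straddling the wrap boundary would
  need circular regression.
- Box-Cox is applied across all subjects (not within groups), and the
  Shapiro-Wilk trigger at α = 0.05 is a screening rule, not a claim about
  optimal transformation.
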