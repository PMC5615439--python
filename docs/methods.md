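# Methods

## The question

Free-living energy balance in wheelchair users with paraplegia is usually
measured with a chest-worn combined accelerometer/heart-rate monitor and a
weighed food diary kept over several consecutive days. Daily values
fluctuate, so a single day is an unreliable estimate of a person's habitual
level; too many days burden participants. This package quantifies the
day-to-day variability of each energy-balance outcome and converts it into
the minimum number of monitoring days needed for acceptable reliability.

Outcomes handled: total energy expenditure (TEE, kcal/d) and its derived
components (PAEE, PAL), intensity-band activity minutes (sedentary < 1.5
METs; light 1.5–2.9 METs; MVPA ≥ 3 METs — the 3.0 boundary counts as MVPA),
total energy intake (kcal/d) and macronutrient shares of intake (protein,
fat, carbohydrate, alcohol, % of energy).

## Valid-day rule

A monitoring day enters the analysis only when the device was worn strictly
more than 80% of the day: wear > 0.80 × 1440 = 1152 min. A day at exactly
1152 min is invalid. Both the fraction and the day length are configurable.
Partially worn, non-valid days are dropped entirely; non-worn minutes inside
a valid day are treated as missing, never as sedentary time.

## Energy components

With a measured resting metabolic rate (RMR) per subject and a fixed
diet-induced thermogenesis (DIT) fraction of 10% of TEE:

    DIT  = 0.10 · TEE
    PAEE = TEE − RMR − DIT
    PAL  = TEE / RMR

so RMR + DIT + PAEE ≡ TEE by construction. On a low-expenditure day a
measured RMR can exceed 0.9·TEE; the negative PAEE is flagged and retained
(downstream log-transforms then engage the offset policy below). Component
calculations are per subject-day, averaged within subject before cohort
averaging, so each participant counts once.

## Variance model, ICC and days needed

Each outcome y is modelled on the natural-log scale with a random-intercept
linear mixed model fitted by REML:

    log(y_ij + c) = x_ij'β + u_i + e_ij,
    u_i ~ N(0, σ²_b),  e_ij ~ N(0, σ²_w)

with subject i, day j, and fixed effects for age, injury level (vertebral
level coded as consecutive integers C1=1 … S5=29, larger = more caudal
lesion), wear time (fraction of day), sex, day-of-week (treatment-coded
against Monday) and the linear measurement-order index. The ICC is the
between-subject share of total variance,

    ICC_s = σ²_b / (σ²_b + σ²_w),

computed from the covariate-adjusted model by default (an unadjusted mode —
an empty covariate tuple — exists and is what the balanced-ANOVA oracle
tests exercise). The days needed for a target reliability ICC_t (default
0.80) follow from the Spearman-Brown prophecy formula

    N = [ICC_t / (1 − ICC_t)] · [(1 − ICC_s) / ICC_s],

reported both as the real N and as whole days ceil(N). Plugging N back into
the step-up form N·ICC_s / (1 + (N−1)·ICC_s) returns ICC_t to machine
precision. Projections beyond the observed monitoring span are flagged
(`extrapolated`): a 7-day record says little about a 24-day requirement.

Intra-individual CVs are computed on the raw scale: per subject,
100·SD/mean across that subject's valid days (sample SD), summarised as the
cohort mean with a 95% t-interval across subjects. Subjects with fewer than
two usable days, or a zero mean, are excluded (with a warning for the
latter).

### Numerical choices

- **Log offset.** Outcomes that can be zero (MVPA minutes, alcohol share)
  or negative (derived PAEE on low days) cannot be logged directly. The
  automatic policy shifts the outcome so its minimum maps to 1: offset 0
  for strictly positive data, +1 when the minimum is 0, 1 − min otherwise.
  Explicit per-outcome offsets override this.
- **REML fit.** statsmodels `MixedLM`, REML, default quasi-Newton start
  followed by a tightly-tolerance simplex polish (the default stop leaves
  O(1e−6) slack in the variance components relative to the balanced-data
  ANOVA closed forms; the polish reaches ~1e−8). Non-convergence falls back
  to Powell and is an error if still unresolved.
- **Negative variance estimates** are truncated at zero before the ICC
  ratio (REML's parameterisation already keeps them non-negative; the
  truncation also covers moment-style inputs). σ²_b = 0 means no number of
  days can reach the target; the outcome is reported `unreliable` rather
  than given an infinite N.
- **Whole-day ceiling.** N is snapped to the nearest integer when within
  1e−9 before taking the ceiling, so float noise (0.8/0.2 =
  4.000000000000001) cannot inflate the day count.
- **Residual df** for intervals and MBI probabilities:
  n_obs − n_fixed_parameters − n_subjects (a conservative between-within
  approximation), floored at 1.

## Magnitude-based inference

Effects are judged against a smallest worthwhile effect (SWE) of 0.20
between-subject standard deviations on the log scale. With T central-t on
the model's residual df:

    p+ = P(T > (SWE − b)/se),  p− = P(T < (−SWE − b)/se),  p0 = 1 − p+ − p−.

An effect is *unclear* when both crossing probabilities exceed 5%.
Otherwise it is clear, its direction is the most probable category (ties
resolved to trivial), and the direction's probability is mapped onto the
conventional scale: <0.5% most unlikely; 0.5–5% very unlikely; 5–25%
unlikely; 25–75% possible; 75–95% likely; 95–99.5% very likely; >99.5%
most likely. A probability on a bin boundary takes the higher bin (0.75 →
"likely"). Log-scale effects and CI bounds back-transform to percent
changes, 100·(exp(b) − 1).

Contrasts provided:

- **Numeric covariates** (age, injury level, wear time): the change from a
  typically-low (mean − 1 SD) to a typically-high (mean + 1 SD) value,
  i.e. 2·SD_x·β — invariant to the covariate's units. SDs are computed over
  the model rows.
- **Sex**: the male − female level difference.
- **Measurement order**: the day-1 → day-7 change (n_days − 1)·β_order,
  probing drift in reporting or behaviour across the monitoring week.
- **Day-of-week**: adjusted means by marginal standardisation (every other
  covariate held at its observed values, predictions averaged over rows),
  back-transformed to the raw scale; all 21 pairwise contrasts with
  unadjusted two-sided t p-values (Holm correction available, off by
  default, mirroring how such tables are conventionally presented); and
  the highest-minus-lowest fitted day coefficient as a percent effect with
  MBI classification. Day levels absent from the data are skipped with a
  warning.

The t distribution (not the normal) drives all probabilities — an honest
choice at 30-ish subjects; df and the 95% CI level are configurable.

## Synthetic cohort generator

No raw cohort accompanies the design this package implements, so every
claim is validated by parameter recovery on generated data. Per outcome:

    log y_ij = μ + x_i'γ + d(dow_ij) + δ·(j−1) + u_i + e_ij

with u_i ~ N(0, σ²_b), e_ij ~ N(0, σ²_w), δ = log(1 + drift%/100)/(n−1) so
the configured drift is the total week-long percent change. Covariate
effects enter centred, so μ stays the grand log-mean and (σ_b, σ_w) remain
the variance components a correctly adjusted model should recover; the
config reports the implied single-day ICC. Percent-scale inputs convert by
exact lognormal identities: σ_w = sqrt(log(1 + CV²)), μ = log(mean) −
(σ²_b + σ²_w)/2. One seed drives everything through
`SeedSequence.spawn`: child 0 the subject table, child 1 wear/day
structure, children 2… one per outcome in sorted name order — adding an
outcome never perturbs the others.

The `paperlike` preset emulates the study population: 33 subjects (18%
female), age ~ N(44, 9) truncated to [22, 61], thoracic/upper-lumbar
lesions centred at T7, measured RMR ~ N(1481, 178) kcal/d. Within-subject
SDs come from the published intra-individual CVs (TEE 7%, sedentary 9%,
light 46%, MVPA 97%, intake 26%, macros 20–26%, alcohol 160%);
between-subject SDs are set so implied single-day ICCs land in the
published days-needed bands. Total intake carries the reported −15%
week-long reporting drift; alcohol share is elevated on Friday/Saturday.
Wear time is drawn per day from N(0.93, 0.12) of the day (clipped to
[0.5, 1]), giving ~96% wear on valid days and per-subject valid-day counts
spanning roughly 4–7 under the 80% rule.

Two derived-outcome choices matter:

- **TEE couples to RMR** with elasticity 1, because TEE physiologically
  contains RMR. PAL = TEE/RMR is then independent of RMR, with residual
  between-subject log-SD 0.107 taken from the published PAL spread
  (1.40 ± 0.15). The day-level draw is truncated below at PAL 1.15
  (redrawn, then clipped), matching the published support (PAL 1.20–1.85,
  PAEE ≥ 6% of TEE) and keeping derived PAEE positive. Truncation slightly
  raises the mean and trims the within-variance; the preset is calibrated
  from printed summaries only and is approximate by design.
- **Macronutrient shares** are drawn lognormally and renormalised to sum
  to 100%, as the data model requires; this induces mild negative
  correlation and slightly distorts the configured per-macro variances.

The minute-epoch generator emits 1440 one-minute METs per day from a
three-state categorical process with configured expected band minutes
(default 1255 sedentary / 172 light / 12 MVPA), MET values uniform within
band, and one contiguous non-worn gap sized to the wear fraction.

### What the generator does not emulate

Real monitor data have autocorrelated within-day behaviour, device error
correlated with wear position and heart-rate calibration quality, diary
under-reporting correlated with intake level, and covariate-outcome
confounding beyond the configured linear effects. Passing recovery tests
therefore shows the *estimators* are correct under the stated model, not
that the model captures every feature of field data.

## Problem sizes

Unit and recovery tests run at the study scale (33 × 7) except the
parameter-recovery checks, which use 500 subjects × 7 days — large enough
that estimator noise (ICC SE ≈ 0.01) is well inside the ±0.03 recovery
band while a full run stays under a minute. The acceptance script runs the
33 × 7 pipeline plus the 500 × 7 recovery checks in ~15 s.

## Known limitations

- The published cohort's raw data are not available, so the preset
  reproduces the *structure* of the published tables, not their exact
  numbers; at 33 subjects the single-day ICC carries a sampling SE around
  0.05, which can move an outcome across an integer day boundary.
- Prophecy projections far beyond the observed week (dietary fat needs
  ~15–24 days) inherit that uncertainty multiplied; they are flagged, not
  suppressed.
- MBI itself is contested methodology; this package implements it as
  specified (the classification layer is separable from the variance
  decomposition, which stands on its own). Bayesian or
  equivalence-testing reformulations are out of scope.
- Only subject random intercepts are supported — no random slopes, no
  nested designs.
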