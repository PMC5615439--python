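# ebvar — how many days to measure energy balance in wheelchair users?

Daily energy expenditure, physical activity and energy intake fluctuate.
For wheelchair users with paraplegia — where a chest-worn
accelerometer/heart-rate monitor plus a weighed food diary is the standard
free-living protocol — a single monitored day is a noisy estimate of a
person's habitual level. `ebvar` quantifies that day-to-day variability
and answers the design question researchers and clinicians actually have:
**how many monitoring days does each outcome need for acceptable
reliability?**

The pipeline:

1. **Valid-day filtering** — a day counts only if the monitor was worn
   strictly more than 80% of it (> 1152 of 1440 min).
2. **Energy components** — TEE splits into resting metabolic rate,
   diet-induced thermogenesis (10% of TEE) and physical-activity energy
   expenditure; PAL = TEE/RMR. Minute-level MET streams aggregate into
   sedentary (< 1.5 METs), light (1.5–2.9) and MVPA (≥ 3) minutes.
3. **Reliability** — each outcome is log-transformed and fitted with a
   random-intercept mixed model (REML) adjusting for age, injury level,
   wear time, sex, day-of-week and measurement order. The single-day
   intraclass correlation ICC_s = σ²_b/(σ²_b + σ²_w) feeds the
   Spearman-Brown prophecy formula
   N = [ICC_t/(1 − ICC_t)]·[(1 − ICC_s)/ICC_s] (target ICC_t = 0.80),
   reported as whole days, alongside intra-individual CVs (100·SD/mean).
4. **Magnitude-based inference** — covariate (2-SD), measurement-order and
   day-of-week effects are back-transformed to percent changes and
   classified as clear/unclear with probabilistic qualifiers against a
   smallest worthwhile effect of 0.20 between-subject SDs.
5. **Synthetic cohorts** — a generator with the exact statistical
   structure the models assume (lognormal outcomes, subject random
   intercepts, covariate/day/order effects, variable wear time), so every
   stage is testable by parameter recovery; a `paperlike` preset emulates
   a 33-subject, 7-day cohort calibrated to published summary statistics.

## Worked example

Generate the study-shaped cohort and run the analyses:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_energy_components.py
python analysis/03_reliability.py
python analysis/04_effect_inference.py
```

`01` reports the cohort and the wear filter:

```
cohort: 33 subjects (7 female), 231 monitored days
valid days (>80% wear): 210/231; per subject 5-7
```

`02` partitions the cohort's mean daily energy flux — RMR dominates
expenditure, activity contributes about a fifth:

```
expenditure:
  rmr              1493 kcal/d  (69.2%)
  dit               216 kcal/d  (10.0%)
  paee              449 kcal/d  (20.8%)
  tee              2157 kcal/d  (100.0%)
```

`03` is the headline table — days needed per outcome at target ICC 0.80:

```
monitoring days needed for ICC > 0.80 (single-day ICC, CV):
  tee_kcal         2 day(s)   ICC_s=0.75   CV=6% (6-7%)
  light_min        2 day(s)   ICC_s=0.78   CV=37% (33-42%)
  pal              3 day(s)   ICC_s=0.62   CV=6% (6-7%)
  mvpa_min         3 day(s)   ICC_s=0.66   CV=72% (63-80%)
  paee_kcal        4 day(s)   ICC_s=0.53   CV=32% (26-38%)
  sedentary_min    4 day(s)   ICC_s=0.51   CV=8% (7-10%)
  intake_kcal      6 day(s)   ICC_s=0.44   CV=28% (24-31%)
  alcohol_pct      7 day(s)   ICC_s=0.38   CV=107% (94-120%)
  carb_pct        12 day(s)   ICC_s=0.26   CV=14% (12-16%) [beyond observed week]
  fat_pct         15 day(s)   ICC_s=0.22   CV=19% (17-22%) [beyond observed week]
  protein_pct     21 day(s)   ICC_s=0.16   CV=24% (21-26%) [beyond observed week]
```

Read it as: total energy expenditure is stable day to day (its largest
component, RMR, is a per-subject constant), so a couple of days suffice;
behavioural outcomes need more; dietary macronutrient composition is so
variable that a week of diary badly under-samples it — those rows are
flagged because projecting a 7-day record to 12–21 days loses precision.

`04` classifies covariate and order effects, e.g.:

```
  mvpa_min       sex male-female        +188.7% (10, 659%)  'very likely' increase
  intake_kcal    order day1->day7        -10.1% (-20, 1%)  'likely' decrease
```

— men accumulate far more MVPA than women in this synthetic cohort, and
reported energy intake drifts downward across the diary week (the
generator injects a −15% drift; at 33 subjects the estimate is −10% with
a wide interval).

The same surfaces are available as a CLI (`ebvar simulate | filter |
reliability | mbi | report`); `ebvar report` writes all tables plus a
provenance log and is byte-deterministic given identical inputs.

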