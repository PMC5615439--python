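"""Synthetic cohorts with the variance structure the analysis assumes.

No raw data accompany the study design this package implements, so every
pipeline stage is validated by parameter recovery on generated cohorts.
Each daily outcome follows a lognormal random-intercept model

    log y_ij = mu + x_i' gamma + d(dow_ij) + delta * (j - 1) + u_i + e_ij

with subject random intercepts u_i ~ N(0, sigma_b^2), day-level noise
e_ij ~ N(0, sigma_w^2), optional covariate effects (sex, age, injury
level, wear time), day-of-week offsets, and a linear measurement-order
drift delta = log(1 + drift%/100) / (n_days - 1) so the configured drift
is the total day-1 to day-7 percent change.  Covariates enter centred at
their sample means, so ``mu`` stays the grand log-mean and the configured
(sigma_b, sigma_w) remain the *adjusted* variance components a correctly
specified model should recover — the config reports the implied single-day
ICC sigma_b^2/(sigma_b^2+sigma_w^2).

Percent-scale quantities convert through exact lognormal identities:
a within-subject CV of c% corresponds to sigma_w = sqrt(log(1+(c/100)^2)),
and the log-mean for a target raw mean m is log(m) - (sigma_b^2+sigma_w^2)/2.

All randomness flows from one seed through a documented splitting scheme
(`numpy.random.SeedSequence.spawn`): child 0 draws the subject table,
child 1 wear time and day structure, and children 2.. one per outcome in
sorted name order — adding an outcome never perturbs the others.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, asdict, replace
from typing import Mapping

import numpy as np

from .components import derive_components
from .errors import DomainError
from .io_model import DAYS_OF_WEEK, DailyRecord, MinuteEpoch, SubjectProfile

_MACRO_OUTCOMES = ("protein_pct", "fat_pct", "carb_pct", "alcohol_pct")
_BAND_OUTCOMES = ("sedentary_min", "light_min", "mvpa_min")


def sigma_within_for_cv(cv_pct: float) -> float:
    """Log-scale SD giving a raw-scale within-subject CV of ``cv_pct`` %."""
    return math.sqrt(math.log1p((cv_pct / 100.0) ** 2))


def cv_for_sigma(sigma_log: float) -> float:
    """Raw-scale CV (%) implied by a log-scale SD (exact lognormal identity)."""
    return 100.0 * math.sqrt(math.expm1(sigma_log**2))


def mu_log_for_mean(mean: float, sigma_between: float, sigma_within: float) -> float:
    """Log-scale grand mean giving a raw-scale expectation of ``mean``."""
    return math.log(mean) - 0.5 * (sigma_between**2 + sigma_within**2)


@dataclass(frozen=True)
class OutcomeSpec:
    """Lognormal generative parameters for one daily outcome."""

    mu_log: float
    sigma_between_log: float
    sigma_within_log: float
    sex_effect_log: float = 0.0  # male minus female
    age_effect_log: float = 0.0  # per year
    injury_effect_log: float = 0.0  # per vertebral code unit (larger = lower lesion)
    wear_effect_log: float = 0.0  # per unit wear fraction
    day_of_week_log: tuple[float, ...] = (0.0,) * 7  # Mon..Sun offsets
    order_drift_total_pct: float = 0.0  # total % change day 1 -> day n
    #: elasticity w.r.t. the subject's measured RMR (log-log slope, centred).
    #: Used for TEE, which physiologically contains RMR: coupling 1 keeps
    #: PAL = TEE/RMR independent of RMR and derived PAEE almost surely positive.
    rmr_coupling: float = 0.0
    #: lower truncation for the outcome/RMR ratio (only meaningful with
    #: rmr_coupling > 0): day-level noise is redrawn below the floor,
    #: emulating the bounded support of a ratio like PAL
    ratio_floor: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_between_log < 0 or self.sigma_within_log < 0:
            raise DomainError("log-scale SDs must be non-negative")
        if len(self.day_of_week_log) != 7:
            raise DomainError("day_of_week_log needs exactly 7 offsets (Mon..Sun)")

    @property
    def implied_icc(self) -> float:
        s2b, s2w = self.sigma_between_log**2, self.sigma_within_log**2
        if s2b + s2w == 0:
            raise DomainError("both variances zero; implied ICC undefined")
        return s2b / (s2b + s2w)

    @property
    def implied_cv_pct(self) -> float:
        """Within-subject raw-scale CV implied by sigma_within."""
        return cv_for_sigma(self.sigma_within_log)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort recipe: size, subject covariates, per-outcome models."""

    outcomes: Mapping[str, OutcomeSpec]
    n_subjects: int = 33
    n_days: int = 7
    seed: int = 0
    # subject covariate distributions
    female_prob: float = 6 / 33
    age_mean: float = 44.0
    age_sd: float = 9.0
    age_range: tuple[float, float] = (22.0, 61.0)
    injury_code_mean: float = 14.0  # T7
    injury_code_sd: float = 3.0
    injury_code_range: tuple[int, int] = (8, 23)  # T1..L4
    rmr_mean: float = 1481.0
    rmr_sd: float = 178.0
    rmr_min: float = 800.0
    # wear-time model (fractions of a 1440-minute day)
    wear_mean_fraction: float = 0.96
    wear_sd_fraction: float = 0.03
    wear_floor_fraction: float = 0.60
    missing_day_prob: float = 0.0
    # post-processing
    derive_energy: bool = True  # add paee_kcal and pal from tee_kcal and RMR
    normalise_macros: bool = True  # rescale macro % rows to sum to 100

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise DomainError("n_subjects must be >= 2")
        if self.n_days < 1:
            raise DomainError("n_days must be >= 1")
        for name, p in (
            ("female_prob", self.female_prob),
            ("missing_day_prob", self.missing_day_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.wear_mean_fraction <= 1.0:
            raise DomainError("wear_mean_fraction must be in (0, 1]")

    def implied_icc(self, outcome: str) -> float:
        return self.outcomes[outcome].implied_icc


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SubjectProfile], list[DailyRecord]]:
    """Draw a full cohort: subject table plus long-format daily records."""
    root = np.random.SeedSequence(config.seed)
    outcome_names = sorted(config.outcomes)
    children = root.spawn(2 + len(outcome_names))
    rng_subj = np.random.default_rng(children[0])
    rng_days = np.random.default_rng(children[1])
    rng_outcomes = {
        name: np.random.default_rng(child)
        for name, child in zip(outcome_names, children[2:])
    }

    n, k = config.n_subjects, config.n_days

    # --- subject table
    sex = np.where(rng_subj.random(n) < config.female_prob, "female", "male")
    age = np.empty(n)
    for i in range(n):  # truncated normal by resampling
        while True:
            a = rng_subj.normal(config.age_mean, config.age_sd)
            if config.age_range[0] <= a <= config.age_range[1]:
                age[i] = round(a, 1)
                break
    injury = np.clip(
        np.rint(rng_subj.normal(config.injury_code_mean, config.injury_code_sd, n)),
        *config.injury_code_range,
    ).astype(int)
    rmr = np.maximum(
        rng_subj.normal(config.rmr_mean, config.rmr_sd, n), config.rmr_min
    ).round(1)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    subjects = [
        SubjectProfile(
            subject_id=ids[i],
            age=float(age[i]),
            sex=str(sex[i]),
            injury_level_code=int(injury[i]),
            rmr=float(rmr[i]),
        )
        for i in range(n)
    ]

    # --- day structure and wear time
    start_dow = rng_days.integers(0, 7, n)
    wear_frac = np.clip(
        rng_days.normal(config.wear_mean_fraction, config.wear_sd_fraction, (n, k)),
        config.wear_floor_fraction,
        1.0,
    )
    present = rng_days.random((n, k)) >= config.missing_day_prob

    # centred covariates keep mu the grand mean and avoid covariate leakage
    # into the random-intercept variance
    is_male_c = (sex == "male").astype(float)
    is_male_c -= is_male_c.mean()
    age_c = age - age.mean()
    injury_c = injury - injury.mean()
    wear_c = wear_frac - wear_frac.mean()

    # --- outcome draws
    values: dict[str, np.ndarray] = {}
    for name in outcome_names:
        spec = config.outcomes[name]
        rng = rng_outcomes[name]
        u = rng.normal(0.0, spec.sigma_between_log, n)
        e = rng.normal(0.0, spec.sigma_within_log, (n, k))
        delta = (
            math.log1p(spec.order_drift_total_pct / 100.0) / (k - 1) if k > 1 else 0.0
        )
        base = (
            spec.mu_log
            + u[:, None]
            + spec.sex_effect_log * is_male_c[:, None]
            + spec.age_effect_log * age_c[:, None]
            + spec.injury_effect_log * injury_c[:, None]
            + spec.wear_effect_log * wear_c
            + delta * np.arange(k)[None, :]
        )
        if spec.rmr_coupling:
            log_rmr = np.log(rmr)
            base = base + spec.rmr_coupling * (log_rmr - log_rmr.mean())[:, None]
        dow_idx = (start_dow[:, None] + np.arange(k)[None, :]) % 7
        base = base + np.asarray(spec.day_of_week_log)[dow_idx]
        if spec.ratio_floor is not None and spec.rmr_coupling:
            # truncated day-level noise: redraw e where the implied
            # outcome/RMR ratio falls below the floor (bounded support of
            # a ratio such as PAL); clip any stragglers
            floor = np.log(spec.ratio_floor) + np.log(rmr)[:, None]
            for _ in range(100):
                bad = base + e < floor
                if not bad.any():
                    break
                e[bad] = rng.normal(0.0, spec.sigma_within_log, int(bad.sum()))
            e = np.maximum(e, floor - base)
        values[name] = np.exp(base + e)

    if config.normalise_macros and all(m in values for m in _MACRO_OUTCOMES):
        total = sum(values[m] for m in _MACRO_OUTCOMES)
        for m in _MACRO_OUTCOMES:
            values[m] = 100.0 * values[m] / total

    # --- assemble records
    records: list[DailyRecord] = []
    for i in range(n):
        for j in range(k):
            if not present[i, j]:
                continue
            wear_min = round(float(wear_frac[i, j]) * 1440.0, 1)
            outcomes: dict[str, float] = {
                name: float(values[name][i, j]) for name in outcome_names
            }
            # keep activity bands consistent with wear time
            if all(b in outcomes for b in _BAND_OUTCOMES):
                band_sum = sum(outcomes[b] for b in _BAND_OUTCOMES)
                if band_sum > wear_min:
                    scale = wear_min / band_sum
                    for b in _BAND_OUTCOMES:
                        outcomes[b] *= scale
            if config.derive_energy and "tee_kcal" in outcomes:
                part = derive_components(outcomes["tee_kcal"], float(rmr[i]))
                outcomes["paee_kcal"] = float(part.paee)
                outcomes["pal"] = float(part.pal)
            records.append(
                DailyRecord(
                    subject_id=ids[i],
                    order_index=j + 1,
                    day_of_week=DAYS_OF_WEEK[(start_dow[i] + j) % 7],
                    wear_minutes=wear_min,
                    outcomes=outcomes,
                )
            )
    return subjects, records


# ---------------------------------------------------------------------------
# Minute-epoch stream


@dataclass(frozen=True)
class EpochConfig:
    """Three-state minute process with configured expected band minutes.

    Defaults reproduce a realistic wheelchair-user day: overwhelmingly
    sedentary, some light activity, a few MVPA minutes.  Worn minutes form
    one contiguous non-worn gap; MET values are drawn uniformly inside each
    band.
    """

    sedentary_min: float = 1255.0
    light_min: float = 172.0
    mvpa_min: float = 12.0
    wear_fraction: float | None = None  # default: band total / 1440

    @property
    def effective_wear_fraction(self) -> float:
        if self.wear_fraction is not None:
            return self.wear_fraction
        return min((self.sedentary_min + self.light_min + self.mvpa_min) / 1440.0, 1.0)


def generate_epoch_stream(
    config: EpochConfig,
    day: _dt.date,
    subject_id: str = "S001",
    seed: int | np.random.Generator = 0,
) -> list[MinuteEpoch]:
    """One calendar day of minute epochs (1440 rows) for one subject."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_worn = int(round(config.effective_wear_fraction * 1440))
    gap = 1440 - n_worn
    gap_start = int(rng.integers(0, 1440 - gap + 1)) if gap else 1440
    probs = np.array([config.sedentary_min, config.light_min, config.mvpa_min])
    probs = probs / probs.sum()
    states = rng.choice(3, size=1440, p=probs)
    met_lo = np.array([0.9, 1.5, 3.0])
    met_hi = np.array([1.45, 2.95, 6.0])
    mets = rng.uniform(met_lo[states], met_hi[states])
    base = _dt.datetime.combine(day, _dt.time())
    return [
        MinuteEpoch(
            subject_id=subject_id,
            timestamp=base + _dt.timedelta(minutes=m),
            met=float(mets[m]),
            worn=not (gap_start <= m < gap_start + gap),
        )
        for m in range(1440)
    ]


# ---------------------------------------------------------------------------
# Study-like preset


def preset_paperlike(seed: int = 0) -> GeneratorConfig:
    """A 33-subject, 7-day cohort shaped like the study population.

    Calibrated from published summary statistics only (cohort means,
    intra-individual CVs, reported covariate and order effects); between-
    subject spreads are approximate.  Within-subject SDs come from the
    printed CVs via the exact lognormal identity; between-subject SDs are
    set so the implied single-day ICCs land in the reported days-needed
    bands (e.g. total energy expenditure ~0.87 -> 1 day; sedentary time
    ~0.52 -> 4 days).  Total energy intake carries the reported -15%
    week-long reporting drift; alcohol share is elevated on Friday and
    Saturday.
    """

    def spec(mean, cv_pct, sb, **kw):
        sw = sigma_within_for_cv(cv_pct)
        return OutcomeSpec(
            mu_log=mu_log_for_mean(mean, sb, sw),
            sigma_between_log=sb,
            sigma_within_log=sw,
            **kw,
        )

    fri_sat = (0.0, 0.0, 0.0, 0.0, 0.8, 0.8, 0.0)
    outcomes = {
        # expenditure side (PAEE and PAL are derived from TEE and RMR)
        # TEE rides on the subject's RMR (elasticity 1), so derived
        # PAL = TEE/RMR is independent of RMR with a ~0.107 log between-
        # subject SD (the published PAL spread of 1.40 +/- 0.15), and the
        # day-level draw is truncated so PAL never falls below 1.15 — the
        # published support is 1.20-1.85 with PAEE >= 6% of TEE
        "tee_kcal": spec(
            2103, 7, 0.107, sex_effect_log=0.12, injury_effect_log=0.0162,
            rmr_coupling=1.0, ratio_floor=1.15,
        ),
        "sedentary_min": spec(
            1255, 9, 0.093, sex_effect_log=-0.05, injury_effect_log=-0.0119
        ),
        "light_min": spec(172, 46, 0.70, sex_effect_log=0.30),
        "mvpa_min": spec(
            12, 97, 1.30, sex_effect_log=0.60, injury_effect_log=0.0954
        ),
        # intake side
        "intake_kcal": spec(
            1742, 26, 0.26, sex_effect_log=0.15, order_drift_total_pct=-15.0
        ),
        "protein_pct": spec(19, 26, 0.186),
        "fat_pct": spec(34.4, 26, 0.105),
        "carb_pct": spec(44, 20, 0.127),
        "alcohol_pct": spec(2.7, 160, 0.756, day_of_week_log=fri_sat),
    }
    # wear: ~96% on valid days but enough low-wear days that per-subject
    # valid-day counts span roughly 4-7 under the 80% cut-off
    return GeneratorConfig(
        outcomes=outcomes,
        n_subjects=33,
        n_days=7,
        seed=seed,
        wear_mean_fraction=0.93,
        wear_sd_fraction=0.12,
        wear_floor_fraction=0.50,
    )


# ---------------------------------------------------------------------------
# Config (de)serialisation for the CLI


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["outcomes"] = {k: asdict(v) for k, v in config.outcomes.items()}
    return d


def config_from_dict(d: Mapping) -> GeneratorConfig:
    d = dict(d)
    outcomes = {
        k: OutcomeSpec(
            **{**v, "day_of_week_log": tuple(v.get("day_of_week_log", (0.0,) * 7))}
        )
        for k, v in d.pop("outcomes").items()
    }
    for key in ("age_range", "injury_code_range"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(outcomes=outcomes, **d)


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)
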