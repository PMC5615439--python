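"""Magnitude-based inference (MBI) over mixed-model effects.

An effect estimated on the log scale is judged against a smallest
worthwhile effect (SWE) threshold of 0.20 between-subject standard
deviations.  With T the central t distribution on the model's residual
degrees of freedom, the probabilities that the true effect is substantially
positive, trivial or substantially negative are

    p+ = P(T > (SWE - b) / se),   p- = P(T < (-SWE - b) / se),
    p0 = 1 - p+ - p-.

An effect is *unclear* when both crossing probabilities exceed 5%;
otherwise it is clear and qualified on the conventional probabilistic
scale (<0.5% most unlikely; 0.5-5% very unlikely; 5-25% unlikely; 25-75%
possible; 75-95% likely; 95-99.5% very likely; >99.5% most likely).
Log-scale effects are back-transformed to percent changes,
100*(exp(b) - 1).

Three contrast builders cover the study's questions: a 2-SD change in a
numeric covariate (or the level difference of a categorical one), the
linear day-1 to day-7 measurement-order drift, and day-of-week contrasts
including the highest-minus-lowest day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .io_model import DAYS_OF_WEEK
from .reliability import VarianceComponents

logger = logging.getLogger(__name__)

SWE_STANDARDISED = 0.20  # smallest worthwhile effect, in between-subject SDs
UNCLEAR_CROSSING_PROB = 0.05

#: Lower edges of the probabilistic qualifier bins; a probability on a
#: boundary falls in the higher bin (0.75 -> "likely").
_QUALIFIER_BINS: tuple[tuple[float, str], ...] = (
    (0.995, "most likely"),
    (0.95, "very likely"),
    (0.75, "likely"),
    (0.25, "possible"),
    (0.05, "unlikely"),
    (0.005, "very unlikely"),
    (0.0, "most unlikely"),
)


@dataclass(frozen=True)
class MBIEffect:
    """A back-transformed effect with its substantiality classification."""

    label: str
    effect_log: float
    se_log: float
    df: float
    effect_pct: float
    ci95_pct: tuple[float, float]
    swe_log: float
    p_positive: float
    p_trivial: float
    p_negative: float
    clarity: str  # "clear" | "unclear"
    direction: str  # "increase" | "trivial" | "decrease"
    qualifier: str

    def phrase(self) -> str:
        """Human-readable summary, e.g. "'likely' substantial increase"."""
        if self.clarity == "unclear":
            return f"{self.label}: unclear"
        noun = {"increase": "increase", "decrease": "decrease", "trivial": "trivial"}[
            self.direction
        ]
        return (
            f"{self.label}: {self.effect_pct:+.1f}% "
            f"({self.ci95_pct[0]:.1f}, {self.ci95_pct[1]:.1f}%), "
            f"'{self.qualifier}' {noun}"
        )


def smallest_worthwhile_effect(sigma_between_log: float) -> float:
    """0.20 x between-subject SD, on the log scale."""
    if sigma_between_log <= 0:
        raise DomainError(
            f"between-subject SD must be positive, got {sigma_between_log}"
        )
    return SWE_STANDARDISED * sigma_between_log


def substantiality_probabilities(
    effect_log: float, se_log: float, df: float, swe_log: float
) -> tuple[float, float, float]:
    """(p_positive, p_trivial, p_negative) under a central t on df."""
    if se_log <= 0:
        raise DomainError(f"standard error must be positive, got {se_log}")
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    p_pos = float(stats.t.sf((swe_log - effect_log) / se_log, df))
    p_neg = float(stats.t.cdf((-swe_log - effect_log) / se_log, df))
    return p_pos, 1.0 - p_pos - p_neg, p_neg


def classify_effect(
    p_positive: float, p_trivial: float, p_negative: float
) -> tuple[str, str, str]:
    """(clarity, direction, qualifier) from the substantiality probabilities.

    Unclear iff both crossing probabilities exceed 5%.  Otherwise the
    direction is the most probable category (ties resolved to trivial) and
    the qualifier is the scale bin containing that category's probability.
    """
    if p_positive > UNCLEAR_CROSSING_PROB and p_negative > UNCLEAR_CROSSING_PROB:
        return "unclear", "trivial", "unclear"
    probs = {"increase": p_positive, "trivial": p_trivial, "decrease": p_negative}
    best = max(probs.values())
    direction = "trivial" if probs["trivial"] == best else max(probs, key=probs.get)
    p = probs[direction]
    qualifier = next(q for lo, q in _QUALIFIER_BINS if p >= lo)
    return "clear", direction, qualifier


def build_effect(
    label: str, effect_log: float, se_log: float, df: float, swe_log: float
) -> MBIEffect:
    """Assemble a full MBIEffect: back-transform, 95% CI, probabilities, label."""
    p_pos, p_triv, p_neg = substantiality_probabilities(effect_log, se_log, df, swe_log)
    clarity, direction, qualifier = classify_effect(p_pos, p_triv, p_neg)
    tcrit = float(stats.t.ppf(0.975, df))
    lo, hi = effect_log - tcrit * se_log, effect_log + tcrit * se_log
    return MBIEffect(
        label=label,
        effect_log=effect_log,
        se_log=se_log,
        df=df,
        effect_pct=100.0 * (np.exp(effect_log) - 1.0),
        ci95_pct=(100.0 * (np.exp(lo) - 1.0), 100.0 * (np.exp(hi) - 1.0)),
        swe_log=swe_log,
        p_positive=p_pos,
        p_trivial=p_triv,
        p_negative=p_neg,
        clarity=clarity,
        direction=direction,
        qualifier=qualifier,
    )


# ---------------------------------------------------------------------------
# Contrast builders over a fitted variance model

_NUMERIC_TERMS = {"age": "age", "injury_level": "injury_level", "wear_time": "wear_time"}


def covariate_effect(vc: VarianceComponents, covariate: str) -> MBIEffect:
    """Effect of a covariate on the outcome, MBI-classified.

    Numeric covariates are evaluated as the change from a typically-low
    (mean - 1 SD) to a typically-high (mean + 1 SD) value, i.e. 2 SD x beta,
    making magnitudes comparable across covariates regardless of units.
    The categorical sex covariate is the male-female level difference.
    """
    swe = smallest_worthwhile_effect(float(np.sqrt(max(vc.sigma2_between, 0.0))))
    if covariate == "sex":
        term = "sex[male]"
        if term not in vc.fixed_effects:
            raise DomainError("sex was not fitted in the model")
        fe = vc.fixed_effects[term]
        return build_effect("sex male-female", fe.beta, fe.se, vc.df_resid, swe)
    if covariate in _NUMERIC_TERMS:
        term = _NUMERIC_TERMS[covariate]
        if term not in vc.fixed_effects:
            raise DomainError(f"{covariate} was not fitted in the model")
        fe = vc.fixed_effects[term]
        sd_x = float(vc.exog[term].std(ddof=1))
        return build_effect(
            f"2 SD {covariate}", 2.0 * sd_x * fe.beta, 2.0 * sd_x * fe.se, vc.df_resid, swe
        )
    raise DomainError(f"unknown covariate {covariate!r}")


def order_effect(vc: VarianceComponents, n_days: int = 7) -> MBIEffect:
    """Day-1 to day-``n_days`` change implied by the linear order term."""
    if "order_index" not in vc.fixed_effects:
        raise DomainError("order_index was not fitted as a linear fixed effect")
    fe = vc.fixed_effects["order_index"]
    span = float(n_days - 1)
    swe = smallest_worthwhile_effect(float(np.sqrt(max(vc.sigma2_between, 0.0))))
    return build_effect(
        f"order day1->day{n_days}", span * fe.beta, span * fe.se, vc.df_resid, swe
    )


@dataclass
class DayOfWeekResult:
    """Adjusted daily means, all pairwise contrasts and the extreme-day effect."""

    adjusted_means: pd.DataFrame  # day, mean, lo95, hi95 (raw outcome scale)
    pairwise: pd.DataFrame  # day_a, day_b, effect_pct, lo95_pct, hi95_pct, p_value
    highest_lowest: MBIEffect
    highest_day: str
    lowest_day: str


def _day_coefficient_vectors(vc: VarianceComponents) -> dict[str, np.ndarray]:
    """Unit contrast vector (over fixed-effect terms) for each present day."""
    present = [d for d in DAYS_OF_WEEK if (vc.model_frame["day_of_week"] == d).any()]
    absent = [d for d in DAYS_OF_WEEK if d not in present]
    for d in absent:
        logger.warning("day level %s absent from data; its contrasts are skipped", d)
    terms = list(vc.fe_params.index)
    vectors = {}
    for d in present:
        v = np.zeros(len(terms))
        col = f"day_of_week[{d}]"
        if col in terms:
            v[terms.index(col)] = 1.0
        vectors[d] = v  # reference day keeps the zero vector
    return vectors


def day_of_week_effects(
    vc: VarianceComponents, holm_adjust: bool = False
) -> DayOfWeekResult:
    """Day-of-week structure of a fitted outcome model.

    Adjusted means hold every other covariate at its observed value and
    average the model prediction over all rows (marginal standardisation),
    back-transformed to the raw scale.  All pairwise day contrasts are
    reported with unadjusted two-sided t p-values (Holm correction
    optional).  The highest-lowest day effect is the back-transformed
    difference between the largest and smallest fitted day coefficients,
    MBI-classified.
    """
    if not any(t.startswith("day_of_week[") for t in vc.fe_params.index) and (
        vc.model_frame["day_of_week"].nunique() <= 1
    ):
        raise DomainError("day_of_week was not fitted as a categorical fixed effect")
    vectors = _day_coefficient_vectors(vc)
    beta = vc.fe_params.to_numpy()
    cov = vc.cov_fe.to_numpy()
    X = vc.exog.to_numpy()
    terms = list(vc.fe_params.index)
    day_cols = {d: f"day_of_week[{d}]" for d in vectors}
    offset = vc.spec.log_offset

    # adjusted means: replace the day dummies row-wise, average predictions
    dow_idx = [i for i, t in enumerate(terms) if t.startswith("day_of_week[")]
    mean_rows = []
    tcrit = float(stats.t.ppf(0.975, vc.df_resid))
    for d, v in vectors.items():
        Xd = X.copy()
        for i in dow_idx:
            Xd[:, i] = v[i]
        g = Xd.mean(axis=0)
        mu = float(g @ beta)
        se = float(np.sqrt(g @ cov @ g))
        mean_rows.append(
            {
                "day": d,
                "mean": np.exp(mu) - offset,
                "lo95": np.exp(mu - tcrit * se) - offset,
                "hi95": np.exp(mu + tcrit * se) - offset,
            }
        )
    adjusted = pd.DataFrame(mean_rows)

    # pairwise contrasts on the log scale
    pair_rows = []
    for a, b in combinations(vectors, 2):
        c = vectors[a] - vectors[b]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        if se == 0:
            logger.warning("contrast %s-%s has zero variance; skipped", a, b)
            continue
        p = float(2.0 * stats.t.sf(abs(est) / se, vc.df_resid))
        pair_rows.append(
            {
                "day_a": a,
                "day_b": b,
                "effect_pct": 100.0 * (np.exp(est) - 1.0),
                "lo95_pct": 100.0 * (np.exp(est - tcrit * se) - 1.0),
                "hi95_pct": 100.0 * (np.exp(est + tcrit * se) - 1.0),
                "p_value": p,
            }
        )
    pairwise = pd.DataFrame(pair_rows)
    if holm_adjust and len(pairwise):
        order = np.argsort(pairwise["p_value"].to_numpy())
        m = len(order)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pairwise["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        pairwise["p_holm"] = adj

    # highest vs lowest fitted day coefficient
    day_effects = {
        d: float(vc.fe_params.get(day_cols[d], 0.0)) for d in vectors
    }
    hi_day = max(day_effects, key=day_effects.get)
    lo_day = min(day_effects, key=day_effects.get)
    c = vectors[hi_day] - vectors[lo_day]
    est = float(c @ beta)
    se = float(np.sqrt(c @ cov @ c))
    swe = smallest_worthwhile_effect(float(np.sqrt(max(vc.sigma2_between, 0.0))))
    if se > 0:
        hl = build_effect(f"highest-lowest day ({hi_day}-{lo_day})", est, se, vc.df_resid, swe)
    else:  # all day effects identical (single day level)
        hl = build_effect(f"highest-lowest day ({hi_day}-{lo_day})", 0.0, 1e-12, vc.df_resid, swe)
    return DayOfWeekResult(
        adjusted_means=adjusted,
        pairwise=pairwise,
        highest_lowest=hl,
        highest_day=hi_day,
        lowest_day=lo_day,
    )


def effects_frame(effects: list[MBIEffect]) -> pd.DataFrame:
    """Tabular view of MBI effects (one row per contrast)."""
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "effect_pct": e.effect_pct,
                "lo95_pct": e.ci95_pct[0],
                "hi95_pct": e.ci95_pct[1],
                "effect_log": e.effect_log,
                "se_log": e.se_log,
                "df": e.df,
                "p_positive": e.p_positive,
                "p_trivial": e.p_trivial,
                "p_negative": e.p_negative,
                "clarity": e.clarity,
                "direction": e.direction,
                "qualifier": e.qualifier,
            }
            for e in effects
        ]
    )
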