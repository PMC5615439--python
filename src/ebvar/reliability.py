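"""Variance decomposition, ICC, Spearman-Brown days-needed and intra-individual CV.

Each daily outcome is log-transformed (natural log, with a configurable
offset for outcomes that can be zero or negative) and modelled with a
random-intercept linear mixed model fitted by REML:

    log(y_ij + offset) = x_ij' beta + u_i + e_ij,
    u_i ~ N(0, sigma2_between),  e_ij ~ N(0, sigma2_within)

where i indexes subjects and j days.  Fixed effects adjust for age, injury
level, wear time, sex, day-of-week and the linear measurement-order index.
The single-day intraclass correlation is the between-subject share of total
variance,

    ICC_s = sigma2_between / (sigma2_between + sigma2_within),

and the number of monitoring days needed for a target reliability ICC_t
follows from the Spearman-Brown prophecy formula,

    N = [ICC_t / (1 - ICC_t)] * [(1 - ICC_s) / ICC_s],

reported as ceil(N) whole days.  Intra-individual coefficients of variation
are computed on the raw scale, per subject, as 100 * SD / mean across that
subject's valid days.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, EstimationError
from .io_model import DAYS_OF_WEEK, DailyRecord, SubjectProfile, records_to_frame

logger = logging.getLogger(__name__)

#: Covariates the study adjusts for, in model order.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "injury_level",
    "wear_time",
    "sex",
    "day_of_week",
    "order_index",
)

DEFAULT_TARGET_ICC = 0.80


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: the outcome, its fixed covariates and the log offset."""

    outcome: str
    fixed_covariates: tuple[str, ...] = DEFAULT_COVARIATES
    log_offset: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.fixed_covariates) - set(DEFAULT_COVARIATES)
        if unknown:
            raise DomainError(f"unknown covariates: {sorted(unknown)}")
        if len(set(self.fixed_covariates)) != len(self.fixed_covariates):
            raise DomainError("fixed_covariates must be distinct")
        if self.log_offset < 0:
            raise DomainError("log_offset must be non-negative")


@dataclass(frozen=True)
class FixedEffect:
    beta: float
    se: float


@dataclass
class VarianceComponents:
    """REML variance components plus everything contrasts downstream need."""

    sigma2_between: float
    sigma2_within: float
    fixed_effects: dict[str, FixedEffect]
    df_resid: int
    n_obs: int
    n_subjects: int
    converged: bool
    spec: ModelSpec
    fe_params: pd.Series = field(repr=False)
    cov_fe: pd.DataFrame = field(repr=False)
    model_frame: pd.DataFrame = field(repr=False)
    exog: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class CVSummary:
    """Per-subject intra-individual CVs with the cohort mean and 95% CI."""

    per_subject: dict[str, float]
    mean_pct: float
    ci95_pct: tuple[float, float]
    n_subjects: int


@dataclass
class ReliabilityResult:
    outcome: str
    icc_single_day: float
    target_icc: float
    days_needed_real: float | None
    days_needed: int | None
    unreliable: bool
    extrapolated: bool
    cv_mean_pct: float
    cv_ci95: tuple[float, float]
    n_subjects: int
    n_days_used: int


# ---------------------------------------------------------------------------
# Transforms


def log_transform(values: Sequence[float] | np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Natural log of (value + offset); every shifted value must be positive."""
    if offset < 0:
        raise DomainError("offset must be non-negative")
    arr = np.asarray(values, dtype=float)
    shifted = arr + offset
    bad = np.flatnonzero(shifted <= 0)
    if bad.size:
        raise DomainError(
            f"value + offset <= 0 at record index {bad[0]} "
            f"(value {arr[bad[0]]}, offset {offset})"
        )
    return np.log(shifted)


def inverse_log_transform(values: np.ndarray, offset: float = 0.0) -> np.ndarray:
    return np.exp(np.asarray(values, dtype=float)) - offset


def auto_offset(values: Sequence[float] | np.ndarray) -> float:
    """Offset policy for zero/negative outcomes: shift so the minimum maps to 1.

    Strictly positive data get offset 0; data whose minimum is 0 (e.g. MVPA
    minutes, alcohol %) get the conventional +1; a negative minimum m (a
    negative derived PAEE day) gets 1 - m.
    """
    m = float(np.min(np.asarray(values, dtype=float)))
    return 0.0 if m > 0 else 1.0 - m


# ---------------------------------------------------------------------------
# Mixed-model fit


def _build_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Fixed-effects design matrix with an explicit intercept.

    Categorical terms use treatment coding: sex relative to female
    (``sex[male]`` is the male-female contrast), day-of-week relative to
    Monday.
    """
    X = pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)
    for cov in covariates:
        if cov == "age":
            X["age"] = df["age"].astype(float)
        elif cov == "injury_level":
            X["injury_level"] = df["injury_level"].astype(float)
        elif cov == "wear_time":
            X["wear_time"] = df["wear_fraction"].astype(float)
        elif cov == "order_index":
            X["order_index"] = df["order_index"].astype(float)
        elif cov == "sex":
            X["sex[male]"] = (df["sex"] == "male").astype(float)
        elif cov == "day_of_week":
            # reference = first present day in Mon..Sun order; absent levels
            # get no column (their contrasts are skipped downstream)
            present = [d for d in DAYS_OF_WEEK if (df["day_of_week"] == d).any()]
            for day in present[1:]:
                X[f"day_of_week[{day}]"] = (df["day_of_week"] == day).astype(float)
        else:  # pragma: no cover - guarded by ModelSpec
            raise DomainError(f"unknown covariate {cov!r}")
    return X


def _check_singularity(X: pd.DataFrame) -> None:
    for col in X.columns:
        if col != "Intercept" and X[col].nunique() <= 1:
            raise EstimationError(f"covariate {col!r} is constant: singular design")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise EstimationError("fixed-effects design matrix is rank deficient")


def fit_variance_model(
    records: Iterable[DailyRecord] | pd.DataFrame,
    subjects: Iterable[SubjectProfile] | None,
    spec: ModelSpec,
) -> VarianceComponents:
    """REML fit of the random-intercept model for one outcome.

    ``records`` may be DailyRecord objects (joined to ``subjects``) or an
    already-joined long DataFrame.  Rows where the outcome is missing are
    dropped.  Requires at least two subjects with two valid days each.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records, subjects)
    if spec.outcome not in df.columns:
        raise DomainError(f"outcome {spec.outcome!r} not present in the data")
    df = df.dropna(subset=[spec.outcome]).copy()
    day_counts = df.groupby("subject_id").size()
    if (day_counts >= 2).sum() < 2:
        raise EstimationError(
            f"outcome {spec.outcome!r}: need >= 2 subjects with >= 2 valid days"
        )
    df["log_y"] = log_transform(df[spec.outcome].to_numpy(), spec.log_offset)

    X = _build_design(df, spec.fixed_covariates)
    _check_singularity(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(df["log_y"].to_numpy(), X, groups=df["subject_id"].to_numpy())
        result = model.fit(reml=True)
        if not result.converged:
            result = model.fit(reml=True, method="powell", start_params=result.params)
        else:
            # simplex polish from the quasi-Newton solution: the default
            # stop leaves O(1e-6) slack in the variance components
            try:
                refined = model.fit(
                    reml=True,
                    start_params=result.params,
                    method="nm",
                    maxiter=2000,
                    xtol=1e-12,
                    ftol=1e-12,
                )
                if refined.converged:
                    result = refined
            except np.linalg.LinAlgError:
                pass
    if not result.converged:
        raise EstimationError(
            f"outcome {spec.outcome!r}: REML did not converge "
            f"(params at stop: {np.asarray(result.params).round(6).tolist()})"
        )

    p = X.shape[1]
    n_subjects = df["subject_id"].nunique()
    df_resid = max(int(len(df) - p - n_subjects), 1)
    fe_params = pd.Series(result.fe_params, index=X.columns)
    cov_fe = pd.DataFrame(
        np.asarray(result.cov_params())[:p, :p], index=X.columns, columns=X.columns
    )
    fixed = {
        name: FixedEffect(beta=float(fe_params[name]), se=float(np.sqrt(cov_fe.loc[name, name])))
        for name in X.columns
    }
    return VarianceComponents(
        sigma2_between=float(np.asarray(result.cov_re)[0, 0]),
        sigma2_within=float(result.scale),
        fixed_effects=fixed,
        df_resid=df_resid,
        n_obs=len(df),
        n_subjects=n_subjects,
        converged=bool(result.converged),
        spec=spec,
        fe_params=fe_params,
        cov_fe=cov_fe,
        model_frame=df,
        exog=X,
    )


# ---------------------------------------------------------------------------
# ICC and the prophecy formula


def icc_from_components(vc: VarianceComponents | tuple[float, float]) -> float:
    """Single-day ICC: between-subject variance over total variance.

    A negative between-subject estimate (possible for moment estimators) is
    truncated to zero before the ratio.
    """
    if isinstance(vc, VarianceComponents):
        s2b, s2w = vc.sigma2_between, vc.sigma2_within
    else:
        s2b, s2w = vc
    s2b = max(s2b, 0.0)
    total = s2b + s2w
    if total <= 0:
        raise DomainError("both variance components are zero; ICC undefined")
    return s2b / total


def days_needed(
    icc_single: float, icc_target: float = DEFAULT_TARGET_ICC
) -> tuple[float, int]:
    """Spearman-Brown prophecy: monitoring days for a target reliability.

    Returns (N as a real number, ceil(N) whole days).  N decreases
    monotonically as the single-day ICC rises and equals 1 when the single
    day already achieves the target.
    """
    for name, v in (("icc_single", icc_single), ("icc_target", icc_target)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must be strictly inside (0, 1), got {v}")
    n_real = (icc_target / (1.0 - icc_target)) * ((1.0 - icc_single) / icc_single)
    # snap float noise (e.g. 0.8/0.2 -> 4.000000000000001) before the ceiling
    n_int = max(1, math.ceil(n_real - 1e-9))
    return n_real, n_int


def spearman_brown_step_up(icc_single: float, n: float) -> float:
    """Reliability of the mean of n days given the single-day ICC."""
    return n * icc_single / (1.0 + (n - 1.0) * icc_single)


# ---------------------------------------------------------------------------
# Intra-individual CV


def intra_individual_cv(
    records: Iterable[DailyRecord] | pd.DataFrame,
    outcome: str,
    min_days: int = 2,
) -> CVSummary:
    """Per-subject day-to-day CV (%) on the raw scale, with a cohort t CI.

    CV_i = 100 * SD_i / mean_i over subject i's valid days (sample SD, ddof
    1).  Subjects with fewer than ``min_days`` days are excluded; a subject
    with mean zero is excluded with a logged warning.  The cohort summary is
    the mean of the per-subject CVs with a 95% CI from the t distribution
    across subjects.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if outcome not in df.columns:
        raise DomainError(f"outcome {outcome!r} not present in the data")
    df = df.dropna(subset=[outcome])

    per_subject: dict[str, float] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        vals = grp[outcome].to_numpy(dtype=float)
        if len(vals) < min_days:
            continue
        mean = vals.mean()
        if mean == 0:
            logger.warning("subject %s: mean %s is zero; excluded from CV", sid, outcome)
            continue
        per_subject[str(sid)] = float(100.0 * vals.std(ddof=1) / mean)

    if not per_subject:
        raise DomainError(f"outcome {outcome!r}: no subject has >= {min_days} usable days")
    cvs = np.array(list(per_subject.values()))
    mean_cv = float(cvs.mean())
    if len(cvs) > 1:
        half = float(stats.t.ppf(0.975, len(cvs) - 1) * cvs.std(ddof=1) / np.sqrt(len(cvs)))
    else:
        half = float("nan")
    return CVSummary(
        per_subject=per_subject,
        mean_pct=mean_cv,
        ci95_pct=(mean_cv - half, mean_cv + half),
        n_subjects=len(cvs),
    )


# ---------------------------------------------------------------------------
# Assembled per-outcome table


def reliability_table(
    records: Iterable[DailyRecord] | pd.DataFrame,
    subjects: Iterable[SubjectProfile] | None,
    outcomes: Sequence[str],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    target_icc: float = DEFAULT_TARGET_ICC,
    log_offsets: Mapping[str, float] | None = None,
) -> list[ReliabilityResult]:
    """One ReliabilityResult per outcome: ICC, days needed, CV.

    ``log_offsets`` overrides the automatic offset policy per outcome (see
    :func:`auto_offset`).  An outcome whose between-subject variance
    collapses to zero cannot reach any reliability target by adding days; it
    is reported with ``unreliable=True`` and no day count.  Rows whose day
    requirement exceeds the observed monitoring span are flagged
    ``extrapolated`` (prophecy projections beyond the observed span lose
    precision).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records, subjects)
    results = []
    for outcome in outcomes:
        sub = df.dropna(subset=[outcome])
        offset = (
            float(log_offsets[outcome])
            if log_offsets and outcome in log_offsets
            else auto_offset(sub[outcome].to_numpy())
        )
        spec = ModelSpec(outcome=outcome, fixed_covariates=tuple(covariates), log_offset=offset)
        vc = fit_variance_model(df, None, spec)
        icc = icc_from_components(vc)
        try:
            n_real, n_int = days_needed(icc, target_icc)
            unreliable = False
        except DomainError:
            n_real, n_int, unreliable = None, None, True
        cv = intra_individual_cv(df, outcome)
        max_span = int(sub.groupby("subject_id").size().max())
        results.append(
            ReliabilityResult(
                outcome=outcome,
                icc_single_day=icc,
                target_icc=target_icc,
                days_needed_real=n_real,
                days_needed=n_int,
                unreliable=unreliable,
                extrapolated=bool(n_int is not None and n_int > max_span),
                cv_mean_pct=cv.mean_pct,
                cv_ci95=cv.ci95_pct,
                n_subjects=vc.n_subjects,
                n_days_used=max_span,
            )
        )
    return results


def reliability_frame(results: Sequence[ReliabilityResult]) -> pd.DataFrame:
    """Tabular view of reliability results (one row per outcome)."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "icc_single_day": r.icc_single_day,
                "days_needed_real": r.days_needed_real,
                "days_needed": r.days_needed,
                "unreliable": r.unreliable,
                "extrapolated": r.extrapolated,
                "cv_mean_pct": r.cv_mean_pct,
                "cv_lo_pct": r.cv_ci95[0],
                "cv_hi_pct": r.cv_ci95[1],
                "n_subjects": r.n_subjects,
                "n_days_used": r.n_days_used,
            }
            for r in results
        ]
    )
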