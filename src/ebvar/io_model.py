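"""Data model, delimited-text I/O, wear-time validity and epoch aggregation.

The analysis operates on three long-format tables:

* a **subject table** — one row per participant with age, sex, spinal-injury
  level (vertebral string such as ``"T7"``) and measured resting metabolic
  rate (RMR, kcal/day);
* a **daily table** — one row per subject-day with monitor wear minutes,
  day-of-week, the measurement-order index (1..7) and the outcome columns
  (energy expenditure, activity minutes, energy intake, macronutrient
  percentages);
* optionally a **minute-epoch stream** — one row per minute with a MET value
  and a worn flag, which :func:`aggregate_epochs` collapses into the daily
  activity-minute outcomes.

A monitoring day is *valid* when the device was worn for strictly more than
a configurable fraction of the day (default 80% of 1440 min, i.e. > 1152
min); :func:`filter_valid_days` applies that rule.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DomainError, IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Outcome columns understood by the default schema, in canonical order.
OUTCOME_COLUMNS: tuple[str, ...] = (
    "tee_kcal",
    "paee_kcal",
    "pal",
    "sedentary_min",
    "light_min",
    "mvpa_min",
    "intake_kcal",
    "protein_pct",
    "fat_pct",
    "carb_pct",
    "alcohol_pct",
)

DAYS_OF_WEEK: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

MINUTES_PER_DAY = 1440


def _build_vertebral_coding() -> dict[str, int]:
    # Consecutive integers down the spinal column; larger = lower (more
    # caudal) lesion, so "a 2 SD increase in injury level" means a lower
    # lesion.  Override by passing a custom mapping to parse_injury_level.
    coding: dict[str, int] = {}
    code = 1
    for prefix, count in (("C", 7), ("T", 12), ("L", 5), ("S", 5)):
        for i in range(1, count + 1):
            coding[f"{prefix}{i}"] = code
            code += 1
    return coding


#: Default vertebral-level coding: C1=1..C7=7, T1=8..T12=19, L1=20..L5=24, S1=25..S5=29.
VERTEBRAL_CODING: Mapping[str, int] = _build_vertebral_coding()


def parse_injury_level(level: str, coding: Mapping[str, int] | None = None) -> int:
    """Map a vertebral-level string like ``"T7"`` to its ordinal code."""
    coding = VERTEBRAL_CODING if coding is None else coding
    key = level.strip().upper()
    if key not in coding:
        raise ParseError(f"unknown injury level {level!r}; expected one of C1..S5")
    return coding[key]


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject covariates used as fixed effects in the variance models."""

    subject_id: str
    age: float
    sex: str
    injury_level_code: int
    rmr: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise DomainError(f"subject {self.subject_id}: age must be positive")
        if self.rmr <= 0:
            raise DomainError(f"subject {self.subject_id}: rmr must be positive")
        if self.sex not in ("male", "female"):
            raise DomainError(
                f"subject {self.subject_id}: sex must be 'male' or 'female', got {self.sex!r}"
            )
        if not 1 <= self.injury_level_code <= max(VERTEBRAL_CODING.values()):
            raise DomainError(
                f"subject {self.subject_id}: injury_level_code {self.injury_level_code} "
                "outside the vertebral coding range"
            )


@dataclass
class DailyRecord:
    """One subject-day: wear time, design variables and outcome values.

    ``outcomes`` maps outcome name to a non-negative value; an outcome that
    was not observed on that day is simply absent from the mapping (never
    stored as zero).
    """

    subject_id: str
    order_index: int
    day_of_week: str
    wear_minutes: float
    outcomes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.wear_minutes <= MINUTES_PER_DAY:
            raise DomainError(
                f"{self.subject_id} day {self.order_index}: wear_minutes "
                f"{self.wear_minutes} outside [0, {MINUTES_PER_DAY}]"
            )
        if self.day_of_week not in DAYS_OF_WEEK:
            raise DomainError(
                f"{self.subject_id} day {self.order_index}: day_of_week must be one "
                f"of {DAYS_OF_WEEK}, got {self.day_of_week!r}"
            )
        bands = [self.outcomes.get(k) for k in ("sedentary_min", "light_min", "mvpa_min")]
        if all(v is not None for v in bands):
            if sum(bands) > self.wear_minutes + 1.0:  # 1-minute rounding tolerance
                raise IntegrityError(
                    f"{self.subject_id} day {self.order_index}: activity band minutes "
                    f"{sum(bands):.1f} exceed wear minutes {self.wear_minutes:.1f}"
                )
        macros = [self.outcomes.get(k) for k in ("protein_pct", "fat_pct", "carb_pct", "alcohol_pct")]
        if all(v is not None for v in macros) and abs(sum(macros) - 100.0) > 0.5:
            raise IntegrityError(
                f"{self.subject_id} day {self.order_index}: macronutrient percentages "
                f"sum to {sum(macros):.2f}, expected 100 ± 0.5"
            )


@dataclass(frozen=True)
class MinuteEpoch:
    """One minute of monitor output: a MET value and whether it was worn."""

    subject_id: str
    timestamp: _dt.datetime
    met: float
    worn: bool

    def __post_init__(self) -> None:
        if self.met < 0:
            raise DomainError(f"{self.subject_id} {self.timestamp}: negative MET value")


@dataclass(frozen=True)
class METBands:
    """Intensity band boundaries in metabolic equivalents.

    Sedentary behaviour is below ``light_lower``; light activity is
    [``light_lower``, ``mvpa_lower``); moderate-to-vigorous activity (MVPA)
    is at or above ``mvpa_lower``.
    """

    light_lower: float = 1.5
    mvpa_lower: float = 3.0

    def classify(self, met: float) -> str:
        if met < self.light_lower:
            return "sedentary"
        if met < self.mvpa_lower:
            return "light"
        return "mvpa"


# ---------------------------------------------------------------------------
# Table I/O


_REQUIRED_DAILY_COLUMNS = ("subject_id", "order_index", "day_of_week", "wear_minutes")


def read_daily_table(
    path: str | Path, schema: Sequence[str] | None = None
) -> list[DailyRecord]:
    """Read a delimited daily table into :class:`DailyRecord` objects.

    Parameters
    ----------
    path
        CSV/TSV file with a header row (delimiter sniffed from the header).
    schema
        Outcome column names to parse. ``None`` parses every non-required
        column as an outcome, so unknown outcome columns are preserved under
        their header names.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.open().readline() else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in _REQUIRED_DAILY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    outcome_cols = (
        [c for c in df.columns if c not in _REQUIRED_DAILY_COLUMNS]
        if schema is None
        else list(schema)
    )
    for col in outcome_cols:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing outcome column {col!r}")

    records: list[DailyRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        row_d = dict(zip(df.columns, row))
        try:
            order = int(row_d["order_index"])
            wear = float(row_d["wear_minutes"])
        except ValueError as exc:
            raise ParseError(f"{path.name} row {i}: {exc}") from exc
        key = (row_d["subject_id"], order)
        if key in seen:
            raise IntegrityError(
                f"{path.name} row {i}: duplicate (subject_id, order_index) = {key}"
            )
        seen.add(key)
        outcomes: dict[str, float] = {}
        for col in outcome_cols:
            cell = row_d[col].strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue  # missing outcomes stay absent, never zero
            try:
                outcomes[col] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} row {i}: non-numeric value {cell!r} in column {col!r}"
                ) from exc
        records.append(
            DailyRecord(
                subject_id=row_d["subject_id"],
                order_index=order,
                day_of_week=row_d["day_of_week"],
                wear_minutes=wear,
                outcomes=outcomes,
            )
        )
    return records


def write_daily_table(records: Iterable[DailyRecord], path: str | Path) -> None:
    """Write records as CSV; outcome columns in canonical-then-alphabetic order."""
    records = list(records)
    extra = sorted(
        {k for r in records for k in r.outcomes} - set(OUTCOME_COLUMNS)
    )
    cols = [c for c in OUTCOME_COLUMNS if any(c in r.outcomes for r in records)] + extra
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "order_index": r.order_index,
            "day_of_week": r.day_of_week,
            "wear_minutes": repr(r.wear_minutes),
        }
        for c in cols:
            row[c] = "" if c not in r.outcomes else repr(r.outcomes[c])
        rows.append(row)
    pd.DataFrame(rows, columns=list(_REQUIRED_DAILY_COLUMNS) + cols).to_csv(
        path, index=False
    )


def read_subject_table(
    path: str | Path, coding: Mapping[str, int] | None = None
) -> list[SubjectProfile]:
    """Read the subject table (subject_id, age, sex, injury_level, rmr_kcal)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("subject_id", "age", "sex", "injury_level", "rmr_kcal"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    subjects = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        if d["subject_id"] in seen:
            raise IntegrityError(f"{path.name} row {i}: duplicate subject_id {d['subject_id']!r}")
        seen.add(d["subject_id"])
        try:
            subjects.append(
                SubjectProfile(
                    subject_id=d["subject_id"],
                    age=float(d["age"]),
                    sex=d["sex"].strip().lower(),
                    injury_level_code=parse_injury_level(d["injury_level"], coding),
                    rmr=float(d["rmr_kcal"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path.name} row {i}: {exc}") from exc
    return subjects


def write_subject_table(subjects: Iterable[SubjectProfile], path: str | Path) -> None:
    inverse = {v: k for k, v in VERTEBRAL_CODING.items()}
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": repr(s.age),
                "sex": s.sex,
                "injury_level": inverse[s.injury_level_code],
                "rmr_kcal": repr(s.rmr),
            }
            for s in subjects
        ]
    ).to_csv(path, index=False)


def read_epoch_file(path: str | Path) -> list[MinuteEpoch]:
    """Read a minute-epoch CSV (subject_id, timestamp ISO-8601, met, worn 0/1)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("subject_id", "timestamp", "met", "worn"):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    epochs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            epochs.append(
                MinuteEpoch(
                    subject_id=d["subject_id"],
                    timestamp=_dt.datetime.fromisoformat(d["timestamp"]),
                    met=float(d["met"]),
                    worn=bool(int(d["worn"])),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path.name} row {i}: {exc}") from exc
    return epochs


# ---------------------------------------------------------------------------
# Valid-day filtering and epoch aggregation


def filter_valid_days(
    records: Iterable[DailyRecord],
    cutoff_fraction: float = 0.80,
    day_minutes: int = MINUTES_PER_DAY,
) -> list[DailyRecord]:
    """Keep days with wear time *strictly greater* than the cut-off.

    With the defaults a day qualifies only when worn > 0.80 x 1440 = 1152
    minutes; a day at exactly 1152 is excluded.  Input order is preserved and
    the per-subject valid-day counts are logged at INFO level.
    """
    if not 0 < cutoff_fraction <= 1:
        raise DomainError(f"cutoff_fraction must be in (0, 1], got {cutoff_fraction}")
    threshold = cutoff_fraction * day_minutes
    kept = [r for r in records if r.wear_minutes > threshold]
    counts = Counter(r.subject_id for r in kept)
    for sid in sorted(counts):
        logger.info("subject %s: %d valid day(s)", sid, counts[sid])
    return kept


def valid_day_counts(records: Iterable[DailyRecord]) -> dict[str, int]:
    """Per-subject day counts of an (already filtered) record collection."""
    return dict(Counter(r.subject_id for r in records))


def aggregate_epochs(
    epochs: Iterable[MinuteEpoch], bands: METBands = METBands()
) -> pd.DataFrame:
    """Collapse minute epochs into per-day wear and intensity-band minutes.

    Non-worn epochs contribute to no band (they are missing data, not
    sedentary time), so the band minutes always sum exactly to the wear
    minutes.  Returns a DataFrame with one row per (subject_id, date) and
    columns wear_minutes, sedentary_min, light_min, mvpa_min.

    Raises :class:`IntegrityError` on duplicate or gapped timestamps within
    a day (epochs must cover whole days at one-minute resolution).
    """
    by_day: dict[tuple[str, _dt.date], list[MinuteEpoch]] = {}
    for e in epochs:
        by_day.setdefault((e.subject_id, e.timestamp.date()), []).append(e)

    rows = []
    for (sid, day), day_epochs in sorted(by_day.items()):
        day_epochs.sort(key=lambda e: e.timestamp)
        minutes = [e.timestamp.hour * 60 + e.timestamp.minute for e in day_epochs]
        if len(set(minutes)) != len(minutes):
            raise IntegrityError(f"subject {sid} {day}: duplicate epoch timestamp")
        if len(minutes) != MINUTES_PER_DAY or minutes != list(range(MINUTES_PER_DAY)):
            raise IntegrityError(
                f"subject {sid} {day}: expected {MINUTES_PER_DAY} one-minute epochs, "
                f"got {len(minutes)} (gap or partial day)"
            )
        counts = Counter(bands.classify(e.met) for e in day_epochs if e.worn)
        wear = sum(counts.values())
        rows.append(
            {
                "subject_id": sid,
                "date": day,
                "wear_minutes": wear,
                "sedentary_min": counts.get("sedentary", 0),
                "light_min": counts.get("light", 0),
                "mvpa_min": counts.get("mvpa", 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "date", "wear_minutes", "sedentary_min", "light_min", "mvpa_min"],
    )


# ---------------------------------------------------------------------------
# DataFrame bridge used by the statistical modules


def records_to_frame(
    records: Iterable[DailyRecord], subjects: Iterable[SubjectProfile] | None = None
) -> pd.DataFrame:
    """Long-format DataFrame of daily records, optionally joined to subjects.

    Outcome values missing on a given day become NaN.  When ``subjects`` is
    given, adds age, sex, injury_level and rmr columns plus ``wear_fraction``
    (wear_minutes / 1440), the form in which wear time enters the models.
    """
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "order_index": r.order_index,
            "day_of_week": r.day_of_week,
            "wear_minutes": r.wear_minutes,
            "wear_fraction": r.wear_minutes / MINUTES_PER_DAY,
        }
        row.update(r.outcomes)
        rows.append(row)
    df = pd.DataFrame(rows)
    if subjects is not None:
        sdf = pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "age": s.age,
                    "sex": s.sex,
                    "injury_level": s.injury_level_code,
                    "rmr": s.rmr,
                }
                for s in subjects
            ]
        )
        missing = set(df["subject_id"]) - set(sdf["subject_id"])
        if missing:
            raise IntegrityError(f"daily records reference unknown subjects: {sorted(missing)}")
        df = df.merge(sdf, on="subject_id", how="left")
    return df
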