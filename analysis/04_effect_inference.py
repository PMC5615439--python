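"""Covariate, measurement-order and day-of-week effects with MBI labels.

For each outcome the fitted mixed model yields: 2-SD covariate effects
(age, injury level, wear time) and the sex contrast; the linear day-1 to
day-7 order drift; and day-of-week adjusted means with pairwise contrasts
and the highest-lowest day effect.  Every effect is back-transformed to a
percent change and classified by magnitude-based inference.  Writes
results/mbi_effects.csv, results/day_of_week_means.csv and
results/day_of_week_contrasts.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ebvar.io_model import filter_valid_days, read_daily_table, read_subject_table, records_to_frame
from ebvar.mbi import covariate_effect, day_of_week_effects, effects_frame, order_effect
from ebvar.reliability import ModelSpec, auto_offset, fit_variance_model

ROOT = Path(__file__).resolve().parents[1]

OUTCOMES = [
    "tee_kcal", "paee_kcal", "pal", "sedentary_min", "light_min", "mvpa_min",
    "intake_kcal", "protein_pct", "fat_pct", "carb_pct", "alcohol_pct",
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    subjects = read_subject_table(args.cohort_dir / "subjects.csv")
    records = filter_valid_days(read_daily_table(args.cohort_dir / "daily.csv"))
    df = records_to_frame(records, subjects)

    all_effects, labels, mean_rows, contrast_rows = [], [], [], []
    for outcome in OUTCOMES:
        sub = df.dropna(subset=[outcome])
        spec = ModelSpec(outcome=outcome, log_offset=auto_offset(sub[outcome].to_numpy()))
        vc = fit_variance_model(df, None, spec)
        for cov in ("age", "injury_level", "wear_time", "sex"):
            all_effects.append(covariate_effect(vc, cov))
            labels.append(outcome)
        all_effects.append(order_effect(vc))
        labels.append(outcome)
        dow = day_of_week_effects(vc)
        m = dow.adjusted_means.copy()
        m.insert(0, "outcome", outcome)
        mean_rows.append(m)
        c = dow.pairwise.copy()
        c.insert(0, "outcome", outcome)
        contrast_rows.append(c)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    eff = effects_frame(all_effects)
    eff.insert(0, "outcome", labels)
    eff.to_csv(args.out_dir / "mbi_effects.csv", index=False)
    pd.concat(mean_rows, ignore_index=True).to_csv(
        args.out_dir / "day_of_week_means.csv", index=False
    )
    pd.concat(contrast_rows, ignore_index=True).to_csv(
        args.out_dir / "day_of_week_contrasts.csv", index=False
    )

    clear = eff[(eff.clarity == "clear") & (eff.direction != "trivial")]
    print("clear non-trivial effects:")
    for _, r in clear.iterrows():
        print(
            f"  {r.outcome:<14s} {r.label:<22s} {r.effect_pct:+6.1f}% "
            f"({r.lo95_pct:.0f}, {r.hi95_pct:.0f}%)  '{r.qualifier}' {r.direction}"
        )
    print(f"tables written to {args.out_dir}")


if __name__ == "__main__":
    main()
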