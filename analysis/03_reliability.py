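"""How many monitoring days does each energy-balance outcome need?

Fits the covariate-adjusted random-intercept model to each log-transformed
outcome, takes the single-day ICC from the variance components, projects to
the 0.80 reliability target with the Spearman-Brown prophecy formula, and
summarises day-to-day variability as intra-individual CVs.  Writes
results/reliability.csv.
"""

import argparse
from pathlib import Path

from ebvar.io_model import filter_valid_days, read_daily_table, read_subject_table, records_to_frame
from ebvar.reliability import reliability_frame, reliability_table

ROOT = Path(__file__).resolve().parents[1]

OUTCOMES = [
    "tee_kcal", "paee_kcal", "pal", "sedentary_min", "light_min", "mvpa_min",
    "intake_kcal", "protein_pct", "fat_pct", "carb_pct", "alcohol_pct",
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "reliability.csv")
    parser.add_argument("--target-icc", type=float, default=0.80)
    args = parser.parse_args()

    subjects = read_subject_table(args.cohort_dir / "subjects.csv")
    records = filter_valid_days(read_daily_table(args.cohort_dir / "daily.csv"))
    df = records_to_frame(records, subjects)

    results = reliability_table(df, None, OUTCOMES, target_icc=args.target_icc)
    table = reliability_frame(results)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    print(f"monitoring days needed for ICC > {args.target_icc:.2f} (single-day ICC, CV):")
    for r in sorted(results, key=lambda r: r.days_needed or 999):
        flag = " [beyond observed week]" if r.extrapolated else ""
        print(
            f"  {r.outcome:<14s} {r.days_needed:>3d} day(s)   "
            f"ICC_s={r.icc_single_day:.2f}   CV={r.cv_mean_pct:.0f}% "
            f"({r.cv_ci95[0]:.0f}-{r.cv_ci95[1]:.0f}%){flag}"
        )
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
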