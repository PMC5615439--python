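"""Partition daily energy expenditure and intake into their components.

For each subject-day, total energy expenditure (TEE) splits into resting
metabolic rate (RMR), diet-induced thermogenesis (10% of TEE) and physical
activity energy expenditure; intake splits into macronutrient kcal.
Writes results/energy_balance.csv and prints the cohort-mean partition.
"""

import argparse
from pathlib import Path

from ebvar.io_model import filter_valid_days, read_daily_table, read_subject_table, records_to_frame
from ebvar.report import energy_balance_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort-dir", type=Path, default=ROOT / "results" / "cohort")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "energy_balance.csv")
    args = parser.parse_args()

    subjects = read_subject_table(args.cohort_dir / "subjects.csv")
    records = filter_valid_days(read_daily_table(args.cohort_dir / "daily.csv"))
    df = records_to_frame(records, subjects)

    eb = energy_balance_summary(df)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    eb.to_csv(args.out, index=False)

    for side in ("expenditure", "intake"):
        rows = eb[eb["side"] == side]
        print(f"{side}:")
        for _, r in rows.iterrows():
            print(f"  {r.component:<13s} {r.mean_kcal:7.0f} kcal/d  ({r.share_pct:.1f}%)")
    print(f"table written to {args.out}")


if __name__ == "__main__":
    main()
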