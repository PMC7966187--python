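#!/usr/bin/env python
"""Apply the maximal-effort screen and summarise the cohort by stratum.

Reads results/cohort.csv, removes records failing RER >= 1.0 or
HRmax >= 85% of the Tanaka prediction (plus athlete/smoker/BMI rules),
writes the kept and excluded sets, the per-(sex, age-band) mean +/- SD
summary table, and the male-referenced sex-difference percentages.
"""

from pathlib import Path

import pandas as pd

from vo2ref.records import (
    Sex,
    apply_exclusions,
    read_cohort_csv,
    sex_difference_percent,
    summaries_to_frame,
    summarize_cohort,
    write_cohort_csv,
    write_exclusions_csv,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    cohort, errors = read_cohort_csv(SCRATCH / "cohort.csv")
    assert not errors, errors
    included, excluded = apply_exclusions(cohort)
    RESULTS.mkdir(exist_ok=True)
    write_cohort_csv(included, SCRATCH / "cohort_maximal.csv")
    write_exclusions_csv(excluded, SCRATCH / "cohort_excluded.csv")
    print(f"kept {len(included)} of {len(cohort)} "
          f"({100 * len(excluded) / len(cohort):.1f}% excluded)")
    reasons = pd.Series([r for _, r in excluded]).value_counts()
    print("exclusion reasons:", reasons.to_dict())

    summaries = summarize_cohort(included)
    frame = summaries_to_frame(summaries)
    frame.to_csv(RESULTS / "stratum_summaries.csv", index=False)
    print(f"wrote {len(frame)} strata to stratum_summaries.csv")

    male_mean = frame[frame.sex == "male"]
    female_mean = frame[frame.sex == "female"]
    overall_m = sum(r.vo2max_rel for r in included if r.sex is Sex.MALE) / sum(
        1 for r in included if r.sex is Sex.MALE
    )
    overall_f = sum(r.vo2max_rel for r in included if r.sex is Sex.FEMALE) / sum(
        1 for r in included if r.sex is Sex.FEMALE
    )
    print(f"overall VO2max/kg: males {overall_m:.2f}, females {overall_f:.2f}, "
          f"sex difference {sex_difference_percent(overall_m, overall_f):.1f}%")
    for band in male_mean.age_band:
        m = male_mean[male_mean.age_band == band]["vo2max_rel_mean"]
        f = female_mean[female_mean.age_band == band]["vo2max_rel_mean"]
        if len(m) and len(f):
            diff = sex_difference_percent(float(m.iloc[0]), float(f.iloc[0]))
            print(f"  band {band}: sex difference {diff:.1f}%")


if __name__ == "__main__":
    main()
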