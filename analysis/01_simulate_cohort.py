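#!/usr/bin/env python
"""Simulate a registry-like CPET cohort.

Draws the default synthetic cohort (n = 4612, ~3.9:1 male:female, ages
6-65 concentrated in the working decades) with 10% injected
submaximal-effort records, and writes it to results/cohort.csv.
"""

import argparse
from collections import Counter
from pathlib import Path

from vo2ref.cohort import CohortSpec, generate_cohort
from vo2ref.records import age_band_label, write_cohort_csv

# per-subject tables are bulky intermediates: they go under scratch/ and are
# regenerated by re-running this script; derived tables live in results/
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20240612)
    parser.add_argument("--n", type=int, default=4612)
    parser.add_argument("--submaximal-fraction", type=float, default=0.1)
    args = parser.parse_args()

    spec = CohortSpec(n=args.n, submaximal_fraction=args.submaximal_fraction, seed=args.seed)
    cohort = generate_cohort(spec)
    SCRATCH.mkdir(exist_ok=True)
    out = SCRATCH / "cohort.csv"
    write_cohort_csv(cohort, out)

    n_male = sum(r.sex.value == "male" for r in cohort)
    bands = Counter(age_band_label(r.age) for r in cohort)
    print(f"wrote {len(cohort)} records to {out}")
    print(f"  males {n_male}, females {len(cohort) - n_male} "
          f"(male fraction {n_male / len(cohort):.3f})")
    print(f"  band counts: {dict(sorted(bands.items()))}")
    print(f"  injected submaximal fraction: {spec.submaximal_fraction}")


if __name__ == "__main__":
    main()
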