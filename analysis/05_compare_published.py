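#!/usr/bin/env python
"""Compare the study's reference equations with legacy published models.

Builds the model × age grid (Jones, Wasserman, Cooper, and this study's
median polynomials) on the ml·min⁻¹·kg⁻¹ scale, using the cohort's
per-stratum mean weights where a formula predicts absolute VO2max, and
writes it to results/comparison_table.csv.
"""

from pathlib import Path

from vo2ref.equations import comparison_table, comparison_to_csv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = comparison_table()
    comparison_to_csv(table, RESULTS / "comparison_table.csv")
    print(table.to_string(index=False))
    print("\n'x' marks ages a source declares unsuitable; values are one-decimal, half-up.")


if __name__ == "__main__":
    main()
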