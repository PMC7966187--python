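"""Measured-vs-predicted agreement on a holdout cohort.

Agreement is assessed with the paired-samples t-test on per-subject
differences d = predicted − measured, so a positive mean difference means
the reference equation over-predicts.  Two-sided p-values throughout;
differences significant at α = 0.05 are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equations import PublishedModel, get_model
from .records import CpetRecord, EffortCriteria, Sex, apply_exclusions

__all__ = ["ALPHA", "PairedComparison", "paired_compare", "crossval_report",
           "report_to_frame", "format_report"]

ALPHA = 0.05

#: Sign convention, quoted in every report.
SIGN_NOTE = "positive mean difference = equation over-predicts (predicted - measured)"


@dataclass(frozen=True)
class PairedComparison:
    """Paired-difference summary: d = predicted − measured."""

    n: int
    mean_diff: float
    sd_diff: float
    t_stat: float              # NaN when sd_diff = 0
    p_value: float             # NaN when degenerate
    degenerate: bool = False   # zero-variance differences: t/p undefined
    note: str = SIGN_NOTE

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < ALPHA

    def summary(self) -> str:
        if self.degenerate:
            return (
                f"mean difference {self.mean_diff:.2f} ± {self.sd_diff:.2f} "
                f"ml·min⁻¹·kg⁻¹ (n={self.n}); zero-variance differences, "
                "t-test degenerate"
            )
        return (
            f"mean difference {self.mean_diff:.2f} ± {self.sd_diff:.2f} "
            f"ml·min⁻¹·kg⁻¹ (n={self.n}), p = {self.p_value:.3f}"
            f"{' (significant)' if self.significant else ''}"
        )


def paired_compare(measured: Sequence[float], predicted: Sequence[float]) -> PairedComparison:
    """Paired t-test of predicted against measured values.

    Mean and SD (n−1 denominator) of the differences, t with n−1 degrees
    of freedom, two-sided p.  Zero-variance differences are reported as a
    degenerate comparison rather than an arbitrary p.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.ndim != 1:
        raise ValueError("measured and predicted must be equal-length 1-D sequences")
    n = len(measured)
    if n < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    d = predicted - measured
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedComparison(n, mean, sd, float("nan"), float("nan"), degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedComparison(n, mean, sd, float(t), float(p))


def crossval_report(
    holdout: Iterable[CpetRecord],
    model: PublishedModel | str = "lowlands",
    criteria: EffortCriteria | None = None,
    apply_effort_filter: bool = True,
    training_ids: set[str] | None = None,
) -> dict[Sex, PairedComparison]:
    """Per-sex measured-vs-predicted comparison on a holdout cohort.

    Effort criteria are applied to the holdout by default (disable with
    ``apply_effort_filter=False`` — whether a validation sample should be
    re-screened is a protocol choice).  When ``training_ids`` is given,
    overlap with the holdout is rejected: validation must be out-of-sample.
    Sex strata with fewer than 2 records are omitted with a warning.
    """
    if isinstance(model, str):
        model = get_model(model)
    records = list(holdout)
    if training_ids is not None:
        overlap = {r.id for r in records} & training_ids
        if overlap:
            raise ValueError(
                f"holdout overlaps training data on {len(overlap)} ids, e.g. "
                f"{sorted(overlap)[:3]}"
            )
    if apply_effort_filter:
        records, _ = apply_exclusions(records, criteria)

    out: dict[Sex, PairedComparison] = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        group = [r for r in records if r.sex is sex]
        if len(group) < 2:
            if group:
                import warnings

                warnings.warn(f"{sex.value} stratum has {len(group)} record(s); omitted")
            continue
        measured = [r.vo2max_rel for r in group]
        predicted = [
            model.predict(sex, r.age, r.weight if sex.value in model.needs_weight else None)
            for r in group
        ]
        out[sex] = paired_compare(measured, predicted)
    return out


def report_to_frame(report: dict[Sex, PairedComparison]) -> pd.DataFrame:
    rows = []
    for sex, cmp in report.items():
        rows.append(
            {
                "sex": sex.value,
                "n": cmp.n,
                "mean_diff": cmp.mean_diff,
                "sd_diff": cmp.sd_diff,
                "t_stat": cmp.t_stat,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
                "degenerate": cmp.degenerate,
            }
        )
    return pd.DataFrame(rows)


def format_report(report: dict[Sex, PairedComparison]) -> str:
    lines = [f"Paired measured-vs-predicted comparison ({SIGN_NOTE}):"]
    for sex, cmp in report.items():
        lines.append(f"  {sex.value}: {cmp.summary()}")
    return "\n".join(lines)


def report_to_csv(report: dict[Sex, PairedComparison], path: str | Path) -> None:
    report_to_frame(report).to_csv(path, index=False)
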