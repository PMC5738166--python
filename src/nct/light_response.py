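"""Light-induction calling from an expression time course.

Features measured at 0, 30, 60 and 120 min after a dark-to-light shift are
called induced when their expression exceeds 2x the time-0 baseline at any
time point, in every dataset considered.  Induced features peaking at
30 min are "early", the rest (peak at 60 or 120 min) "late".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .splice_classifier import round_half_away

__all__ = [
    "TimeCourse",
    "fold_change",
    "call_induced",
    "classify_timing",
    "sense_antisense_concordance",
    "induction_table",
]

DEFAULT_TIMEPOINTS = (0, 30, 60, 120)


@dataclass
class TimeCourse:
    feature_id: str
    values: dict[int, float]  # minute -> normalized expression
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if 0 not in self.values:
            raise ValueError(f"{self.feature_id}: time 0 missing")
        if any(v < 0 for v in self.values.values()):
            raise ValueError(f"{self.feature_id}: negative expression")

    @property
    def times(self) -> list[int]:
        return sorted(self.values)


def fold_change(tc: TimeCourse, pseudocount: float = 1.0) -> dict[int, float]:
    """FC_t = (v_t + pseudocount) / (v_0 + pseudocount) for each t > 0."""
    v0 = tc.values[0]
    return {
        t: (tc.values[t] + pseudocount) / (v0 + pseudocount)
        for t in tc.times
        if t != 0
    }


def call_induced(
    tcs_per_dataset: Mapping[str, Sequence[TimeCourse]],
    threshold: float = 2.0,
    pseudocount: float = 1.0,
    require_all_datasets: bool = True,
) -> list[str]:
    """Features with max fold change strictly above the threshold at any
    time point, in every dataset (or any dataset when not required)."""
    if not tcs_per_dataset:
        raise ValueError("need at least one dataset")
    verdicts: dict[str, list[bool]] = {}
    for tcs in tcs_per_dataset.values():
        for tc in tcs:
            fcs = fold_change(tc, pseudocount)
            verdicts.setdefault(tc.feature_id, []).append(
                bool(fcs) and max(fcs.values()) > threshold
            )
    n_ds = len(tcs_per_dataset)
    out = []
    for fid, flags in verdicts.items():
        if require_all_datasets:
            if len(flags) == n_ds and all(flags):
                out.append(fid)
        elif any(flags):
            out.append(fid)
    return out


def classify_timing(
    induced: Sequence[str],
    tcs: Sequence[TimeCourse],
    early_time: int = 30,
) -> dict[str, str]:
    """'early' iff peak expression over the course occurs at ``early_time``;
    ties between time points break toward the earlier one."""
    by_id = {tc.feature_id: tc for tc in tcs}
    labels = {}
    for fid in induced:
        tc = by_id[fid]
        times = tc.times
        vals = [tc.values[t] for t in times]
        peak_t = times[int(np.argmax(vals))]  # argmax takes first maximum: earlier tie wins
        labels[fid] = "early" if peak_t <= early_time else "late"
    return labels


def sense_antisense_concordance(
    induced_antisense: Sequence[str],
    induced_sense: Sequence[str],
    pairing: Mapping[str, str],
    ndigits: int = 0,
) -> tuple[float, int]:
    """Fraction of induced antisense whose paired sense gene is also induced.

    ``pairing`` maps antisense feature id -> sense gene id.  Returns
    (percentage rounded half-away-from-zero, co-induced count).
    """
    if not induced_antisense:
        return 0.0, 0
    sense_set = set(induced_sense)
    co = sum(1 for a in induced_antisense if pairing.get(a) in sense_set)
    pct = round_half_away(100.0 * co / len(induced_antisense), ndigits)
    return pct, co


def induction_table(
    tcs_per_dataset: Mapping[str, Sequence[TimeCourse]],
    threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Induction report: feature, max fold change per dataset, peak time
    and early/late class (timing from the first dataset's course)."""
    induced = call_induced(tcs_per_dataset, threshold, pseudocount)
    first = next(iter(tcs_per_dataset.values()))
    timing = classify_timing(induced, first)
    by_id = {tc.feature_id: tc for tc in first}
    rows = []
    for fid in induced:
        tc = by_id[fid]
        fcs = fold_change(tc, pseudocount)
        peak_t = tc.times[int(np.argmax([tc.values[t] for t in tc.times]))]
        rows.append(
            {"feature_id": fid, "max_fold_change": max(fcs.values()),
             "peak_time": peak_t, "timing": timing[fid]}
        )
    return pd.DataFrame(rows, columns=["feature_id", "max_fold_change", "peak_time", "timing"])
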