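"""Classification of transcription units into coding genes and lincRNAs.

Pipeline order: units overlapping an annotated gene are coding; intergenic
units at least 500 bp from any gene are lincRNA candidates; candidate
segments less than 100 bp apart are merged; candidates whose
length-normalized polysome signal exceeds the median polysome signal of the
detected coding units are set aside as polysome-positive and recovered as
lincRNAs only when an external coding-potential assessment is negative.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneModel, normalize_counts
from .unit_caller import TranscriptionUnit

__all__ = [
    "LincCall",
    "classify_units",
    "merge_linc_segments",
    "polysome_threshold",
    "apply_polysome_filter",
    "assemble_final_catalog",
    "catalog_summary",
]

STATUSES = (
    "coding",
    "linc_candidate",
    "linc_confident",
    "polysome_positive",
    "possibly_coding",
    "linc_recovered",
    "discarded",
)


@dataclass
class LincCall:
    unit: TranscriptionUnit
    status: str
    distance_to_nearest_gene: float = float("inf")  # bp gap; 0 = adjacent/overlap
    polysome_value: float = float("nan")  # length-normalized polysome coverage
    coding_potential_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # half-open [start, end+1) so 1-based inclusive overlap works
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    return trees


def gap_to_nearest_gene(
    chrom: str, start: int, end: int, genes_by_chrom: Mapping[str, Sequence[GeneModel]]
) -> float:
    """Gap in bp between closest boundaries; 0 for adjacent or overlapping."""
    best = float("inf")
    for g in genes_by_chrom.get(chrom, ()):
        if g.end < start:
            gap = start - g.end - 1
        elif g.start > end:
            gap = g.start - end - 1
        else:
            gap = 0
        best = min(best, gap)
    return best


def classify_units(
    units: Sequence[TranscriptionUnit],
    genes: Sequence[GeneModel],
    min_intergenic_gap: int = 500,
) -> list[LincCall]:
    """Assign coding / lincRNA-candidate / discarded status to called units.

    Overlap >= 1 bp with an annotated gene -> coding.  No overlap and a gap
    of at least ``min_intergenic_gap`` bp to the nearest gene -> lincRNA
    candidate.  No overlap but closer than that -> discarded (kept in the
    output with its own status so the partition is explicit).
    """
    trees = _gene_trees(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    calls = []
    for u in units:
        tree = trees.get(u.chrom)
        if tree is not None and tree.overlaps(u.start, u.end + 1):
            calls.append(LincCall(u, "coding", distance_to_nearest_gene=0.0))
            continue
        gap = gap_to_nearest_gene(u.chrom, u.start, u.end, by_chrom)
        status = "linc_candidate" if gap >= min_intergenic_gap else "discarded"
        calls.append(LincCall(u, status, distance_to_nearest_gene=gap))
    return calls


def merge_linc_segments(
    calls: Sequence[LincCall], max_gap: int = 100
) -> list[LincCall]:
    """Merge lincRNA candidate segments less than ``max_gap`` bp apart.

    Non-candidate calls pass through untouched.  Merged unit counts are
    summed; normalized values are recomputed for the merged length from the
    members' raw counts and implied library totals.  Idempotent.
    """
    candidates = [c for c in calls if c.status == "linc_candidate"]
    others = [c for c in calls if c.status != "linc_candidate"]
    by_chrom: dict[str, list[LincCall]] = {}
    for c in candidates:
        by_chrom.setdefault(c.unit.chrom, []).append(c)
    merged: list[LincCall] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda c: c.unit.start)
        cluster = [group[0]]
        for c in group[1:]:
            gap = c.unit.start - cluster[-1].unit.end - 1
            if gap < max_gap:
                cluster.append(c)
            else:
                merged.append(_merge_cluster(cluster))
                cluster = [c]
        merged.append(_merge_cluster(cluster))
    return others + merged


def _merge_cluster(cluster: list[LincCall]) -> LincCall:
    if len(cluster) == 1:
        return cluster[0]
    first = cluster[0].unit
    start = min(c.unit.start for c in cluster)
    end = max(c.unit.end for c in cluster)
    length = end - start + 1
    counts: dict[str, float] = {}
    normalized: dict[str, float] = {}
    for lib in first.counts:
        raw = sum(c.unit.counts.get(lib, 0.0) for c in cluster)
        counts[lib] = raw
        # recover the library scale factor from any member with signal
        total = _implied_total(cluster, lib)
        if total is not None:
            normalized[lib] = float(normalize_counts([raw], total, [length])[0])
    unit = TranscriptionUnit(
        unit_id=first.unit_id,
        chrom=first.chrom,
        start=start,
        end=end,
        strand=first.strand,
        mean_logodds=float(
            np.average(
                [c.unit.mean_logodds for c in cluster],
                weights=[c.unit.length for c in cluster],
            )
        ),
        counts=counts,
        normalized=normalized,
    )
    return LincCall(
        unit,
        "linc_candidate",
        distance_to_nearest_gene=min(c.distance_to_nearest_gene for c in cluster),
    )


def _implied_total(cluster: list[LincCall], lib: str) -> float | None:
    for c in cluster:
        raw, norm = c.unit.counts.get(lib), c.unit.normalized.get(lib)
        if raw and norm:
            return raw / norm * 1e6 / (c.unit.length / 1000.0)
    return None


def polysome_threshold(
    coding_calls: Sequence[LincCall], polysome_library: str = "polysome"
) -> float:
    """Median length-normalized polysome value over detected coding units.

    An even count takes the arithmetic mean of the central pair.
    """
    values = [
        c.unit.normalized.get(polysome_library, c.unit.counts.get(polysome_library))
        for c in coding_calls
        if c.status == "coding"
    ]
    values = [v for v in values if v is not None]
    if not values:
        raise ValueError("no coding units with polysome values; cannot set threshold")
    return float(statistics.median(values))


def apply_polysome_filter(
    candidates: Sequence[LincCall],
    threshold: float,
    polysome_library: str = "polysome",
) -> tuple[list[LincCall], list[LincCall]]:
    """Split candidates into (linc_confident, polysome_positive).

    Strictly above the threshold -> polysome_positive (ribosome-associated,
    deferred to coding-potential assessment); at or below -> linc_confident.
    """
    confident, positive = [], []
    for c in candidates:
        val = c.unit.normalized.get(polysome_library, c.unit.counts.get(polysome_library, 0.0))
        val = 0.0 if val is None else float(val)
        if val > threshold:
            positive.append(replace(c, status="polysome_positive", polysome_value=val))
        else:
            confident.append(replace(c, status="linc_confident", polysome_value=val))
    return confident, positive


def assemble_final_catalog(
    linc_confident: Sequence[LincCall],
    polysome_positive: Sequence[LincCall],
    coding_potential_flags: Mapping[str, bool],
) -> tuple[list[LincCall], list[LincCall]]:
    """Build the final lincRNA catalog and the possibly-coding remainder.

    Every polysome-positive record needs an external coding-potential
    verdict (True = predicted coding).  Flag-false records are recovered as
    lincRNAs; flag-true records form the possibly-coding set.
    """
    missing = [
        c.unit.unit_id for c in polysome_positive
        if c.unit.unit_id not in coding_potential_flags
    ]
    if missing:
        raise ValueError(f"missing coding-potential flags for: {missing}")
    final = [replace(c, status="linc_confident") if c.status != "linc_confident" else c
             for c in linc_confident]
    possibly_coding = []
    for c in polysome_positive:
        flag = bool(coding_potential_flags[c.unit.unit_id])
        if flag:
            possibly_coding.append(replace(c, status="possibly_coding",
                                           coding_potential_flag=True))
        else:
            final.append(replace(c, status="linc_recovered", coding_potential_flag=False))
    return final, possibly_coding


def catalog_summary(
    features: Sequence[LincCall] | Sequence[TranscriptionUnit],
    libraries: Iterable[str] = (),
) -> pd.Series:
    """Count, median length, median inter-feature gap and per-library medians."""
    units = [f.unit if isinstance(f, LincCall) else f for f in features]
    out: dict[str, float] = {"count": len(units)}
    if not units:
        return pd.Series(out)
    out["median_length"] = float(np.median([u.length for u in units]))
    gaps = []
    by_chrom: dict[str, list[TranscriptionUnit]] = {}
    for u in units:
        by_chrom.setdefault(u.chrom, []).append(u)
    for chrom_units in by_chrom.values():
        chrom_units.sort(key=lambda u: u.start)
        for a, b in zip(chrom_units, chrom_units[1:]):
            gaps.append(max(0, b.start - a.end - 1))
    out["median_distance"] = float(np.median(gaps)) if gaps else float("nan")
    for lib in libraries:
        vals = [u.normalized.get(lib) for u in units]
        vals = [v for v in vals if v is not None]
        if vals:
            out[f"median_norm_{lib}"] = float(np.median(vals))
    return pd.Series(out)
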