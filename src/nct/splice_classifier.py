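"""Splice-junction classification against annotated introns.

Observed junctions (donor = first intronic base, acceptor = last intronic
base, both 1-based) are compared with the annotated intron catalog:

* ``perfect``     — both ends match an annotated intron exactly
* ``alternative`` — shares exactly one of donor/acceptor with an annotated intron
* ``weak``        — near an annotated intron (both ends within a tolerance)
                    but neither end exact
* ``novel``       — matches no annotated intron
* ``filtered``    — non-annotated junction whose read support falls below
                    the cutoff (the 25th percentile of read counts over
                    junctions that match annotated introns)

Intron lengths are constrained to [50, 500000] bp at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Junction",
    "load_junctions",
    "annotated_coverage_cutoff",
    "classify_junctions",
    "junctions_in_features",
    "splice_fraction_report",
    "round_half_away",
]

MIN_INTRON = 50
MAX_INTRON = 500_000


@dataclass
class Junction:
    chrom: str
    donor: int  # 1-based first intronic base
    acceptor: int  # 1-based last intronic base
    strand: str
    reads: int
    cls: str | None = None

    def __post_init__(self) -> None:
        if self.acceptor <= self.donor:
            raise ValueError(f"acceptor {self.acceptor} must exceed donor {self.donor}")
        if self.reads < 0:
            raise ValueError("negative read support")

    @property
    def intron_length(self) -> int:
        return self.acceptor - self.donor + 1


def load_junctions(
    path: str | Path,
    min_intron: int = MIN_INTRON,
    max_intron: int = MAX_INTRON,
) -> tuple[list[Junction], int]:
    """Load junctions from a TSV (chrom, donor, acceptor, strand, reads)
    or 6+-column BED (blockless; name carries the read count).

    Returns (accepted junctions, number rejected by the intron-length
    bounds).
    """
    path = Path(path)
    accepted: list[Junction] = []
    rejected = 0
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        try:
            if path.suffix.lower() == ".bed":
                chrom = parts[0]
                donor = int(parts[1]) + 1  # BED 0-based start -> first intronic base
                acceptor = int(parts[2])
                reads = int(float(parts[3]))
                strand = parts[5] if len(parts) > 5 else "."
            else:
                chrom, donor, acceptor, strand, reads = (
                    parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]),
                )
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: malformed junction record") from exc
        length = acceptor - donor + 1
        if not (min_intron <= length <= max_intron):
            rejected += 1
            continue
        accepted.append(Junction(chrom, donor, acceptor, strand, reads))
    return accepted, rejected


def _intron_key(chrom: str, donor: int, acceptor: int) -> tuple[str, int, int]:
    return (chrom, donor, acceptor)


def annotated_coverage_cutoff(
    junctions: Sequence[Junction],
    annotated_introns: Sequence[tuple[str, int, int]],
) -> float:
    """25th percentile of read support over junctions that exactly match
    annotated introns (linear interpolation between order statistics)."""
    annotated = {_intron_key(*iv) for iv in annotated_introns}
    matched = [j.reads for j in junctions if _intron_key(j.chrom, j.donor, j.acceptor) in annotated]
    if not matched:
        raise ValueError("no junction matches an annotated intron; cannot set cutoff")
    return float(np.quantile(np.asarray(matched, dtype=float), 0.25))


def classify_junctions(
    junctions: Sequence[Junction],
    annotated_introns: Sequence[tuple[str, int, int]],
    cutoff: float,
    weak_tolerance: int = 10,
) -> list[Junction]:
    """Classify each junction against ALL annotated introns.

    Precedence: perfect > alternative > weak > novel; non-annotated
    junctions with read support below the cutoff are ``filtered`` (ties at
    the cutoff are kept).  Classes are disjoint and exhaustive.
    """
    exact = set()
    donors: dict[tuple[str, int], bool] = {}
    acceptors: dict[tuple[str, int], bool] = {}
    near: dict[str, IntervalTree] = {}
    for chrom, d, a in annotated_introns:
        exact.add((chrom, d, a))
        donors[(chrom, d)] = True
        acceptors[(chrom, a)] = True
        near.setdefault(chrom, IntervalTree()).addi(d, a + 1, (d, a))
    out = []
    for j in junctions:
        key = (j.chrom, j.donor, j.acceptor)
        if key in exact:
            cls = "perfect"
        elif j.reads < cutoff:
            cls = "filtered"
        elif ((j.chrom, j.donor) in donors) != ((j.chrom, j.acceptor) in acceptors):
            cls = "alternative"
        elif (j.chrom, j.donor) in donors and (j.chrom, j.acceptor) in acceptors:
            # both ends annotated but never together: still alternative isoform
            cls = "alternative"
        elif _is_weak(j, near.get(j.chrom), weak_tolerance):
            cls = "weak"
        else:
            cls = "novel"
        out.append(Junction(j.chrom, j.donor, j.acceptor, j.strand, j.reads, cls))
    return out


def _is_weak(j: Junction, tree: IntervalTree | None, tol: int) -> bool:
    if tree is None:
        return False
    for iv in tree.overlap(j.donor - tol, j.acceptor + tol + 1):
        d, a = iv.data
        if abs(j.donor - d) <= tol and abs(j.acceptor - a) <= tol:
            return True
    return False


def junctions_in_features(
    junctions: Sequence[Junction],
    feature_sets: Mapping[str, Sequence[tuple[str, int, int]]],
    min_reads: int = 10,
) -> dict[str, int]:
    """Count junctions (reads >= min_reads) whose intron lies fully inside
    a feature interval, per named feature set."""
    counts = {}
    for name, features in feature_sets.items():
        trees: dict[str, IntervalTree] = {}
        for chrom, s, e in features:
            trees.setdefault(chrom, IntervalTree()).addi(s, e + 1)
        n = 0
        for j in junctions:
            if j.reads < min_reads:
                continue
            tree = trees.get(j.chrom)
            if tree is None:
                continue
            if any(iv.begin <= j.donor and j.acceptor < iv.end for iv in
                   tree.overlap(j.donor, j.acceptor + 1)):
                n += 1
        counts[name] = n
    return counts


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-style rounding, unlike banker's)."""
    factor = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def splice_fraction_report(
    spliced_counts: Mapping[str, int],
    set_sizes: Mapping[str, int],
    ndigits: Mapping[str, int] | int = 1,
) -> pd.DataFrame:
    """Per feature set: spliced / unspliced counts and the percentage
    spliced, rounded half-away-from-zero to the requested precision."""
    rows = []
    for name, total in set_sizes.items():
        spliced = int(spliced_counts.get(name, 0))
        nd = ndigits[name] if isinstance(ndigits, Mapping) else ndigits
        pct = round_half_away(100.0 * spliced / total, nd) if total else 0.0
        rows.append(
            {"set": name, "spliced": spliced, "unspliced": total - spliced,
             "total": total, "pct_spliced": pct}
        )
    return pd.DataFrame(rows).set_index("set")
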