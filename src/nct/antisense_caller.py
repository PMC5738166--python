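"""Natural antisense transcript detection from strand-specific coverage.

The logistic transcription classifier is fitted per strand; a called unit
on the strand opposite an annotated gene that overlaps that gene is an
antisense fragment.  Fragments over the same gene are merged into one
antisense transcript, retained only when the gene itself carries an
above-cutoff sense unit, and discarded when a different same-strand gene
within 500 bp could explain the signal.  Genes with antisense but no sense
expression are detected separately from per-gene stranded coverage
averages (sense < 1 and antisense > 1 reads per 50-bp bin in every
dataset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import BinGrid, GeneModel
from .unit_caller import (
    BinLabeling,
    LogitModel,
    TranscriptionUnit,
    call_units,
    fit_logit,
    score_bins,
)

__all__ = [
    "AntisenseCall",
    "AntisenseOnlyCall",
    "call_stranded_units",
    "pair_sense_antisense",
    "filter_by_neighbor_distance",
    "detect_antisense_only",
    "antisense_summary",
    "tss_offset_profile",
]

OPPOSITE = {"+": "-", "-": "+"}


@dataclass
class AntisenseCall:
    """A merged antisense transcript paired with its sense gene."""

    gene_id: str
    fragments: list[TranscriptionUnit]
    chrom: str
    start: int
    end: int
    strand: str  # antisense strand (opposite to the gene)
    antisense_level: float = float("nan")
    sense_level: float = float("nan")
    tss_offset: float = float("nan")  # antisense 5' start vs sense TSS
    tts_offset: float = float("nan")  # antisense 5' start vs sense TTS

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def five_prime_start(self) -> int:
        """5'-most coordinate in ANTISENSE orientation."""
        return self.end if self.strand == "-" else self.start


@dataclass
class AntisenseOnlyCall:
    """A gene expressing antisense RNA but no sense RNA."""

    gene_id: str
    sense_avg: dict[str, float] = field(default_factory=dict)  # per dataset
    antisense_avg: dict[str, float] = field(default_factory=dict)
    datasets_passed: list[str] = field(default_factory=list)


def call_stranded_units(
    grid: BinGrid,
    labeling: BinLabeling | Mapping[str, BinLabeling],
    model_spec: LogitModel,
    rna_library: str,
    pol_library: str | None = None,
    min_reads: int = 10,
) -> dict[str, list[TranscriptionUnit]]:
    """Run the unit-calling pipeline separately for each strand.

    ``labeling`` may be a single labeling shared by both fits or a mapping
    strand -> labeling (strand-aware targets).  A bin is eligible only
    when its fitted log-odds exceed the cutoff AND its raw strand count is
    at least ``min_reads`` per bin.  When no RNAPII library is given, the
    fit drops the second covariate (RNAPII ChIP is unstranded, so no
    independent per-strand second signal exists; duplicating the RNA
    column would make the design singular).
    """
    if not any(s == "+" for _, s in grid.libraries()):
        raise ValueError("stranded unit calling requires a stranded grid")
    units: dict[str, list[TranscriptionUnit]] = {}
    for strand in ("+", "-"):
        from dataclasses import replace as _replace
        spec = _replace(model_spec)
        lab = labeling[strand] if isinstance(labeling, Mapping) else labeling
        fitted = fit_logit(grid, lab, spec, rna_library=rna_library,
                           pol_library=pol_library, strand=strand)
        scores = score_bins(fitted, grid, rna_library=rna_library,
                            pol_library=pol_library, strand=strand)
        units[strand] = call_units(
            scores, fitted.cutoff, grid, strand=strand,
            min_reads=min_reads, min_reads_library=rna_library,
            id_prefix=f"AS{'P' if strand == '+' else 'M'}",
        )
    return units


def _tree_of_units(units: Sequence[TranscriptionUnit]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for u in units:
        trees.setdefault(u.chrom, IntervalTree()).addi(u.start, u.end + 1, u)
    return trees


def pair_sense_antisense(
    units_by_strand: Mapping[str, Sequence[TranscriptionUnit]],
    genes: Sequence[GeneModel],
    rna_library: str | None = None,
) -> list[AntisenseCall]:
    """Pair antisense units with sense genes; merge fragments per gene.

    An antisense unit is any called unit overlapping a gene on the opposite
    strand; the pair is kept only if the gene also overlaps an above-cutoff
    unit on its own strand.  All fragments over one gene merge into a
    single call spanning their extremes.
    """
    trees = {s: _tree_of_units(us) for s, us in units_by_strand.items()}
    calls = []
    for gene in genes:
        anti_strand = OPPOSITE[gene.strand]
        anti_tree = trees.get(anti_strand, {}).get(gene.chrom)
        sense_tree = trees.get(gene.strand, {}).get(gene.chrom)
        if anti_tree is None:
            continue
        frags = sorted(
            (iv.data for iv in anti_tree.overlap(gene.start, gene.end + 1)),
            key=lambda u: u.start,
        )
        if not frags:
            continue
        if sense_tree is None or not sense_tree.overlaps(gene.start, gene.end + 1):
            continue  # sense not expressed: antisense-only path handles it
        sense_units = [iv.data for iv in sense_tree.overlap(gene.start, gene.end + 1)]
        call = AntisenseCall(
            gene_id=gene.gene_id,
            fragments=list(frags),
            chrom=gene.chrom,
            start=min(u.start for u in frags),
            end=max(u.end for u in frags),
            strand=anti_strand,
        )
        if rna_library is not None:
            call.antisense_level = float(
                np.sum([u.normalized.get(rna_library, 0.0) * u.length for u in frags])
                / call.length
            )
            call.sense_level = float(
                np.sum([u.normalized.get(rna_library, 0.0) * u.length for u in sense_units])
                / sum(u.length for u in sense_units)
            )
        calls.append(call)
    return calls


def filter_by_neighbor_distance(
    calls: Sequence[AntisenseCall],
    genes: Sequence[GeneModel],
    min_gap: int = 500,
) -> list[AntisenseCall]:
    """Drop calls explainable by a neighboring same-strand gene.

    A call is removed when its antisense span overlaps, or lies closer than
    ``min_gap`` bp to, a DIFFERENT annotated gene located on the antisense
    strand — that gene's own transcription (e.g. read-through from a
    convergent or overlapping neighbor) would produce the same signal.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    kept = []
    for call in calls:
        suspicious = False
        for g in by_chrom.get(call.chrom, ()):
            if g.gene_id == call.gene_id or g.strand != call.strand:
                continue
            if g.end < call.start:
                gap = call.start - g.end - 1
            elif g.start > call.end:
                gap = g.start - call.end - 1
            else:
                gap = 0  # overlap
            if gap < min_gap:
                suspicious = True
                break
        if not suspicious:
            kept.append(call)
    return kept


def gene_strand_averages(
    grid: BinGrid,
    genes: Sequence[GeneModel],
    rna_library: str,
    reference_total: float | None = None,
) -> pd.DataFrame:
    """Per-gene average sense/antisense reads per bin, total-count normalized.

    "Average coverage" for a gene = read count over the gene's bins divided
    by the number of bins, i.e. reads per 50-bp bin.  With
    ``reference_total`` set, counts are normalized between samples by total
    count: each library is rescaled by reference_total / library_total
    (sense and antisense share the library total), so the thresholds
    "below/above 1 read per bin" compare libraries on a common depth.
    """
    total = grid.total_reads(rna_library)  # both strands
    scale = 1.0 if reference_total is None else reference_total / total
    rows = []
    w = grid.bin_width
    for gene in genes:
        lo = (gene.start - 1) // w
        hi = (gene.end - 1) // w
        n_bins = hi - lo + 1
        sense = float(grid.get_counts(rna_library, gene.strand, gene.chrom)[lo : hi + 1].sum())
        anti = float(
            grid.get_counts(rna_library, OPPOSITE[gene.strand], gene.chrom)[lo : hi + 1].sum()
        )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "sense_avg": sense * scale / n_bins,
                "antisense_avg": anti * scale / n_bins,
                "library_total": total,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def detect_antisense_only(
    averages_per_dataset: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    sense_below: float = 1.0,
    antisense_above: float = 1.0,
) -> list[AntisenseOnlyCall]:
    """Genes whose average sense coverage is below 1 and antisense above 1
    read per bin in EVERY dataset; genes overlapping other genes removed."""
    if not averages_per_dataset:
        raise ValueError("need at least one dataset of per-gene averages")
    overlapping = _overlapping_gene_ids(genes)
    calls = []
    for gene in genes:
        if gene.gene_id in overlapping:
            continue
        sense_avgs, anti_avgs, passed = {}, {}, []
        ok = True
        for ds, df in averages_per_dataset.items():
            if gene.gene_id not in df.index:
                ok = False
                break
            s = float(df.loc[gene.gene_id, "sense_avg"])
            a = float(df.loc[gene.gene_id, "antisense_avg"])
            sense_avgs[ds], anti_avgs[ds] = s, a
            if s < sense_below and a > antisense_above:
                passed.append(ds)
            else:
                ok = False
        if ok and len(passed) == len(averages_per_dataset):
            calls.append(
                AntisenseOnlyCall(gene.gene_id, sense_avgs, anti_avgs, passed)
            )
    return calls


def _overlapping_gene_ids(genes: Sequence[GeneModel]) -> set[str]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    out = set()
    for g in genes:
        hits = {iv.data for iv in trees[g.chrom].overlap(g.start, g.end + 1)}
        if len(hits) > 1:
            out.add(g.gene_id)
    return out


def antisense_summary(
    paired: Sequence[AntisenseCall],
    antisense_only: Sequence[AntisenseOnlyCall],
    genes: Sequence[GeneModel] | None = None,
) -> pd.Series:
    """Totals and medians for the antisense catalog.

    total = paired + antisense-only (disjoint by construction: pairing
    requires sense expression, antisense-only requires its absence).
    """
    out: dict[str, float] = {
        "n_paired": len(paired),
        "n_antisense_only": len(antisense_only),
        "n_total": len(paired) + len(antisense_only),
    }
    if paired:
        out["median_antisense_length"] = float(np.median([c.length for c in paired]))
        if genes is not None:
            by_id = {g.gene_id: g for g in genes}
            out["median_sense_length"] = float(
                np.median([by_id[c.gene_id].length for c in paired if c.gene_id in by_id])
            )
        levels = [
            (c.sense_level, c.antisense_level)
            for c in paired
            if np.isfinite(c.sense_level) and np.isfinite(c.antisense_level)
        ]
        if len(levels) >= 3:
            s, a = np.array(levels).T
            if s.std() > 0 and a.std() > 0:
                out["sense_antisense_correlation"] = float(np.corrcoef(s, a)[0, 1])
    return pd.Series(out)


def tss_offset_profile(
    calls: Sequence[AntisenseCall],
    genes: Sequence[GeneModel],
    bins: int = 50,
) -> pd.DataFrame:
    """Signed offsets of each antisense 5' start to the sense TSS and TTS.

    The antisense 5' start is the boundary that is 5' on the ANTISENSE
    strand.  Positive offsets point downstream of the landmark in
    sense-gene orientation.  Returns one row per call plus histogram-ready
    columns; the annotated calls get tss_offset/tts_offset filled in place.
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for call in calls:
        gene = by_id[call.gene_id]
        a5 = call.five_prime_start()
        sign = 1 if gene.strand == "+" else -1
        call.tss_offset = float(sign * (a5 - gene.tss))
        call.tts_offset = float(sign * (a5 - gene.tts))
        rows.append(
            {"gene_id": call.gene_id, "tss_offset": call.tss_offset,
             "tts_offset": call.tts_offset}
        )
    return pd.DataFrame(rows)
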