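"""Synthetic genome, coverage and time-course generator with planted truth.

Emulates the statistical structure of a compact fungal genome and its
noncoding transcriptome so every pipeline stage can be exercised against a
known answer: multi-exon coding genes (length median ~1782 bp, ~80% with
introns of median ~69 bp), shorter and lower-expressed intergenic
noncoding transcripts (median ~551 bp) placed at least 500 bp from genes,
antisense transcripts (median ~251 bp) on the strand opposite a coding
gene with their 5' starts biased toward the sense 3' end, polysome signal
restricted to coding features, and a light time course in which a subset
of features is induced more than two-fold with configured peak times.

Counts are drawn from a negative binomial around background + feature
contribution; all randomness flows from a single integer seed through one
numpy Generator, so runs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import BinGrid, GeneModel, build_bin_grid
from .light_response import TimeCourse

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_coverage",
    "simulate_junctions",
    "simulate_time_courses",
    "recovery_metrics",
    "write_gff3",
    "write_truth_table",
]

TIMEPOINTS = (0, 30, 60, 120)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 500_000
    bin_width: int = 50

    n_coding: int = 200
    coding_median_length: int = 1782
    coding_length_sigma: float = 0.45  # lognormal sigma around the median
    coding_intron_fraction: float = 0.8
    intron_median_length: int = 69
    max_introns_per_gene: int = 4

    n_linc: int = 40
    linc_median_length: int = 551
    linc_length_sigma: float = 0.35
    linc_intron_fraction: float = 0.016

    n_antisense: int = 30
    antisense_median_length: int = 251
    antisense_length_sigma: float = 0.3
    antisense_intron_fraction: float = 0.025
    antisense_tts_jitter: float = 100.0  # sd of antisense 5' start around sense TTS
    n_antisense_only: int = 8  # genes with antisense but no sense expression

    # expression: mean reads per 50-bp bin over the feature, at depth 1.
    # The defaults realise a well-separated regime: noncoding features sit
    # >= 10x above background and >= 2 sd of combined count + level noise
    # above the classifier's fitted decision boundary, while staying below
    # the coding median (noncoding transcripts accumulate at lower levels
    # than mRNAs).  The wide coding dynamic range anchors that boundary
    # well below the noncoding levels, as weakly expressed coding genes do
    # in real data.
    coding_median_level: float = 40.0
    coding_level_sigma: float = 1.5  # wide dynamic range, as in real RNA-seq
    linc_median_level: float = 16.0
    antisense_median_level: float = 30.0
    level_sigma: float = 0.2
    background_mean: float = 1.0  # unstranded libraries, per bin, at depth 1
    stranded_background_mean: float = 0.4  # per strand per bin, at depth 1
    polysome_background_mean: float = 0.2
    nb_shape: float = 30.0  # negative binomial size; var = m + m^2/shape
    # per-library sequencing depth multipliers: the pooled unstranded
    # libraries are an order of magnitude deeper than the individual
    # strand-specific ones, as is typical when many runs are pooled
    library_depth: dict = field(
        default_factory=lambda: {
            "rna": 10.0, "pol": 10.0, "polysome": 10.0,
            "ss_dark": 1.5, "ss_light": 1.5,
        }
    )

    min_feature_gap: int = 1200  # enforced spacing between planted features

    # light response
    linc_induced_fraction: float = 0.3
    antisense_induced_fraction: float = 0.35
    early_fraction: float = 0.58  # induced features peaking at 30 min
    sense_coinduced_fraction: float = 0.35
    induced_fold_low: float = 3.0
    induced_fold_high: float = 8.0
    timecourse_noise_sigma: float = 0.08

    n_decoy_junctions: int = 30

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chromosome_length for i in range(self.n_chromosomes)}

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: float, sigma: float,
    lo: int, hi: int,
) -> np.ndarray:
    vals = np.exp(rng.normal(np.log(median), sigma, size=n))
    return np.clip(np.round(vals), lo, hi).astype(int)


def _plant_introns(
    rng: np.random.Generator, start: int, end: int, n_introns: int, median: int
) -> list[tuple[int, int]]:
    """Place non-overlapping introns inside [start, end], each >= 50 bp,
    keeping >= 60 bp of exon at both ends and between introns."""
    introns: list[tuple[int, int]] = []
    cursor = start + 60
    for _ in range(n_introns):
        length = int(np.clip(round(np.exp(rng.normal(np.log(median), 0.25))), 50, 300))
        lo = cursor
        hi = end - 60 - length
        if lo > hi:
            break
        s = int(rng.integers(lo, hi + 1))
        introns.append((s, s + length - 1))
        cursor = s + length + 60
    return introns


def _exons_from_introns(
    start: int, end: int, introns: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    exons = []
    cur = start
    for s, e in sorted(introns):
        exons.append((cur, s - 1))
        cur = e + 1
    exons.append((cur, end))
    return exons


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place coding genes, lincRNAs and antisense features; return the gene
    models and the truth table (one row per planted feature).

    Features are packed left to right per chromosome with at least
    ``min_feature_gap`` bp between them, so every lincRNA is > 500 bp from
    any gene and no two genes overlap.  Raises when the requested features
    do not fit.
    """
    rng = config.rng()
    sizes = config.chrom_sizes()
    chroms = list(sizes)

    coding_len = _lognormal_lengths(
        rng, config.n_coding, config.coding_median_length,
        config.coding_length_sigma, 400, 12_000,
    )
    linc_len = _lognormal_lengths(
        rng, config.n_linc, config.linc_median_length,
        config.linc_length_sigma, 250, 2_500,
    )
    # interleave coding and linc placements in shuffled order
    kinds = ["coding"] * config.n_coding + ["linc"] * config.n_linc
    lengths = np.concatenate([coding_len, linc_len])
    order = rng.permutation(len(kinds))

    placements: list[tuple[str, str, int, int]] = []  # (kind, chrom, start, end)
    cursors = {c: 1000 for c in chroms}
    ci = 0
    for k in order:
        kind, length = kinds[k], int(lengths[k])
        placed = False
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            gap = int(rng.integers(config.min_feature_gap, 2 * config.min_feature_gap))
            start = cursors[chrom] + gap
            end = start + length - 1
            if end <= sizes[chrom] - 1000:
                placements.append((kind, chrom, start, end))
                cursors[chrom] = end
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible packing: features plus margins exceed chromosome "
                "lengths; increase chromosome_length or reduce feature counts"
            )

    genes: list[GeneModel] = []
    rows: list[dict] = []
    n_gene = n_linc = 0
    coding_levels = np.exp(
        rng.normal(
            np.log(config.coding_median_level), config.coding_level_sigma, config.n_coding
        )
    )
    linc_levels = np.exp(
        rng.normal(np.log(config.linc_median_level), config.level_sigma, config.n_linc)
    )
    for kind, chrom, start, end in placements:
        if kind == "coding":
            n_gene += 1
            gid = f"GENE{n_gene:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < config.coding_intron_fraction:
                n_int = int(rng.integers(1, config.max_introns_per_gene + 1))
                introns = _plant_introns(rng, start, end, n_int, config.intron_median_length)
            else:
                introns = []
            exons = _exons_from_introns(start, end, introns)
            genes.append(GeneModel(gid, chrom, start, end, strand, exons=exons))
            rows.append(
                {"feature_id": gid, "cls": "coding", "chrom": chrom, "start": start,
                 "end": end, "strand": strand, "level": float(coding_levels[n_gene - 1]),
                 "introns": ";".join(f"{s}-{e}" for s, e in introns)}
            )
        else:
            n_linc += 1
            fid = f"LINC{n_linc:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            introns = (
                _plant_introns(rng, start, end, 1, config.intron_median_length)
                if rng.random() < config.linc_intron_fraction
                else []
            )
            rows.append(
                {"feature_id": fid, "cls": "linc", "chrom": chrom, "start": start,
                 "end": end, "strand": strand, "level": float(linc_levels[n_linc - 1]),
                 "introns": ";".join(f"{s}-{e}" for s, e in introns)}
            )

    # antisense: hosted by coding genes; a subset of hosts is silenced on
    # the sense strand (antisense-only loci).  Paired antisense requires a
    # detectable sense partner by definition, so hosts come from genes
    # above the lower quartile of expression; silent hosts can be any gene.
    n_as_total = config.n_antisense + config.n_antisense_only
    gene_levels = coding_levels[: len(genes)]
    q25 = float(np.quantile(gene_levels, 0.25))
    eligible = np.flatnonzero(gene_levels >= q25)
    pool = eligible if eligible.size >= n_as_total else np.arange(len(genes))
    host_idx = rng.choice(pool, size=min(n_as_total, pool.size), replace=False)
    as_levels = np.exp(
        rng.normal(np.log(config.antisense_median_level), config.level_sigma, len(host_idx))
    )
    as_len = _lognormal_lengths(
        rng, len(host_idx), config.antisense_median_length,
        config.antisense_length_sigma, 150, 1_200,
    )
    truth_by_id = {r["feature_id"]: r for r in rows}
    for i, (gi, level, length) in enumerate(zip(host_idx, as_levels, as_len)):
        gene = genes[gi]
        anti_strand = "-" if gene.strand == "+" else "+"
        length = int(min(length, gene.length - 20))
        # antisense 5' start near the sense TTS, extending toward the gene body
        jitter = rng.normal(0.0, config.antisense_tts_jitter)
        if gene.strand == "+":
            a5 = int(np.clip(gene.tts + jitter, gene.start + length, gene.end))
            start, end = a5 - length + 1, a5
        else:
            a5 = int(np.clip(gene.tts + jitter, gene.start, gene.end - length))
            start, end = a5, a5 + length - 1
        only = i >= config.n_antisense
        fid = f"AS{i + 1:04d}"
        introns = (
            _plant_introns(rng, start, end, 1, config.intron_median_length)
            if (not only and rng.random() < config.antisense_intron_fraction)
            else []
        )
        rows.append(
            {"feature_id": fid, "cls": "antisense_only" if only else "antisense",
             "chrom": gene.chrom, "start": start, "end": end, "strand": anti_strand,
             "level": float(level), "host_gene": gene.gene_id,
             "introns": ";".join(f"{s}-{e}" for s, e in introns)}
        )
        if only:  # silence the host on the sense strand
            truth_by_id[gene.gene_id]["level"] = 0.0

    truth = pd.DataFrame(rows)
    if "host_gene" not in truth.columns:  # no antisense features requested
        truth["host_gene"] = ""
    truth["induced"] = False
    truth["peak_time"] = 0
    truth = _assign_induction(truth, config, rng)
    return genes, truth


def _assign_induction(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Mark induced lincRNAs and antisense features with peak times, and
    co-induce the configured fraction of antisense host genes."""
    for cls, frac in (("linc", config.linc_induced_fraction),
                      ("antisense", config.antisense_induced_fraction)):
        idx = truth.index[truth["cls"] == cls].to_numpy()
        n_ind = int(round(frac * idx.size))
        chosen = rng.choice(idx, size=n_ind, replace=False)
        truth.loc[chosen, "induced"] = True
        n_early = int(round(config.early_fraction * n_ind))
        early = rng.permutation(chosen)
        truth.loc[early[:n_early], "peak_time"] = 30
        truth.loc[early[n_early:], "peak_time"] = rng.choice(
            [60, 120], size=max(0, n_ind - n_early)
        )
    # co-induce sense hosts of a fraction of the induced antisense features
    induced_as = truth.index[(truth["cls"] == "antisense") & truth["induced"]].to_numpy()
    n_co = int(round(config.sense_coinduced_fraction * induced_as.size))
    co = rng.choice(induced_as, size=n_co, replace=False)
    hosts = truth.loc[co, "host_gene"]
    for host in hosts:
        sel = truth["feature_id"] == host
        truth.loc[sel, "induced"] = True
        truth.loc[sel, "peak_time"] = 30
    return truth


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, shape: float
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + mean^2/shape."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p).astype(np.int64)


def _add_feature_mean(
    mean: np.ndarray, grid: BinGrid, chrom: str, start: int, end: int, level: float
) -> None:
    """Add ``level`` reads per fully-covered bin, pro-rated at the edges."""
    starts, ends = grid.bin_bounds(chrom)
    lo = (start - 1) // grid.bin_width
    hi = min((end - 1) // grid.bin_width, mean.size - 1)
    for k in range(lo, hi + 1):
        ov = min(end, ends[k]) - max(start, starts[k]) + 1
        mean[k] += level * ov / grid.bin_width


def simulate_coverage(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> BinGrid:
    """Draw per-bin counts for every library into one BinGrid.

    Libraries: ``rna`` and ``pol`` (unstranded; RNA over exons, RNAPII over
    full feature spans), ``polysome`` (unstranded, coding features only),
    ``ss_dark`` and ``ss_light`` (strand-specific RNA-seq; the light
    library scales induced features by their planted peak fold change).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    grid = build_bin_grid(config.chrom_sizes(), config.bin_width)
    by_id = {g.gene_id: g for g in genes}
    shape = config.nb_shape

    def blank() -> dict[str, np.ndarray]:
        return {c: np.zeros(grid.n_bins(c), dtype=float) for c in grid.chromosomes}

    means: dict[tuple[str, str | None], dict[str, np.ndarray]] = {}
    for lib in ("rna", "pol", "polysome"):
        means[(lib, None)] = blank()
    for lib in ("ss_dark", "ss_light"):
        means[(lib, "+")] = blank()
        means[(lib, "-")] = blank()

    depth = config.library_depth
    pol_noise = np.exp(rng.normal(0.0, 0.2, size=len(truth)))
    for row_i, row in enumerate(truth.itertuples()):
        level = float(row.level)
        if level <= 0:
            continue
        chrom, start, end, strand = row.chrom, int(row.start), int(row.end), row.strand
        spans_exonic: list[tuple[int, int]]
        if row.cls == "coding":
            spans_exonic = by_id[row.feature_id].exons
        else:
            spans_exonic = [(start, end)]
        for s, e in spans_exonic:
            _add_feature_mean(
                means[("rna", None)][chrom], grid, chrom, s, e,
                level * depth.get("rna", 1.0),
            )
        _add_feature_mean(
            means[("pol", None)][chrom], grid, chrom, start, end,
            level * pol_noise[row_i] * depth.get("pol", 1.0),
        )
        if row.cls == "coding":
            _add_feature_mean(
                means[("polysome", None)][chrom], grid, chrom, start, end,
                level * float(np.exp(rng.normal(0.0, 0.15))) * depth.get("polysome", 1.0),
            )
        light_factor = 1.0
        if bool(row.induced):
            light_factor = float(rng.uniform(config.induced_fold_low, config.induced_fold_high))
        for lib, factor in (("ss_dark", 1.0), ("ss_light", light_factor)):
            for s, e in spans_exonic:
                _add_feature_mean(
                    means[(lib, strand)][chrom], grid, chrom, s, e,
                    level * factor * depth.get(lib, 1.0),
                )

    for (lib, strand), per_chrom in means.items():
        if lib == "polysome":
            bg = config.polysome_background_mean
        elif strand is None:
            bg = config.background_mean
        else:
            bg = config.stranded_background_mean
        bg *= depth.get(lib, 1.0)
        grid.counts[(lib, strand)] = {
            chrom: _nb_draw(rng, mean + bg, shape) for chrom, mean in per_chrom.items()
        }
    return grid


def simulate_junctions(
    genes: Sequence[GeneModel],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One junction per planted intron (reads scale with expression, floor
    5) plus decoy junctions whose support (1 read) sits below the 25th
    percentile of the planted junctions' support by construction."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rows = []
    for row in truth.itertuples():
        if not row.introns:
            continue
        for iv in str(row.introns).split(";"):
            if not iv:
                continue
            s, e = (int(x) for x in iv.split("-"))
            reads = max(5, int(round(float(row.level) * float(rng.uniform(0.3, 0.7)))))
            rows.append(
                {"chrom": row.chrom, "donor": s, "acceptor": e,
                 "strand": row.strand, "reads": reads, "decoy": False}
            )
    sizes = config.chrom_sizes()
    chroms = list(sizes)
    for _ in range(config.n_decoy_junctions):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(2000, sizes[chrom] - 2000))
        length = int(rng.integers(55, 200))
        rows.append(
            {"chrom": chrom, "donor": s, "acceptor": s + length - 1,
             "strand": "+" if rng.random() < 0.5 else "-", "reads": 1, "decoy": True}
        )
    return pd.DataFrame(rows)


def simulate_time_courses(
    truth: pd.DataFrame,
    config: SimulationConfig,
    datasets: Sequence[str] = ("ds1", "ds2"),
    rng: np.random.Generator | None = None,
) -> dict[str, list[TimeCourse]]:
    """Per-dataset expression time courses at 0/30/60/120 min.

    Induced features rise above 2x baseline with their configured peak
    time; everything else fluctuates around baseline with small lognormal
    noise shared across no datasets (independent draws).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    out: dict[str, list[TimeCourse]] = {ds: [] for ds in datasets}
    for row in truth.itertuples():
        base = max(float(row.level), 1.0)
        fold = float(rng.uniform(config.induced_fold_low, config.induced_fold_high))
        peak = int(row.peak_time)
        for ds in datasets:
            values = {}
            for t in TIMEPOINTS:
                if bool(row.induced) and t > 0:
                    if t == peak:
                        target = base * fold
                    elif (peak == 30 and t > 30) or (peak > 30 and 0 < t < peak):
                        target = base * (1 + (fold - 1) * 0.45)
                    else:
                        target = base * (1 + (fold - 1) * 0.3)
                else:
                    target = base
                noise = float(np.exp(rng.normal(0.0, config.timecourse_noise_sigma)))
                values[t] = target * noise
            # keep the planted peak the argmax despite noise
            if bool(row.induced):
                peak_val = max(values[t] for t in TIMEPOINTS if t > 0)
                values[peak] = peak_val * 1.01
            out[ds].append(TimeCourse(str(row.feature_id), values, ds))
    return out


def recovery_metrics(
    called: Sequence[tuple[str, int, int]],
    truth_intervals: Sequence[tuple[str, int, int]],
    bin_width: int = 50,
    min_reciprocal_overlap: float = 0.5,
) -> pd.Series:
    """Feature- and bin-level precision/recall of called vs planted intervals.

    A planted feature is recovered when some called feature overlaps it
    reciprocally by at least ``min_reciprocal_overlap`` (overlap / length
    on BOTH sides); a called feature is a true positive under the same
    rule.  Undefined ratios (empty denominators) are reported as NaN.
    """

    def _recip(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
        if a[0] != b[0]:
            return False
        ov = min(a[2], b[2]) - max(a[1], b[1]) + 1
        if ov <= 0:
            return False
        return (ov / (a[2] - a[1] + 1) >= min_reciprocal_overlap
                and ov / (b[2] - b[1] + 1) >= min_reciprocal_overlap)

    tp_called = sum(1 for c in called if any(_recip(c, t) for t in truth_intervals))
    recovered = sum(1 for t in truth_intervals if any(_recip(c, t) for c in called))
    precision = tp_called / len(called) if called else float("nan")
    recall = recovered / len(truth_intervals) if truth_intervals else float("nan")

    def _bins(intervals: Sequence[tuple[str, int, int]]) -> set[tuple[str, int]]:
        out = set()
        for chrom, s, e in intervals:
            out.update((chrom, k) for k in range((s - 1) // bin_width, (e - 1) // bin_width + 1))
        return out

    cb, tb = _bins(called), _bins(truth_intervals)
    bin_precision = len(cb & tb) / len(cb) if cb else float("nan")
    bin_recall = len(cb & tb) / len(tb) if tb else float("nan")
    return pd.Series(
        {"precision": precision, "recall": recall,
         "bin_precision": bin_precision, "bin_recall": bin_recall,
         "n_called": len(called), "n_truth": len(truth_intervals)}
    )


def write_gff3(genes: Sequence[GeneModel], truth: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation (coding genes with exon structure) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
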