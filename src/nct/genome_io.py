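"""Annotation and coverage I/O, bin grids, count aggregation and normalization.

All internal coordinates are 1-based inclusive, matching the coordinate
convention of the Neurospora crassa NC10/NC12 assemblies.  BED output
converts to 0-based half-open on the way out.

The genome is segmented into fixed-width, non-overlapping units ("bins",
default 50 bp); every downstream detection step operates on per-bin read
counts, optionally split by strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "CoverageTrack",
    "BinGrid",
    "read_annotation",
    "read_chrom_sizes",
    "read_bedgraph",
    "read_placements",
    "build_bin_grid",
    "aggregate_counts",
    "normalize_counts",
    "write_bed6",
]

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation records."""


@dataclass
class GeneModel:
    """A protein-coding gene with its exon/intron structure.

    Coordinates are 1-based inclusive.  Introns are derived as exactly the
    gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            self.exons = [(self.start, self.end)]
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(f"{self.gene_id}: exon start {s} > end {e}")
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span ({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise AnnotationError(f"{self.gene_id}: overlapping exons at {s}")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tss(self) -> int:
        """Transcription start site (5' end in gene orientation)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Transcription termination site (3' end in gene orientation)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class CoverageTrack:
    """Read 5'-end placements for one sequencing library.

    ``placements`` maps (chrom, strand) -- strand is None for unstranded
    libraries -- to a pair of aligned arrays (1-based positions, counts of
    read 5' ends at that position).
    """

    library_id: str
    stranded: bool
    placements: dict[tuple[str, str | None], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @property
    def total_reads(self) -> int:
        return int(sum(int(c.sum()) for _, c in self.placements.values()))

    def chromosomes(self) -> set[str]:
        return {chrom for chrom, _ in self.placements}

    def add(self, chrom: str, strand: str | None, positions: np.ndarray, counts: np.ndarray) -> None:
        if self.stranded and strand not in STRANDS:
            raise ValueError(f"stranded track requires '+'/'-' strand, got {strand!r}")
        if not self.stranded and strand is not None:
            raise ValueError("unstranded track takes strand=None")
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if (counts < 0).any():
            raise ValueError("negative placement count")
        key = (chrom, strand)
        if key in self.placements:
            p0, c0 = self.placements[key]
            positions = np.concatenate([p0, positions])
            counts = np.concatenate([c0, counts])
        order = np.argsort(positions, kind="stable")
        self.placements[key] = (positions[order], counts[order])


@dataclass
class BinGrid:
    """The genome tiled into non-overlapping fixed-width units.

    ``bins[chrom]`` is the bin count for that chromosome; bin k (0-based)
    spans [k*w + 1, min((k+1)*w, chrom_size)] in 1-based inclusive
    coordinates.  ``counts[(library, strand)][chrom]`` are arrays aligned
    to the bins; strand is None for unstranded libraries.
    """

    bin_width: int
    chrom_sizes: dict[str, int]
    counts: dict[tuple[str, str | None], dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_width)

    def bin_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """1-based inclusive (starts, ends) of the bins of a chromosome."""
        n = self.n_bins(chrom)
        starts = np.arange(n, dtype=np.int64) * self.bin_width + 1
        ends = np.minimum(starts + self.bin_width - 1, self.chrom_sizes[chrom])
        return starts, ends

    def bin_index(self, chrom: str, pos: int | np.ndarray) -> np.ndarray:
        return (np.asarray(pos, dtype=np.int64) - 1) // self.bin_width

    def libraries(self) -> list[tuple[str, str | None]]:
        return list(self.counts)

    def get_counts(self, library_id: str, strand: str | None, chrom: str) -> np.ndarray:
        return self.counts[(library_id, strand)][chrom]

    def total_reads(self, library_id: str, strand: str | None = None) -> int:
        """Total placements for a library; strand=None on a stranded library
        sums both strands."""
        keys = [k for k in self.counts if k[0] == library_id]
        if strand is not None:
            keys = [k for k in keys if k[1] == strand]
        if not keys:
            raise KeyError(f"no counts for library {library_id!r}")
        return int(sum(arr.sum() for k in keys for arr in self.counts[k].values()))

    def stacked(self, library_id: str, strand: str | None) -> np.ndarray:
        """All chromosomes' count arrays concatenated in chromosome order."""
        per = self.counts[(library_id, strand)]
        return np.concatenate([per[c] for c in self.chromosomes])


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column chrom.sizes TSV (name, length in bp)."""
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{i}: expected 2 columns")
        sizes[parts[0]] = int(parts[1])
    return sizes


def _parse_gff3_attributes(attr: str) -> dict[str, str]:
    out = {}
    for kv in attr.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    id_to_gene: dict[str, str] = {}
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise AnnotationError(f"{path}:{i}: expected 9 GFF3 columns, got {len(parts)}")
        chrom, _, ftype, start, end, _, strand, _, attr = parts
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(f"{path}:{i}: non-integer coordinates") from exc
        if start_i <= 0 or end_i <= 0:
            raise AnnotationError(f"{path}:{i}: non-positive coordinate")
        attrs = _parse_gff3_attributes(attr)
        if ftype in ("gene", "ncRNA_gene"):
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise AnnotationError(f"{path}:{i}: gene record without ID")
            genes[gid] = GeneModel(gid, chrom, start_i, end_i, strand, exons=[(start_i, end_i)])
            exons.setdefault(gid, [])
            id_to_gene[gid] = gid
        elif ftype in ("mRNA", "transcript", "ncRNA"):
            parent = attrs.get("Parent")
            tid = attrs.get("ID")
            if parent in id_to_gene and tid is not None:
                id_to_gene[tid] = id_to_gene[parent]
        elif ftype == "exon":
            parent = attrs.get("Parent")
            gid = id_to_gene.get(parent, parent)
            if gid is None:
                raise AnnotationError(f"{path}:{i}: exon without Parent")
            exons.setdefault(gid, []).append((start_i, end_i))
    out = []
    for gid, gene in genes.items():
        ex = sorted(set(exons.get(gid) or []))
        out.append(GeneModel(gid, gene.chrom, gene.start, gene.end, gene.strand,
                             exons=ex or [(gene.start, gene.end)]))
    return sorted(out, key=lambda g: (g.chrom, g.start, g.gene_id))


def _read_bed12(path: Path) -> list[GeneModel]:
    out = []
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise AnnotationError(f"{path}:{i}: expected 12 BED columns, got {len(parts)}")
        chrom = parts[0]
        chrom_start = int(parts[1])  # 0-based
        name, strand = parts[3], parts[5]
        block_count = int(parts[9])
        block_sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in parts[11].rstrip(",").split(",")]
        if len(block_sizes) != block_count or len(block_starts) != block_count:
            raise AnnotationError(f"{path}:{i}: block count mismatch")
        exons = [
            (chrom_start + bs + 1, chrom_start + bs + sz)
            for bs, sz in zip(block_starts, block_sizes)
        ]
        out.append(
            GeneModel(name, chrom, exons[0][0], exons[-1][1], strand, exons=exons)
        )
    return sorted(out, key=lambda g: (g.chrom, g.start, g.gene_id))


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 or BED12 (by file extension).

    Returns one :class:`GeneModel` per gene with introns derived from the
    exon structure.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    return _read_gff3(path)


def read_bedgraph(
    path: str | Path, library_id: str, strand: str | None = None,
    track: CoverageTrack | None = None,
) -> CoverageTrack:
    """Read a 4-column bedGraph (chrom, start0, end0, value) as coverage.

    Values are per-base placement counts: every base in [start0, end0)
    carries ``value`` read 5' ends.  Pass ``strand`` and reuse ``track`` to
    accumulate the two strand files of a strand-specific library.
    """
    if track is None:
        track = CoverageTrack(library_id, stranded=strand is not None)
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise AnnotationError(f"{path}:{i}: expected 4 bedGraph columns")
        chrom, s0, e0, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        if val < 0:
            raise AnnotationError(f"{path}:{i}: negative coverage value")
        per_chrom.setdefault(chrom, []).append((s0, e0, int(round(val))))
    for chrom, ivs in per_chrom.items():
        pos_chunks, cnt_chunks = [], []
        for s0, e0, v in ivs:
            if v == 0 or e0 <= s0:
                continue
            pos_chunks.append(np.arange(s0 + 1, e0 + 1, dtype=np.int64))
            cnt_chunks.append(np.full(e0 - s0, v, dtype=np.int64))
        if pos_chunks:
            track.add(chrom, strand, np.concatenate(pos_chunks), np.concatenate(cnt_chunks))
        else:
            track.add(chrom, strand, np.empty(0, np.int64), np.empty(0, np.int64))
    return track


def read_placements(
    path: str | Path, library_id: str, stranded: bool = True
) -> CoverageTrack:
    """Read a placement TSV (chrom, pos 1-based, strand-or-'.', count).

    Each row records ``count`` read 5' ends at ``pos``.
    """
    track = CoverageTrack(library_id, stranded=stranded)
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "pos", "strand", "count"], dtype={"chrom": str})
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
        strand_key = None if strand == "." else str(strand)
        track.add(str(chrom), strand_key, grp["pos"].to_numpy(np.int64),
                  grp["count"].to_numpy(np.int64))
    return track


def build_bin_grid(chrom_sizes: Mapping[str, int], width: int = 50) -> BinGrid:
    """Tile each chromosome with non-overlapping ``width``-bp bins.

    The last bin of a chromosome is truncated at the chromosome end.
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    for chrom, size in chrom_sizes.items():
        if size < 1:
            raise ValueError(f"chromosome {chrom} has non-positive size {size}")
    return BinGrid(bin_width=width, chrom_sizes=dict(chrom_sizes))


def aggregate_counts(track: CoverageTrack, grid: BinGrid) -> BinGrid:
    """Assign each read placement to the bin containing its 5'-most base.

    Fills per-strand arrays for stranded tracks, a single (library, None)
    array otherwise.  Returns the grid (counts added in place).
    """
    unknown = track.chromosomes() - set(grid.chrom_sizes)
    if unknown:
        raise ValueError(f"track chromosomes not in grid: {sorted(unknown)}")
    strands: Iterable[str | None] = STRANDS if track.stranded else (None,)
    for strand in strands:
        per_chrom = {
            chrom: np.zeros(grid.n_bins(chrom), dtype=np.int64)
            for chrom in grid.chromosomes
        }
        for (chrom, s), (pos, cnt) in track.placements.items():
            if s != strand:
                continue
            if pos.size == 0:
                continue
            if (pos < 1).any() or (pos > grid.chrom_sizes[chrom]).any():
                raise ValueError(
                    f"placement outside chromosome {chrom} (size {grid.chrom_sizes[chrom]})"
                )
            idx = grid.bin_index(chrom, pos)
            np.add.at(per_chrom[chrom], idx, cnt)
        grid.counts[(track.library_id, strand)] = per_chrom
    return grid


def normalize_counts(
    counts: np.ndarray | Sequence[float],
    library_total: float,
    lengths: np.ndarray | Sequence[float],
    scale: float = 1e6,
) -> np.ndarray:
    """Normalize feature read counts by library total and feature length.

    value = (count / library_total) * scale / (length / 1000), i.e.
    counts-per-million per kilobase with the default scale.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if library_total <= 0:
        raise ValueError(f"library total must be > 0, got {library_total}")
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be > 0")
    return counts / library_total * scale / (lengths / 1000.0)


def write_bed6(
    records: Iterable[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write (chrom, start1, end1, name, score, strand) records as BED6.

    Input coordinates are 1-based inclusive; BED is 0-based half-open.
    """
    with open(path, "w") as fh:
        for chrom, start1, end1, name, score, strand in records:
            fh.write(f"{chrom}\t{start1 - 1}\t{end1}\t{name}\t{score:.6g}\t{strand}\n")
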