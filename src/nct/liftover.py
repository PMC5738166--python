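"""Interval liftover between assembly versions related per chromosome by
identity, whole-chromosome reverse complement, or reverse complement of a
single internal segment.

This covers the NC10 -> NC12 relation of the Neurospora crassa assemblies:
chromosomes 1-5 are identical, chromosome 6 has one internal segment
reverse complemented, and chromosome 7 is reverse complemented whole.
Reverse-complement operations flip strand; strandless features stay
strandless.  All three operations are involutions, so the map is its own
inverse.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "Identity",
    "RevCompWhole",
    "RevCompSegment",
    "AssemblyMap",
    "convert_interval",
    "invert_map",
    "NEUROSPORA_NC10_TO_NC12",
]

FLIP = {"+": "-", "-": "+", ".": "."}


@dataclass(frozen=True)
class Identity:
    pass


@dataclass(frozen=True)
class RevCompWhole:
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chromosome length must be >= 1")


@dataclass(frozen=True)
class RevCompSegment:
    start: int  # 1-based inclusive segment bounds
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid segment ({self.start}, {self.end})")


Operation = Identity | RevCompWhole | RevCompSegment


@dataclass
class AssemblyMap:
    """One operation per chromosome; unlisted chromosomes are identity."""

    operations: dict[str, Operation]

    def op(self, chrom: str) -> Operation:
        return self.operations.get(chrom, Identity())

    def to_json(self, path: str | Path) -> None:
        enc = {}
        for chrom, op in self.operations.items():
            if isinstance(op, Identity):
                enc[chrom] = {"op": "identity"}
            elif isinstance(op, RevCompWhole):
                enc[chrom] = {"op": "revcomp_whole", "length": op.length}
            else:
                enc[chrom] = {"op": "revcomp_segment", "start": op.start, "end": op.end}
        Path(path).write_text(json.dumps(enc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AssemblyMap":
        raw = json.loads(Path(path).read_text())
        ops: dict[str, Operation] = {}
        for chrom, d in raw.items():
            kind = d["op"]
            if kind == "identity":
                ops[chrom] = Identity()
            elif kind == "revcomp_whole":
                ops[chrom] = RevCompWhole(int(d["length"]))
            elif kind == "revcomp_segment":
                ops[chrom] = RevCompSegment(int(d["start"]), int(d["end"]))
            else:
                raise ValueError(f"unknown operation {kind!r} for {chrom}")
        return cls(ops)


def convert_interval(
    iv: tuple[str, int, int] | tuple[str, int, int, str],
    amap: AssemblyMap,
) -> tuple:
    """Map a 1-based inclusive interval (chrom, start, end[, strand]).

    Under a segment reverse complement the interval must lie entirely
    inside or entirely outside the segment; straddling intervals have no
    well-defined image and raise.  Length is always preserved.
    """
    chrom, start, end = iv[0], int(iv[1]), int(iv[2])
    strand = iv[3] if len(iv) > 3 else None
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    op = amap.op(chrom)
    flipped = False
    if isinstance(op, Identity):
        new_start, new_end = start, end
    elif isinstance(op, RevCompWhole):
        if end > op.length:
            raise ValueError(f"interval end {end} beyond chromosome length {op.length}")
        new_start, new_end = op.length - end + 1, op.length - start + 1
        flipped = True
    else:  # RevCompSegment
        a, b = op.start, op.end
        inside = a <= start and end <= b
        outside = end < a or start > b
        if inside:
            new_start, new_end = a + b - end, a + b - start
            flipped = True
        elif outside:
            new_start, new_end = start, end
        else:
            raise ValueError(
                f"interval ({chrom},{start},{end}) straddles reverse-complemented "
                f"segment ({a},{b}); no defined image"
            )
    if strand is None:
        return (chrom, new_start, new_end)
    return (chrom, new_start, new_end, FLIP[strand] if flipped else strand)


def invert_map(amap: AssemblyMap) -> AssemblyMap:
    """The inverse map; every supported operation is self-inverse."""
    return AssemblyMap(dict(amap.operations))


def convert_bed(
    lines: Iterable[str], amap: AssemblyMap
) -> list[str]:
    """Convert BED6 lines (0-based half-open) through the map."""
    out = []
    for line in lines:
        if not line.strip() or line.startswith(("#", "track")):
            out.append(line)
            continue
        parts = line.rstrip("\n").split("\t")
        chrom, s0, e0 = parts[0], int(parts[1]), int(parts[2])
        strand = parts[5] if len(parts) > 5 else "."
        c, s1, e1, st = convert_interval((chrom, s0 + 1, e0, strand), amap)
        parts[0], parts[1], parts[2] = c, str(s1 - 1), str(e1)
        if len(parts) > 5:
            parts[5] = st
        out.append("\t".join(parts))
    return out


# NC10 -> NC12: chromosomes 1-5 identical; chromosome 6 has positions
# 1,847,027-2,788,223 reverse complemented; chromosome 7 is reverse
# complemented whole (length inferred from the published coordinate pairs).
NEUROSPORA_NC10_TO_NC12 = AssemblyMap(
    {
        "6": RevCompSegment(1_847_027, 2_788_223),
        "7": RevCompWhole(4_255_303),
    }
)
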