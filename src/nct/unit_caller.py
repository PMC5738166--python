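"""Bin-level logistic transcription classifier and unit segmentation.

The genome, tiled into 50-bp bins, is scored with a logistic regression

    logit(pi_i) = beta0 + beta1 * t(x_i_rna) + beta2 * t(x_i_pol)

where pi_i is the probability that bin i is transcribed (the "coding
indication" target, 1 when the bin overlaps an annotated exon), x_i_rna and
x_i_pol are the bin's RNA-seq and RNAPII ChIP-seq counts, and t is a
configurable covariate transform (default: ln(1 + counts-per-million)).
The model is fitted on a random 60% training subsample of the bins; bins
whose fitted log-odds exceed a natural-log-ratio cutoff of 1.5 are merged
into maximal runs, the transcription units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .genome_io import BinGrid, GeneModel, normalize_counts

__all__ = [
    "LogitModel",
    "BinLabeling",
    "TranscriptionUnit",
    "label_bins",
    "fit_logit",
    "score_bins",
    "call_units",
]

# t(x): transforms applied to per-bin counts before the logistic fit.
# "log1p_cpm" first scales counts to counts-per-million of the library.
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log1p": np.log1p,
    "log1p_cpm": np.log1p,  # CPM scaling handled before the transform
}


@dataclass
class LogitModel:
    """Specification + fitted state of the bin-level transcription classifier."""

    beta0: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    cutoff: float = 1.5
    train_fraction: float = 0.6
    seed: int = 0
    covariate_transform: str = "log1p_cpm"
    trials_per_bin: int = 1
    bse: tuple[float, float, float] | None = None
    converged: bool | None = None
    separation_warning: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction <= 1):
            raise ValueError(f"train_fraction must be in (0, 1], got {self.train_fraction}")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.covariate_transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.covariate_transform!r}")

    @property
    def fitted(self) -> bool:
        return self.beta0 is not None

    @property
    def coef(self) -> np.ndarray:
        if not self.fitted:
            raise ValueError("model not fitted")
        return np.array([self.beta0, self.beta1, self.beta2], dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LogitModel":
        d = json.loads(Path(path).read_text())
        if d.get("bse") is not None:
            d["bse"] = tuple(d["bse"])
        return cls(**d)


@dataclass
class BinLabeling:
    """Per-bin binary transcription target, aligned to a grid's stacked bins."""

    labels: np.ndarray
    source: str = "bin overlaps an annotated exon by >= 1 bp"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")


@dataclass
class TranscriptionUnit:
    """A maximal run of super-cutoff bins: one contiguous transcribed interval."""

    unit_id: str
    chrom: str
    start: int  # 1-based inclusive, bin-aligned
    end: int
    strand: str = "."
    mean_logodds: float = float("nan")
    counts: dict[str, float] = field(default_factory=dict)  # raw per library
    normalized: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def label_bins(
    grid: BinGrid, genes: list[GeneModel], strand: str | None = None
) -> BinLabeling:
    """Label each bin 1 iff it overlaps any annotated exon by >= 1 bp.

    With ``strand`` set, only genes on that strand contribute (the target
    for the per-strand fits of strand-specific libraries).
    """
    per_chrom = {c: np.zeros(grid.n_bins(c), dtype=np.int8) for c in grid.chromosomes}
    w = grid.bin_width
    for gene in genes:
        if gene.chrom not in per_chrom:
            continue
        if strand is not None and gene.strand != strand:
            continue
        arr = per_chrom[gene.chrom]
        for s, e in gene.exons:
            lo = (s - 1) // w
            hi = min((e - 1) // w, arr.size - 1)
            arr[lo : hi + 1] = 1
    return BinLabeling(np.concatenate([per_chrom[c] for c in grid.chromosomes]))


def _design_matrix(
    grid: BinGrid, model: LogitModel, rna_key: tuple[str, str | None],
    pol_key: tuple[str, str | None] | None,
) -> np.ndarray:
    """Stacked [1, t(x_rna), t(x_pol)] design across chromosomes.

    With ``pol_key`` None the design has a single covariate column (used
    when no independent second library exists, e.g. the per-strand fits
    on strand-specific RNA-seq alone, where duplicating the RNA column
    would make the design singular).
    """
    cols = []
    for key in (rna_key, pol_key):
        if key is None:
            continue
        x = grid.stacked(*key).astype(float)
        if model.covariate_transform == "log1p_cpm":
            total = grid.total_reads(key[0], key[1])
            if total > 0:
                x = x / total * 1e6
        cols.append(TRANSFORMS[model.covariate_transform](x))
    return np.column_stack([np.ones(cols[0].size), *cols])


def fit_logit(
    grid: BinGrid,
    labeling: BinLabeling,
    model: LogitModel,
    rna_library: str = "rna",
    pol_library: str | None = "pol",
    strand: str | None = None,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogitModel:
    """Fit the logistic model on a seeded random training subsample of bins.

    The training set is a uniform random draw of ``train_fraction`` of the
    bins (the genome's units).  Labels are modelled as Binomial(n_i=1, pi_i);
    the fit maximizes the Bernoulli log-likelihood via IRLS.  Perfect
    separation produces a capped-iteration fit flagged on the model rather
    than an error.
    """
    pol_key = None if pol_library is None else (pol_library, strand)
    X = _design_matrix(grid, model, (rna_library, strand), pol_key)
    y = labeling.labels.astype(float)
    if y.size != X.shape[0]:
        raise ValueError(f"labeling has {y.size} bins, grid has {X.shape[0]}")
    rng = np.random.default_rng(model.seed)
    n_train = max(1, int(round(model.train_fraction * y.size)))
    idx = rng.choice(y.size, size=n_train, replace=False)
    y_tr, X_tr = y[idx], X[idx]
    if y_tr.min() == y_tr.max():
        raise ValueError("training subsample contains a single label class")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = sm.GLM(y_tr, X_tr, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
        sep = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
    params = [float(v) for v in fit.params]
    bse = [float(v) for v in fit.bse]
    if pol_library is None:
        params.append(0.0)
        bse.append(0.0)
    model.beta0, model.beta1, model.beta2 = params
    model.bse = tuple(bse)
    model.converged = bool(fit.converged)
    model.separation_warning = sep
    return model


def score_bins(
    model: LogitModel,
    grid: BinGrid,
    rna_library: str = "rna",
    pol_library: str | None = "pol",
    strand: str | None = None,
) -> np.ndarray:
    """Per-bin fitted log-odds (the natural-log ratio pi/(1-pi)), stacked."""
    pol_key = None if pol_library is None else (pol_library, strand)
    X = _design_matrix(grid, model, (rna_library, strand), pol_key)
    coef = model.coef[: X.shape[1]]
    return X @ coef


def _split_by_chrom(grid: BinGrid, stacked: np.ndarray) -> dict[str, np.ndarray]:
    out, offset = {}, 0
    for chrom in grid.chromosomes:
        n = grid.n_bins(chrom)
        out[chrom] = stacked[offset : offset + n]
        offset += n
    if offset != stacked.size:
        raise ValueError(f"stacked array has {stacked.size} bins, grid has {offset}")
    return out


def call_units(
    scores: np.ndarray,
    cutoff: float,
    grid: BinGrid,
    strand: str = ".",
    min_reads: int | None = None,
    min_reads_library: str | None = None,
    id_prefix: str = "TU",
) -> list[TranscriptionUnit]:
    """Merge maximal runs of bins with score strictly above the cutoff.

    A tie (score exactly at the cutoff) is sub-threshold.  With
    ``min_reads`` set, a bin is eligible only if its raw count in
    ``min_reads_library`` (on ``strand`` when stranded) is also >=
    min_reads.  Unit counts are sums over member bins for every library in
    the grid, length-normalized by library total and unit length.
    """
    per_scores = _split_by_chrom(grid, np.asarray(scores, dtype=float))
    eligible = {c: s > cutoff for c, s in per_scores.items()}
    count_strand = strand if strand in ("+", "-") else None
    if min_reads is not None:
        if min_reads_library is None:
            raise ValueError("min_reads requires min_reads_library")
        for chrom in grid.chromosomes:
            raw = grid.get_counts(min_reads_library, count_strand, chrom)
            eligible[chrom] &= raw >= min_reads
    units: list[TranscriptionUnit] = []
    k = 0
    for chrom in grid.chromosomes:
        mask = eligible[chrom]
        if not mask.any():
            continue
        starts_b, ends_b = grid.bin_bounds(chrom)
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(diff == 1)
        run_ends = np.flatnonzero(diff == -1) - 1
        for lo, hi in zip(run_starts, run_ends):
            k += 1
            unit = TranscriptionUnit(
                unit_id=f"{id_prefix}{k:05d}",
                chrom=chrom,
                start=int(starts_b[lo]),
                end=int(ends_b[hi]),
                strand=strand,
                mean_logodds=float(per_scores[chrom][lo : hi + 1].mean()),
            )
            for lib, lib_strand in grid.libraries():
                if count_strand is not None and lib_strand not in (count_strand, None):
                    continue
                raw = float(grid.get_counts(lib, lib_strand, chrom)[lo : hi + 1].sum())
                unit.counts[lib] = raw
                total = grid.total_reads(lib, lib_strand)
                if total > 0:
                    unit.normalized[lib] = float(
                        normalize_counts([raw], total, [unit.length])[0]
                    )
            units.append(unit)
    return units
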