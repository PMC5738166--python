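# Methods

This note records the statistical models, the provenance of every
threshold, the numerical choices, and the synthetic generator's design
and limits.

## 1. Transcription classifier

**Model.** For each 50-bp bin *i* of a non-overlapping genome tiling,
`unit_caller` fits

    logit(pi_i) = beta0 + beta1 * t(x_i_rna) + beta2 * t(x_i_pol)

with a Binomial(n=1) likelihood, where the target is 1 iff the bin
overlaps an annotated coding exon by at least 1 bp and the covariates
are the bin's pooled RNA-seq and RNAPII ChIP-seq read counts.  The
transform *t* defaults to ln(1 + CPM) (counts scaled to
counts-per-million of the library, then log1p); `identity` and plain
`log1p` are available for testing and for pre-normalized inputs.  The
CPM scaling makes the covariates and hence the fitted coefficients
invariant to sequencing depth.

**Fitting.** A uniform random 60% subsample of bins (seeded) is the
training set; the fit is IRLS via `statsmodels` GLM.  This is a standard
maximum-likelihood logistic fit, deliberately delegated to an
established library.  Quasi-separation (possible when classes barely
overlap) is caught and flagged on the model rather than raised.  When
no second library is supplied (per-strand fits on strand-specific
RNA-seq, where ChIP has no strand), the design drops to a single
covariate; duplicating the RNA column instead would make the design
singular and the pseudo-inverse returns arbitrary, exploding
coefficient splits.

**Calling.** Bins with fitted log-odds strictly above the natural-log
ratio cutoff 1.5 (posterior odds e^1.5 ≈ 4.5 : 1) are transcribed;
maximal runs of such bins form transcription units.  Ties at the cutoff
are sub-threshold.  For stranded calling a bin must additionally carry
≥ 10 raw reads on the strand.

**Why the classifier generalizes.** Exon labels are a proxy, not the
estimand.  Transcribed-but-unannotated bins (lincRNAs, antisense) enter
training labeled 0, so the fitted boundary settles where the label-1
mass (coding exons, including weakly expressed genes) balances the
mislabeled noncoding mass.  A wide coding dynamic range anchors the
boundary *below* typical noncoding expression — weakly expressed coding
genes are the effective calibration set — which is exactly the regime of
real RNA-seq and the regime the synthetic defaults reproduce.

## 2. lincRNA catalog

Units overlapping an annotated gene by ≥ 1 bp are coding; units ≥ 500 bp
from the nearest gene are lincRNA candidates; the remainder (closer than
500 bp but not overlapping) are discarded as possible UTR fragments.
Candidates separated by gaps < 100 bp merge into one feature (counts are
re-aggregated over the merged span).  Candidates shorter than 100 bp
(2 bins) are dropped as shot noise — a package choice; the shortest
published features (antisense, median 251 bp) are far above it.  A
candidate strictly above the median length-normalized polysome signal of
coding units is "polysome positive" and leaves the confident set; of
the positives, only those with predicted coding potential stay excluded
("possibly coding"), the rest are recovered into the final catalog.
Coding-potential assessment itself (CPC/BLASTX in the original work) is
out of scope; the pipeline takes the flags as input, and the synthetic
pipeline supplies all-False flags.

## 3. Antisense calling

Per-strand classifier fits (strand-restricted exon labels, single RNA
covariate) yield stranded units.  A unit is a paired antisense call when
it overlaps an annotated gene on the opposite strand whose own strand is
expressed; multiple fragments over one gene merge into one call spanning
their extremes.  Calls within 500 bp of a same-strand neighboring gene
are removed (run-through transcription cannot be excluded).  Separately,
`gene_strand_averages` computes per-gene mean reads per bin on each
strand; genes with sense < 1 and antisense > 1 reads/bin in *every*
dataset — strict inequalities — and no overlapping gene form the
antisense-only set.  Dark and light strand-specific datasets are scaled
to a common reference depth before these absolute thresholds are
applied.

## 4. Splice junctions

Junctions with implied intron length outside [50, 500000] bp are
rejected on input.  The read-support cutoff is the 25th percentile
(linear interpolation, `numpy.quantile`) of the support of junctions
exactly matching annotated introns.  Classes, in priority order:
`perfect` (exact donor and acceptor match; never filtered),
`alternative` (shares donor or acceptor with an annotated intron),
`weak` (both ends within ±10 bp of an annotated intron), `novel`
(neither), with non-annotated junctions below the cutoff `filtered`.
Support ties at the cutoff are kept.  A feature "contains" a junction
when the junction lies entirely inside it and carries ≥ 10 reads.

## 5. Light response

Fold change uses a pseudocount of 1 on both numerator and denominator,
so zero baselines stay finite.  A feature is induced iff its maximum
fold change over post-zero time points is strictly > 2.0 in every
dataset.  Induced features peaking at 30 min are early; `argmax` takes
the first maximum, so ties break toward the earlier time.  Reported
percentages round half away from zero (Python's banker's rounding would
turn e.g. 2.45 into 2.4).

## 6. Liftover

Assembly maps are one operation per chromosome: identity,
whole-chromosome reverse complement (start' = L − end + 1), or reverse
complement of an internal segment [a, b] (start' = a + b − end).  Both
reverse-complement forms flip strand and preserve length; intervals
straddling a segment boundary have no well-defined image and raise.
Every operation is an involution, so the inverse map equals the forward
map.  The built-in map reverse-complements positions
1,847,027–2,788,223 of chromosome 6 and all of chromosome 7; the
chromosome 7 length (4,255,303) is inferred from the published
coordinate pair (L − 1,362,500 + 1 = 2,892,804).

## 7. Synthetic generator

**Structure.** Four 500-kb chromosomes (problem size is a package
choice — large enough for ~40k bins and stable fits, small enough for
seconds-scale runs).  Features are packed left to right with ≥ 1.2 kb
gaps, so lincRNAs are automatically > 500 bp from genes.  Lengths are
lognormal around the published medians (coding 1782 bp, lincRNA 551 bp,
antisense 251 bp); 80% of coding genes carry 1–4 introns of median
69 bp.  Antisense features sit on the strand opposite a host gene with
their 5′ start jittered around the sense TTS (the observed 3′-biased
positioning); hosts are drawn from genes at or above the 25th expression
percentile, since pairing requires an expressed sense partner.  Eight
antisense-only hosts have sense expression zeroed.

**Counts.** Per-bin counts are negative binomial with variance
m + m²/shape (shape 30) around background + feature contribution,
pro-rated at feature edges.  Per-library depth multipliers (10× for the
pooled unstranded RNA/ChIP/polysome libraries, 1.5× for each
strand-specific library) mirror the order-of-magnitude depth gap between
pooled and individual libraries in real designs.  Polysome signal is
restricted to coding features, which makes the polysome filter exact on
synthetic data (0 planted lincRNAs lost is therefore a hard
expectation, not a statistical one).

**Expression regime.** The default configuration is *defined* as the
well-separated, ≥ 10× signal-to-noise regime.  Concretely: coding median
40 reads/bin with lognormal sigma 1.5 (wide dynamic range — this anchors
the classifier boundary below noncoding levels, see §1), lincRNA median
16, antisense median 30, per-feature level sigma 0.2, backgrounds
1.0/0.4/0.2 reads per bin.  These values were chosen from the fit
geometry so that planted noncoding bins clear the fitted decision
boundary by ≥ 2 standard deviations of the combined count + level noise
while staying below the coding median (noncoding transcripts accumulate
at lower levels than mRNAs).  They were frozen before the acceptance
tests were written.

**Junctions and time courses.** One junction per planted intron with
support proportional to expression (floor 5), plus 30 decoys at 1 read —
below the annotated 25th-percentile cutoff by construction.  Time
courses at 0/30/60/120 min put induced features at 3–8× baseline at
their planted peak (small lognormal noise, with the planted peak nudged
to stay the argmax so timing truth is exact).

**Limits.** The generator is a caricature: no GC or mappability bias, no
fragment-length effects, no positional autocorrelation of noise beyond
the feature means, uniform decoy placement, no overlapping or nested
genes, no UTR structure (which is why the < 500 bp "discard" zone is
empty by construction), and independent noise across libraries.
Recovery numbers on it measure the pipeline's logic, not performance on
real libraries.  Published catalog sizes (1478 lincRNAs, 1056 antisense)
come from ~175M-read datasets and are not reproducible at this scale;
they are validated as arithmetic on printed counts instead.

## 8. Numerical choices

- All randomness flows from integer seeds through `numpy.random.default_rng`;
  pipeline results are bit-reproducible for a seed.
- Coordinates are 1-based inclusive internally; BED output is 0-based
  half-open; bin k of width w covers (k·w + 1, …, (k+1)·w), truncated at
  chromosome ends; a read is assigned to the bin of its 5′-most base.
- Normalization: counts / library_total × 10⁶ / (length_kb) — CPM per kb.
- Medians via `statistics.median` / `numpy.median` (mean of central pair
  for even n); quantiles via `numpy.quantile` linear interpolation.
- Percentage rounding is half-away-from-zero, implemented as
  sign(x) · floor(|x| · 10^d + 0.5) / 10^d (Python's built-in `round`
  is banker's rounding and would, e.g., turn 2.45 into 2.4).
- Interval overlap queries use `intervaltree`; run detection uses a
  padded `numpy.diff` scan.
- Reciprocal-overlap recovery (≥ 0.5 on both sides) is the package's own
  criterion for matching called to planted features; the original study
  had no ground truth and hence no recovery metric.
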