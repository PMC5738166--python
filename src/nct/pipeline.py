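"""End-to-end orchestration: bin -> fit -> call -> classify -> antisense ->
splice -> light, with one config object carrying every threshold.

The defaults are the thresholds of the detection procedure: 50-bp bins,
ln-ratio cutoff 1.5, 60% training fraction, 500-bp intergenic rule,
100-bp lincRNA merge gap, minimum 10 reads per bin for stranded calling,
sense < 1 / antisense > 1 reads per bin for antisense-only loci, 2-fold
light induction, junction cutoff at the 25% quantile of annotated-intron
coverage, and 10 spliced reads for junction-in-feature counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import antisense_caller as ac
from . import genome_io, light_response, splice_classifier, synthetic_data
from . import transcript_classifier as tc
from . import unit_caller as uc

__all__ = ["PipelineConfig", "run_synthetic_pipeline"]


@dataclass
class PipelineConfig:
    bin_width: int = 50
    cutoff: float = 1.5
    train_fraction: float = 0.6
    intergenic_gap: int = 500
    merge_gap: int = 100
    min_reads_per_bin: int = 10
    sense_below: float = 1.0
    antisense_above: float = 1.0
    fold_threshold: float = 2.0
    pseudocount: float = 1.0
    junction_quantile: float = 0.25
    min_spliced_reads: int = 10
    weak_tolerance: int = 10
    min_candidate_length: int = 100  # drop sub-100-bp lincRNA candidates (shot noise)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bin_width", "intergenic_gap", "merge_gap", "min_reads_per_bin",
                     "fold_threshold", "min_spliced_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def run_synthetic_pipeline(
    sim_config: synthetic_data.SimulationConfig | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate a genome and run every detection stage against the planted
    truth.  Returns a results dictionary with the called catalogs, truth,
    recovery metrics and per-stage summaries; writes BED/TSV outputs and a
    manifest when ``out_dir`` is given."""
    sim = sim_config or synthetic_data.SimulationConfig()
    cfg = config or PipelineConfig(seed=sim.seed)

    genes, truth = synthetic_data.simulate_genome(sim)
    grid = synthetic_data.simulate_coverage(genes, truth, sim)

    # --- unstranded unit calling (RNA-seq + RNAPII) ---
    labeling = uc.label_bins(grid, genes)
    model = uc.fit_logit(
        grid, labeling,
        uc.LogitModel(cutoff=cfg.cutoff, train_fraction=cfg.train_fraction, seed=cfg.seed),
        rna_library="rna", pol_library="pol",
    )
    scores = uc.score_bins(model, grid, rna_library="rna", pol_library="pol")
    units = uc.call_units(scores, model.cutoff, grid)

    # --- coding vs lincRNA classification ---
    calls = tc.classify_units(units, genes, min_intergenic_gap=cfg.intergenic_gap)
    calls = [
        c for c in calls
        if c.status != "linc_candidate" or c.unit.length >= cfg.min_candidate_length
    ]
    calls = tc.merge_linc_segments(calls, max_gap=cfg.merge_gap)
    coding = [c for c in calls if c.status == "coding"]
    candidates = [c for c in calls if c.status == "linc_candidate"]
    poly_thr = tc.polysome_threshold(coding, polysome_library="polysome")
    confident, positive = tc.apply_polysome_filter(candidates, poly_thr, "polysome")
    # coding-potential stub: no synthetic candidate carries an ORF signal
    flags = {c.unit.unit_id: False for c in positive}
    final_linc, possibly_coding = tc.assemble_final_catalog(confident, positive, flags)

    # --- antisense calling from strand-specific coverage ---
    stranded_labels = {s: uc.label_bins(grid, genes, strand=s) for s in ("+", "-")}
    spec = uc.LogitModel(cutoff=cfg.cutoff, train_fraction=cfg.train_fraction, seed=cfg.seed)
    units_by_strand = ac.call_stranded_units(
        grid, stranded_labels, spec, rna_library="ss_dark",
        min_reads=cfg.min_reads_per_bin,
    )
    paired = ac.pair_sense_antisense(units_by_strand, genes, rna_library="ss_dark")
    paired = ac.filter_by_neighbor_distance(paired, genes, min_gap=cfg.intergenic_gap)
    stranded_totals = [grid.total_reads(ds) for ds in ("ss_dark", "ss_light")]
    reference_total = float(np.mean(stranded_totals))
    averages = {
        ds: ac.gene_strand_averages(grid, genes, ds, reference_total=reference_total)
        for ds in ("ss_dark", "ss_light")
    }
    antisense_only = ac.detect_antisense_only(
        averages, genes, sense_below=cfg.sense_below, antisense_above=cfg.antisense_above
    )
    as_summary = ac.antisense_summary(paired, antisense_only, genes)
    ac.tss_offset_profile(paired, genes)

    # --- splice junctions ---
    jdf = synthetic_data.simulate_junctions(genes, truth, sim)
    junctions = [
        splice_classifier.Junction(r.chrom, int(r.donor), int(r.acceptor), r.strand, int(r.reads))
        for r in jdf.itertuples()
        if splice_classifier.MIN_INTRON <= int(r.acceptor) - int(r.donor) + 1
        <= splice_classifier.MAX_INTRON
    ]
    annotated_introns = [
        (g.chrom, s, e) for g in genes for s, e in g.introns
    ]
    j_cutoff = splice_classifier.annotated_coverage_cutoff(junctions, annotated_introns)
    classified = splice_classifier.classify_junctions(
        junctions, annotated_introns, j_cutoff, weak_tolerance=cfg.weak_tolerance
    )
    class_counts = pd.Series([j.cls for j in classified]).value_counts().to_dict()
    feature_sets = {
        "linc": [
            (r.chrom, int(r.start), int(r.end))
            for r in truth[truth["cls"] == "linc"].itertuples()
        ],
        "antisense": [
            (r.chrom, int(r.start), int(r.end))
            for r in truth[truth["cls"].isin(["antisense", "antisense_only"])].itertuples()
        ],
    }
    in_features = splice_classifier.junctions_in_features(
        classified, feature_sets, min_reads=cfg.min_spliced_reads
    )

    # --- light induction ---
    tcs = synthetic_data.simulate_time_courses(truth, sim)
    induced = light_response.call_induced(
        tcs, threshold=cfg.fold_threshold, pseudocount=cfg.pseudocount
    )
    timing = light_response.classify_timing(induced, next(iter(tcs.values())))
    pairing = {
        str(r.feature_id): str(r.host_gene)
        for r in truth[truth["cls"] == "antisense"].itertuples()
    }
    induced_as = [f for f in induced if f in pairing]
    concordance_pct, n_co = light_response.sense_antisense_concordance(
        induced_as, induced, pairing
    )

    # --- recovery against planted truth ---
    linc_truth = feature_sets["linc"]
    linc_called = [(c.unit.chrom, c.unit.start, c.unit.end) for c in final_linc]
    linc_recovery = synthetic_data.recovery_metrics(linc_called, linc_truth, cfg.bin_width)
    as_truth = [
        (r.chrom, int(r.start), int(r.end))
        for r in truth[truth["cls"] == "antisense"].itertuples()
    ]
    as_called = [(c.chrom, c.start, c.end) for c in paired]
    as_recovery = synthetic_data.recovery_metrics(as_called, as_truth, cfg.bin_width)
    planted_linc_excluded = sum(
        1 for c in positive
        if any(
            _reciprocal(c.unit.chrom, c.unit.start, c.unit.end, t) for t in linc_truth
        )
    )
    as_only_truth_ids = set(truth.loc[truth["cls"] == "antisense_only", "host_gene"])
    as_only_called_ids = {c.gene_id for c in antisense_only}

    results = {
        "genes": genes,
        "truth": truth,
        "model": model,
        "units": units,
        "coding_calls": coding,
        "final_linc": final_linc,
        "possibly_coding": possibly_coding,
        "polysome_threshold": poly_thr,
        "planted_linc_excluded_by_polysome": planted_linc_excluded,
        "paired_antisense": paired,
        "antisense_only": antisense_only,
        "antisense_summary": as_summary,
        "junction_cutoff": j_cutoff,
        "junction_class_counts": class_counts,
        "junctions_in_features": in_features,
        "induced": induced,
        "timing": timing,
        "concordance_pct": concordance_pct,
        "n_coinduced": n_co,
        "linc_recovery": linc_recovery,
        "antisense_recovery": as_recovery,
        "antisense_only_truth": as_only_truth_ids,
        "antisense_only_called": as_only_called_ids,
        "config": cfg,
        "sim_config": sim,
    }
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def _reciprocal(
    chrom: str, start: int, end: int, truth_iv: tuple[str, int, int],
    min_frac: float = 0.5,
) -> bool:
    tc_, ts, te = truth_iv
    if chrom != tc_:
        return False
    ov = min(end, te) - max(start, ts) + 1
    return ov > 0 and ov / (end - start + 1) >= min_frac and ov / (te - ts + 1) >= min_frac


def _write_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _bed(name: str, records) -> None:
        path = out_dir / name
        genome_io.write_bed6(records, path)
        manifest[name] = str(path)

    _bed(
        "linc_catalog.bed",
        [(c.unit.chrom, c.unit.start, c.unit.end, c.unit.unit_id,
          c.unit.mean_logodds, c.unit.strand) for c in results["final_linc"]],
    )
    _bed(
        "antisense.bed",
        [(c.chrom, c.start, c.end, c.gene_id, 0.0, c.strand)
         for c in results["paired_antisense"]],
    )
    truth_path = out_dir / "truth.tsv"
    results["truth"].to_csv(truth_path, sep="\t", index=False)
    manifest["truth.tsv"] = str(truth_path)
    summary = {
        "polysome_threshold": results["polysome_threshold"],
        "junction_cutoff": results["junction_cutoff"],
        "junction_class_counts": results["junction_class_counts"],
        "junctions_in_features": results["junctions_in_features"],
        "n_induced": len(results["induced"]),
        "concordance_pct": results["concordance_pct"],
        "linc_recovery": results["linc_recovery"].to_dict(),
        "antisense_recovery": results["antisense_recovery"].to_dict(),
        "config": asdict(results["config"]),
        "sim_config": asdict(results["sim_config"]),
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    manifest["summary.json"] = str(summary_path)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
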