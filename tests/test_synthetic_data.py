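import numpy as np
import pandas as pd
import pytest

from nct import synthetic_data as sd
from nct.light_response import fold_change


@pytest.fixture(scope="module")
def default_sim():
    cfg = sd.SimulationConfig()
    genes, truth = sd.simulate_genome(cfg)
    return cfg, genes, truth


class TestSimulateGenome:
    def test_deterministic_for_a_seed(self):
        cfg = sd.SimulationConfig(seed=5)
        g1, t1 = sd.simulate_genome(cfg)
        g2, t2 = sd.simulate_genome(sd.SimulationConfig(seed=5))
        pd.testing.assert_frame_equal(t1, t2)
        assert [(g.gene_id, g.start, g.end, tuple(g.exons)) for g in g1] == [
            (g.gene_id, g.start, g.end, tuple(g.exons)) for g in g2
        ]

    def test_seeds_differ(self):
        _, t1 = sd.simulate_genome(sd.SimulationConfig(seed=1))
        _, t2 = sd.simulate_genome(sd.SimulationConfig(seed=2))
        assert not t1.equals(t2)

    def test_feature_counts(self, default_sim):
        cfg, genes, truth = default_sim
        counts = truth["cls"].value_counts()
        assert counts["coding"] == cfg.n_coding
        assert counts["linc"] == cfg.n_linc
        assert counts["antisense"] == cfg.n_antisense
        assert counts["antisense_only"] == cfg.n_antisense_only
        assert len(genes) == cfg.n_coding

    def test_median_lengths_near_configured(self, default_sim):
        cfg, _, truth = default_sim
        for cls, med in (
            ("coding", cfg.coding_median_length),
            ("linc", cfg.linc_median_length),
            ("antisense", cfg.antisense_median_length),
        ):
            lengths = truth.loc[truth["cls"] == cls].eval("end - start + 1")
            assert med * 0.75 <= lengths.median() <= med * 1.35, cls

    def test_linc_far_from_genes(self, default_sim):
        cfg, genes, truth = default_sim
        for r in truth[truth["cls"] == "linc"].itertuples():
            gaps = [
                max(g.start - r.end, r.start - g.end) - 1
                for g in genes
                if g.chrom == r.chrom
            ]
            assert min(gaps) >= 500

    def test_same_class_features_do_not_overlap(self, default_sim):
        _, genes, truth = default_sim
        spans = sorted(
            (r.chrom, int(r.start), int(r.end))
            for r in truth[truth["cls"].isin(["coding", "linc"])].itertuples()
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or s2 > e1

    def test_antisense_opposite_strand_inside_host(self, default_sim):
        _, genes, truth = default_sim
        by_id = {g.gene_id: g for g in genes}
        anti = truth[truth["cls"].isin(["antisense", "antisense_only"])]
        for r in anti.itertuples():
            host = by_id[r.host_gene]
            assert r.strand != host.strand
            overlap = min(r.end, host.end) - max(r.start, host.start) + 1
            assert overlap > 0

    def test_antisense_only_host_silenced(self, default_sim):
        _, _, truth = default_sim
        hosts = set(truth.loc[truth["cls"] == "antisense_only", "host_gene"])
        host_rows = truth[truth["feature_id"].isin(hosts)]
        assert (host_rows["level"] == 0.0).all()

    def test_overfull_genome_is_an_error(self):
        cfg = sd.SimulationConfig(
            n_coding=500, n_chromosomes=1, chromosome_length=100_000
        )
        with pytest.raises(ValueError):
            sd.simulate_genome(cfg)


class TestSimulateCoverage:
    def test_deterministic(self, default_sim):
        cfg, genes, truth = default_sim
        g1 = sd.simulate_coverage(genes, truth, cfg)
        g2 = sd.simulate_coverage(genes, truth, cfg)
        np.testing.assert_array_equal(
            g1.get_counts("rna", None, "chr1"), g2.get_counts("rna", None, "chr1")
        )

    def test_interior_bin_mean_tracks_level(self, default_sim):
        # Monte Carlo over fresh draws: interior coding exon bins of a known
        # gene average level * depth within sampling tolerance
        cfg, genes, truth = default_sim
        row = truth[truth["cls"] == "linc"].iloc[0]
        lo = (int(row.start) - 1) // cfg.bin_width + 1  # skip edge bin
        hi = (int(row.end) - 1) // cfg.bin_width - 1
        assert hi >= lo, "need an interior bin"
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(30):
            grid = sd.simulate_coverage(genes, truth, cfg, rng=rng)
            vals.append(grid.get_counts("rna", None, row.chrom)[lo : hi + 1].mean())
        expected = row.level * cfg.library_depth["rna"] + (
            cfg.background_mean * cfg.library_depth["rna"]
        )
        assert np.mean(vals) == pytest.approx(expected, rel=0.12)

    def test_polysome_background_only_at_lincs(self, default_sim):
        cfg, genes, truth = default_sim
        grid = sd.simulate_coverage(genes, truth, cfg)
        linc_bins, coding_bins = [], []
        for r in truth.itertuples():
            lo, hi = (r.start - 1) // cfg.bin_width, (r.end - 1) // cfg.bin_width
            counts = grid.get_counts("polysome", None, r.chrom)[lo : hi + 1]
            if r.cls == "linc":
                linc_bins.append(counts)
            elif r.cls == "coding":
                coding_bins.append(counts)
        linc_mean = np.concatenate(linc_bins).mean()
        coding_mean = np.concatenate(coding_bins).mean()
        assert linc_mean < cfg.polysome_background_mean * cfg.library_depth["polysome"] * 3
        assert coding_mean > 20 * linc_mean

    def test_stranded_signal_on_correct_strand(self, default_sim):
        cfg, genes, truth = default_sim
        grid = sd.simulate_coverage(genes, truth, cfg)
        r = truth[truth["cls"] == "antisense"].iloc[0]
        lo, hi = (int(r.start) - 1) // cfg.bin_width, (int(r.end) - 1) // cfg.bin_width
        own = grid.get_counts("ss_dark", r.strand, r.chrom)[lo : hi + 1].mean()
        assert own > 5 * cfg.stranded_background_mean * cfg.library_depth["ss_dark"]

    def test_light_library_scales_induced_features(self, default_sim):
        cfg, genes, truth = default_sim
        grid = sd.simulate_coverage(genes, truth, cfg)
        ind = truth[(truth["cls"] == "linc") & truth["induced"]]
        if ind.empty:
            pytest.skip("no induced linc in this draw")
        ratios = []
        for r in ind.itertuples():
            lo, hi = (r.start - 1) // cfg.bin_width, (r.end - 1) // cfg.bin_width
            dark = grid.get_counts("ss_dark", r.strand, r.chrom)[lo : hi + 1].sum()
            light = grid.get_counts("ss_light", r.strand, r.chrom)[lo : hi + 1].sum()
            ratios.append(light / max(dark, 1))
        assert np.median(ratios) > 2.0


class TestSimulateJunctions:
    def test_one_junction_per_planted_intron(self, default_sim):
        cfg, genes, truth = default_sim
        jdf = sd.simulate_junctions(genes, truth, cfg)
        n_introns = sum(
            len([p for p in str(r).split(";") if p]) for r in truth["introns"]
        )
        assert (~jdf["decoy"]).sum() == n_introns
        assert jdf["decoy"].sum() == cfg.n_decoy_junctions

    def test_decoys_below_planted_q25(self, default_sim):
        cfg, genes, truth = default_sim
        jdf = sd.simulate_junctions(genes, truth, cfg)
        q25 = np.quantile(jdf.loc[~jdf["decoy"], "reads"], 0.25)
        assert (jdf.loc[jdf["decoy"], "reads"] < q25).all()

    def test_junction_coordinates_match_truth_introns(self, default_sim):
        cfg, genes, truth = default_sim
        jdf = sd.simulate_junctions(genes, truth, cfg)
        planted = {
            (r.chrom, int(p.split("-")[0]), int(p.split("-")[1]))
            for r in truth.itertuples()
            for p in str(r.introns).split(";")
            if p
        }
        for r in jdf[~jdf["decoy"]].itertuples():
            assert (r.chrom, r.donor, r.acceptor) in planted


class TestSimulateTimeCourses:
    def test_induced_features_exceed_twofold(self, default_sim):
        cfg, _, truth = default_sim
        tcs = sd.simulate_time_courses(truth, cfg)
        induced_ids = set(truth.loc[truth["induced"], "feature_id"])
        for ds, courses in tcs.items():
            for tc in courses:
                if tc.feature_id in induced_ids:
                    assert max(fold_change(tc).values()) > 2.0, (ds, tc.feature_id)

    def test_planted_peak_is_argmax(self, default_sim):
        cfg, _, truth = default_sim
        tcs = sd.simulate_time_courses(truth, cfg)
        peaks = dict(zip(truth["feature_id"], truth["peak_time"]))
        induced_ids = set(truth.loc[truth["induced"], "feature_id"])
        for tc in tcs["ds1"]:
            if tc.feature_id in induced_ids:
                vals = {t: v for t, v in tc.values.items() if t > 0}
                assert max(vals, key=vals.get) == peaks[tc.feature_id]

    def test_both_datasets_cover_all_features(self, default_sim):
        cfg, _, truth = default_sim
        tcs = sd.simulate_time_courses(truth, cfg)
        for courses in tcs.values():
            assert len(courses) == len(truth)


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        ivs = [("c", 101, 200), ("c", 501, 700)]
        m = sd.recovery_metrics(ivs, ivs)
        assert m["precision"] == 1.0 and m["recall"] == 1.0
        assert m["bin_precision"] == 1.0 and m["bin_recall"] == 1.0

    def test_empty_called_set(self):
        m = sd.recovery_metrics([], [("c", 1, 100)])
        assert np.isnan(m["precision"]) and m["recall"] == 0.0

    def test_empty_truth_set(self):
        m = sd.recovery_metrics([("c", 1, 100)], [])
        assert m["precision"] == 0.0 and np.isnan(m["recall"])

    def test_reciprocal_threshold_boundary(self):
        truth = [("c", 1, 100)]
        # 50 of 100 truth bases covered, called length 50 -> both ratios
        # exactly 0.5 -> counts as recovered (>= threshold)
        assert sd.recovery_metrics([("c", 51, 100)], truth)["recall"] == 1.0
        # 49 of 100 -> below threshold
        assert sd.recovery_metrics([("c", 52, 100)], truth)["recall"] == 0.0

    def test_one_sided_overlap_insufficient(self):
        # called covers all of truth but is 4x longer: called-side ratio 0.25
        m = sd.recovery_metrics([("c", 1, 400)], [("c", 1, 100)])
        assert m["precision"] == 0.0 and m["recall"] == 0.0

    def test_chromosome_mismatch(self):
        m = sd.recovery_metrics([("c1", 1, 100)], [("c2", 1, 100)])
        assert m["precision"] == 0.0 and m["recall"] == 0.0


class TestWriters:
    def test_truth_table_roundtrip(self, tmp_path, default_sim):
        _, _, truth = default_sim
        path = tmp_path / "truth.tsv"
        sd.write_truth_table(truth, path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == len(truth)
        assert list(back["feature_id"]) == list(truth["feature_id"])

    def test_gff3_header_and_record_counts(self, tmp_path, default_sim):
        _, genes, truth = default_sim
        path = tmp_path / "a.gff3"
        sd.write_gff3(genes, truth, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        n_gene = sum(1 for ln in lines if "\tgene\t" in ln)
        assert n_gene == len(genes)
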