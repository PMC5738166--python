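import numpy as np
import pandas as pd
import pytest

from nct.antisense_caller import (
    AntisenseCall,
    AntisenseOnlyCall,
    antisense_summary,
    call_stranded_units,
    detect_antisense_only,
    filter_by_neighbor_distance,
    gene_strand_averages,
    pair_sense_antisense,
    tss_offset_profile,
)
from nct.genome_io import GeneModel, build_bin_grid
from nct.unit_caller import BinLabeling, LogitModel, TranscriptionUnit

from conftest import fill_counts


def tu(start, end, strand, chrom="c", uid=None):
    return TranscriptionUnit(uid or f"u{start}{strand}", chrom, start, end, strand)


class TestCallStrandedUnits:
    def test_unstranded_grid_rejected(self):
        grid = build_bin_grid({"c": 1000}, 50)
        fill_counts(grid, "rna", None, {"c": np.ones(20, dtype=np.int64)})
        with pytest.raises(ValueError, match="stranded"):
            call_stranded_units(grid, BinLabeling(np.zeros(20, dtype=np.int8)),
                                LogitModel(seed=0), rna_library="rna")

    def test_min_reads_excludes_weak_bins(self):
        # plus strand carries a clear signal block; one signal bin has only
        # 8 reads and must be excluded despite its high score
        n = 200
        rng = np.random.default_rng(1)
        plus = rng.poisson(0.3, n)
        plus[50:60] = 40
        plus[55] = 8
        minus = rng.poisson(0.3, n)
        grid = build_bin_grid({"c": n * 50}, 50)
        fill_counts(grid, "rna", "+", {"c": plus})
        fill_counts(grid, "rna", "-", {"c": minus})
        labels = np.zeros(n, dtype=np.int8)
        labels[50:60] = 1
        lab = BinLabeling(labels)
        units = call_stranded_units(
            grid, lab, LogitModel(train_fraction=1.0, seed=0),
            rna_library="rna", min_reads=10,
        )
        plus_bins = set()
        for u in units["+"]:
            plus_bins.update(range((u.start - 1) // 50, (u.end - 1) // 50 + 1))
        assert 55 not in plus_bins
        assert {50, 54, 56, 59} <= plus_bins
        assert units["-"] == []


GENE = GeneModel("g1", "c", 1001, 3000, "+")


class TestPairSenseAntisense:
    def test_overlapping_pair_detected(self):
        units = {"+": [tu(1001, 3000, "+")], "-": [tu(2501, 2800, "-")]}
        (call,) = pair_sense_antisense(units, [GENE])
        assert call.gene_id == "g1" and call.strand == "-"
        assert (call.start, call.end) == (2501, 2800)

    def test_silent_sense_gives_no_pair(self):
        units = {"+": [], "-": [tu(2501, 2800, "-")]}
        assert pair_sense_antisense(units, [GENE]) == []

    def test_fragments_over_one_gene_merge(self):
        units = {
            "+": [tu(1001, 3000, "+")],
            "-": [tu(1201, 1400, "-"), tu(2501, 2800, "-")],
        }
        (call,) = pair_sense_antisense(units, [GENE])
        assert len(call.fragments) == 2
        assert (call.start, call.end) == (1201, 2800)


class TestNeighborDistanceFilter:
    def make_call(self, start, end, strand="-"):
        return AntisenseCall("g1", [tu(start, end, strand)], "c", start, end, strand)

    def test_nearby_same_strand_neighbor_removes_call(self):
        neighbor = GeneModel("g2", "c", 3101, 4000, "-")  # 200 bp from fragment end 2900
        call = self.make_call(2601, 2900)
        assert filter_by_neighbor_distance([call], [GENE, neighbor]) == []

    def test_distant_neighbor_keeps_call(self):
        neighbor = GeneModel("g2", "c", 5001, 6000, "-")  # 2.1 kb away
        call = self.make_call(2601, 2900)
        assert len(filter_by_neighbor_distance([call], [GENE, neighbor])) == 1

    def test_overlapping_convergent_gene_removes_call(self):
        neighbor = GeneModel("g2", "c", 2801, 3600, "-")
        call = self.make_call(2601, 2900)
        assert filter_by_neighbor_distance([call], [GENE, neighbor]) == []

    def test_opposite_strand_neighbor_is_ignored(self):
        neighbor = GeneModel("g2", "c", 3101, 4000, "+")  # on the sense strand
        call = self.make_call(2601, 2900)
        assert len(filter_by_neighbor_distance([call], [GENE, neighbor])) == 1


class TestDetectAntisenseOnly:
    def avg(self, sense, anti):
        return pd.DataFrame(
            {"sense_avg": [sense], "antisense_avg": [anti], "library_total": [1e6]},
            index=pd.Index(["g1"], name="gene_id"),
        )

    def test_pass_in_both_datasets(self):
        calls = detect_antisense_only(
            {"dark": self.avg(0.4, 3.1), "light": self.avg(0.5, 2.2)}, [GENE]
        )
        assert [c.gene_id for c in calls] == ["g1"]

    def test_pass_in_one_dataset_only_is_rejected(self):
        calls = detect_antisense_only(
            {"dark": self.avg(0.4, 3.1), "light": self.avg(1.5, 3.1)}, [GENE]
        )
        assert calls == []

    def test_overlapping_genes_filtered_out(self):
        overlapper = GeneModel("g2", "c", 2000, 5000, "-")
        df = pd.DataFrame(
            {"sense_avg": [0.4, 0.4], "antisense_avg": [3.0, 3.0],
             "library_total": [1e6, 1e6]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        calls = detect_antisense_only({"dark": df}, [GENE, overlapper])
        assert calls == []

    def test_boundary_values_rejected(self):
        # sense exactly 1 fails "< 1"; antisense exactly 1 fails "> 1"
        assert detect_antisense_only({"d": self.avg(1.0, 3.0)}, [GENE]) == []
        assert detect_antisense_only({"d": self.avg(0.2, 1.0)}, [GENE]) == []


class TestGeneStrandAverages:
    def test_reads_per_bin_and_normalization(self):
        grid = build_bin_grid({"c": 1000}, 50)
        plus = np.zeros(20, dtype=np.int64)
        minus = np.zeros(20, dtype=np.int64)
        plus[2:6] = 10   # gene spans bins 2..5
        minus[2:6] = 2
        fill_counts(grid, "ss", "+", {"c": plus})
        fill_counts(grid, "ss", "-", {"c": minus})
        gene = GeneModel("g", "c", 101, 300, "+")
        df = gene_strand_averages(grid, [gene], "ss")
        assert df.loc["g", "sense_avg"] == pytest.approx(10.0)
        assert df.loc["g", "antisense_avg"] == pytest.approx(2.0)
        # halving the implied depth by doubling the reference doubles values
        df2 = gene_strand_averages(grid, [gene], "ss", reference_total=2 * (40 + 8))
        assert df2.loc["g", "sense_avg"] == pytest.approx(20.0)


class TestSummaryAndOffsets:
    def test_total_is_paired_plus_antisense_only(self):
        paired = [
            AntisenseCall(f"g{i}", [], "c", 100, 350, "-") for i in range(826)
        ]
        only = [AntisenseOnlyCall(f"h{i}") for i in range(230)]
        s = antisense_summary(paired, only)
        assert s["n_total"] == 1056
        assert s["median_antisense_length"] == 251

    def test_empty_sets_do_not_crash(self):
        s = antisense_summary([], [])
        assert s["n_total"] == 0

    def test_offset_zero_at_tts(self):
        gene = GeneModel("g1", "c", 1001, 3000, "+")
        call = AntisenseCall("g1", [], "c", 2701, 3000, "-")
        df = tss_offset_profile([call], [gene])
        assert df.loc[0, "tts_offset"] == 0.0  # antisense 5' start == sense TTS
        assert df.loc[0, "tss_offset"] == 1999.0

    def test_offset_sign_for_minus_strand_gene(self):
        gene = GeneModel("g1", "c", 1001, 3000, "-")  # TSS 3000, TTS 1001
        call = AntisenseCall("g1", [], "c", 1001, 1300, "+")  # antisense 5' = 1001
        df = tss_offset_profile([call], [gene])
        assert df.loc[0, "tts_offset"] == 0.0
        assert df.loc[0, "tss_offset"] == 1999.0

    def test_downstream_is_positive(self):
        gene = GeneModel("g1", "c", 1001, 3000, "+")
        call = AntisenseCall("g1", [], "c", 2901, 3100, "-")  # 5' start 3100
        df = tss_offset_profile([call], [gene])
        assert df.loc[0, "tts_offset"] == 100.0
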