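import numpy as np
import pytest

from nct.splice_classifier import (
    Junction,
    annotated_coverage_cutoff,
    classify_junctions,
    junctions_in_features,
    load_junctions,
    round_half_away,
    splice_fraction_report,
)


def jn(donor, acceptor, reads=20, chrom="c", strand="+"):
    return Junction(chrom, donor, acceptor, strand, reads)


class TestLoadJunctions:
    def write(self, tmp_path, rows):
        path = tmp_path / "j.tsv"
        path.write_text("".join(f"c\t{d}\t{a}\t+\t{r}\n" for d, a, r in rows))
        return path

    def test_intron_length_bounds(self, tmp_path):
        path = self.write(
            tmp_path,
            [(100, 148, 5),        # length 49: rejected
             (100, 168, 5),        # length 69: accepted
             (100, 600_100, 5)],   # length 500,001: rejected
        )
        accepted, rejected = load_junctions(path)
        assert len(accepted) == 1 and rejected == 2
        assert accepted[0].intron_length == 69

    def test_boundary_lengths_kept(self, tmp_path):
        path = self.write(tmp_path, [(100, 149, 5), (100, 500_099, 5)])
        accepted, rejected = load_junctions(path)
        assert [j.intron_length for j in accepted] == [50, 500_000]
        assert rejected == 0

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "j.tsv"
        path.write_text("c\t100\t200\t+\t5\nc\tnot-a-number\n")
        with pytest.raises(ValueError, match=":2"):
            load_junctions(path)

    def test_bed_input(self, tmp_path):
        path = tmp_path / "j.bed"
        path.write_text("c\t100\t200\t15\t0\t+\n")  # 0-based start -> donor 101
        accepted, _ = load_junctions(path)
        assert (accepted[0].donor, accepted[0].acceptor) == (101, 200)
        assert accepted[0].reads == 15


ANNOT = [("c", 201, 300), ("c", 501, 580), ("c", 801, 900)]


class TestCutoff:
    def test_interpolated_quantile(self):
        juncs = [jn(201, 300, 4), jn(501, 580, 8), jn(801, 900, 12), jn(201, 300, 16)]
        # matched read counts {4, 8, 12, 16} -> Q25 = 7.0
        assert annotated_coverage_cutoff(juncs, ANNOT) == pytest.approx(7.0)

    def test_constant_counts(self):
        juncs = [jn(201, 300, 10), jn(501, 580, 10), jn(801, 900, 10)]
        assert annotated_coverage_cutoff(juncs, ANNOT) == 10

    def test_single_match(self):
        assert annotated_coverage_cutoff([jn(201, 300, 5)], ANNOT) == 5

    def test_no_match_is_an_error(self):
        with pytest.raises(ValueError):
            annotated_coverage_cutoff([jn(1001, 1100, 5)], ANNOT)


class TestClassify:
    def classify(self, juncs, cutoff=7.0, tol=10):
        return {(-j.donor, j.acceptor): j.cls
                for j in classify_junctions(juncs, ANNOT, cutoff, tol)}

    def test_exact_match_is_perfect(self):
        (j,) = classify_junctions([jn(201, 300)], ANNOT, 7.0)
        assert j.cls == "perfect"

    def test_shared_donor_is_alternative(self):
        (j,) = classify_junctions([jn(201, 350)], ANNOT, 7.0)
        assert j.cls == "alternative"

    def test_shared_acceptor_is_alternative(self):
        (j,) = classify_junctions([jn(151, 300)], ANNOT, 7.0)
        assert j.cls == "alternative"

    def test_near_miss_is_weak(self):
        (j,) = classify_junctions([jn(204, 297)], ANNOT, 7.0)
        assert j.cls == "weak"

    def test_far_from_annotation_is_novel(self):
        (j,) = classify_junctions([jn(1001, 1100, reads=20)], ANNOT, 7.0)
        assert j.cls == "novel"

    def test_low_support_nonannotated_is_filtered(self):
        (j,) = classify_junctions([jn(1001, 1100, reads=3)], ANNOT, 7.0)
        assert j.cls == "filtered"

    def test_tie_at_cutoff_is_kept(self):
        (j,) = classify_junctions([jn(1001, 1100, reads=7)], ANNOT, 7.0)
        assert j.cls == "novel"

    def test_perfect_match_never_filtered(self):
        (j,) = classify_junctions([jn(201, 300, reads=1)], ANNOT, 7.0)
        assert j.cls == "perfect"

    def test_partition_and_allpairs_oracle(self):
        rng = np.random.default_rng(3)
        juncs = []
        for _ in range(200):
            d = int(rng.integers(100, 2000))
            juncs.append(jn(d, d + int(rng.integers(50, 400)),
                            reads=int(rng.integers(1, 30))))
        # seed in some exact and one-sided matches
        juncs += [jn(201, 300), jn(201, 444), jn(444, 580), jn(205, 296)]
        cutoff = 7.0
        out = classify_junctions(juncs, ANNOT, cutoff)
        assert len(out) == len(juncs)
        assert all(j.cls in ("perfect", "weak", "alternative", "novel", "filtered")
                   for j in out)
        donors = {(c, d) for c, d, a in ANNOT}
        acceptors = {(c, a) for c, d, a in ANNOT}
        for j in out:
            # brute-force comparison against every annotated intron
            exact = any(j.chrom == c and j.donor == d and j.acceptor == a
                        for c, d, a in ANNOT)
            shares = ((j.chrom, j.donor) in donors) or ((j.chrom, j.acceptor) in acceptors)
            near = any(j.chrom == c and abs(j.donor - d) <= 10 and abs(j.acceptor - a) <= 10
                       for c, d, a in ANNOT)
            if exact:
                expected = "perfect"
            elif j.reads < cutoff:
                expected = "filtered"
            elif shares:
                expected = "alternative"
            elif near:
                expected = "weak"
            else:
                expected = "novel"
            assert j.cls == expected, (j.donor, j.acceptor, j.reads)

    def test_raising_cutoff_never_grows_nonfiltered_classes(self):
        rng = np.random.default_rng(4)
        juncs = [jn(int(d), int(d) + 100, reads=int(r))
                 for d, r in zip(rng.integers(100, 5000, 50), rng.integers(1, 30, 50))]
        counts = []
        for cutoff in (2, 8, 15):
            out = classify_junctions(juncs, ANNOT, cutoff)
            counts.append(sum(1 for j in out if j.cls in ("novel", "alternative", "weak")))
        assert counts == sorted(counts, reverse=True)


class TestJunctionsInFeatures:
    FEATURES = {"linc": [("c", 1000, 2000)]}

    def test_read_support_threshold(self):
        counts = junctions_in_features(
            [jn(1200, 1300, reads=9), jn(1400, 1500, reads=12)], self.FEATURES
        )
        assert counts["linc"] == 1

    def test_straddling_junction_not_counted(self):
        counts = junctions_in_features([jn(1900, 2100, reads=20)], self.FEATURES)
        assert counts["linc"] == 0

    def test_fully_contained_counted(self):
        counts = junctions_in_features([jn(1000, 2000, reads=20)], self.FEATURES)
        assert counts["linc"] == 1


class TestFractionReport:
    def test_published_percentages(self):
        report = splice_fraction_report(
            {"antisense": 26, "linc": 23}, {"antisense": 1056, "linc": 1478}
        )
        assert report.loc["antisense", "pct_spliced"] == 2.5
        assert report.loc["linc", "pct_spliced"] == 1.6

    def test_zero_spliced(self):
        report = splice_fraction_report({}, {"x": 10})
        assert report.loc["x", "pct_spliced"] == 0.0
        assert report.loc["x", "unspliced"] == 10

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(2.45, 1) == 2.5
        assert round_half_away(58.011) == 58.0
        assert round_half_away(-2.45, 1) == -2.5
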