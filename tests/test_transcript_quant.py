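import numpy as np
import pytest

from strainscope import transcript_quant as tq
from strainscope.io_formats import AlignmentRecord
from tests.conftest import make_feature


def _aln(contig, identity, q_start, q_end, s_start=5000, length=None, score=100.0):
    length = length if length is not None else q_end - q_start + 1
    return AlignmentRecord(
        query_id=contig,
        subject_id="g",
        identity=identity,
        aln_length=length,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_start + (q_end - q_start),
        orientation="forward",
        score=score,
    )


class TestClassification:
    def test_full_length_perfect_alignment_assigned(self):
        kept = tq.classify_contigs([_aln("c", 1.0, 1, 1000)], {"c": 1000})
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "identity,coverage_span,expected",
        [
            (0.969, 1000, False),
            (0.970, 1000, True),
            (1.0, 989, False),
            (1.0, 990, True),
        ],
    )
    def test_thresholds_are_sharp(self, identity, coverage_span, expected):
        kept = tq.classify_contigs([_aln("c", identity, 1, coverage_span)], {"c": 1000})
        assert bool(kept) is expected

    def test_best_alignment_is_highest_identity_then_longest_then_leftmost(self):
        alns = [
            _aln("c", 0.98, 1, 500, s_start=100),
            _aln("c", 0.99, 1, 400, s_start=9000),  # best identity, too short
            _aln("c", 0.98, 1, 990, s_start=100),
        ]
        kept = tq.classify_contigs(alns, {"c": 1000})
        assert kept == []  # best (0.99) covers only 40%
        alns = [
            _aln("c", 0.99, 1, 990, s_start=7000),
            _aln("c", 0.99, 1, 990, s_start=100),
        ]
        kept = tq.classify_contigs(alns, {"c": 1000})
        assert kept[0].s_start == 100  # leftmost among equals

    def test_missing_contig_length_is_error(self):
        with pytest.raises(KeyError):
            tq.classify_contigs([_aln("c", 1.0, 1, 100)], {})

    def test_counts_attached(self):
        kept = tq.classify_contigs(
            [_aln("c", 1.0, 1, 1000)], {"c": 1000}, counts={"c": 12.5}
        )
        assert kept[0].read_count == 12.5


class TestOverlap:
    FEATS = [
        make_feature("A", 100, 300),
        make_feature("B", 400, 900),
        make_feature("T", 950, 1050, ftype="tRNA"),
        make_feature("C", 1100, 1400),
    ]

    def test_interval_spanning_two_cds(self):
        found = tq.overlapping_cds((150, 450), self.FEATS)
        assert [f.locus_tag for f in found] == ["A", "B"]

    def test_intergenic_interval_empty(self):
        assert tq.overlapping_cds((310, 390), self.FEATS) == []

    def test_non_cds_excluded(self):
        found = tq.overlapping_cds((940, 1060), self.FEATS)
        assert [f.locus_tag for f in found] == []

    def test_single_bp_overlap_counts(self):
        assert [f.locus_tag for f in tq.overlapping_cds((300, 310), self.FEATS)] == ["A"]

    def test_random_intervals_match_brute_force(self, rng):
        feats = []
        cursor = 1
        for i in range(80):
            start = cursor + int(rng.integers(10, 200))
            end = start + int(rng.integers(90, 1200))
            feats.append(make_feature(f"g{i}", start, end))
            cursor = end
        for _ in range(200):
            a = int(rng.integers(1, cursor))
            b = a + int(rng.integers(1, 3000))
            got = {f.locus_tag for f in tq.overlapping_cds((a, b), feats)}
            brute = {
                f.locus_tag for f in feats if f.start <= b and f.end >= a
            }
            assert got == brute


class TestApportionment:
    def test_single_cds_takes_all(self):
        out = tq.apportion_counts(10.0, [make_feature("A", 1, 300)])
        assert out == {"A": 10.0}

    def test_length_weighted_split(self):
        feats = [make_feature("A", 1, 300), make_feature("B", 400, 999)]
        out = tq.apportion_counts(9.0, feats)
        assert out["A"] == pytest.approx(3.0)
        assert out["B"] == pytest.approx(6.0)

    def test_zero_count_gives_zeros(self):
        feats = [make_feature("A", 1, 300), make_feature("B", 400, 999)]
        assert all(v == 0.0 for v in tq.apportion_counts(0.0, feats).values())

    def test_empty_feature_list_is_error(self):
        with pytest.raises(ValueError):
            tq.apportion_counts(1.0, [])

    def test_weights_use_full_cds_length_not_overlap(self):
        # contig [250, 450] clips A to 51 bp and B to 51 bp, but weights
        # remain the full 300/600 gene lengths
        feats = [make_feature("A", 1, 300), make_feature("B", 400, 999)]
        contig = tq.AssignedContig("c", 201, 250, 450, 1.0, read_count=9.0)
        rows, sink = tq.aggregate_counts([contig], feats)
        by = {r.locus_tag: r.count for r in rows}
        assert by["A"] == pytest.approx(3.0) and by["B"] == pytest.approx(6.0)


def _random_fixture(rng, n_genes=12, n_contigs=10):
    feats = []
    cursor = 1
    for i in range(n_genes):
        start = cursor + int(rng.integers(20, 120))
        end = start + int(rng.integers(150, 1500))
        feats.append(make_feature(f"g{i}", start, end))
        cursor = end
    genome_end = cursor + 200
    contigs = []
    for j in range(n_contigs):
        a = int(rng.integers(1, genome_end - 100))
        b = a + int(rng.integers(100, 2500))
        contigs.append(
            tq.AssignedContig(f"c{j}", b - a + 1, a, min(b, genome_end), 1.0,
                              read_count=float(rng.lognormal(1, 1.5)))
        )
    return feats, contigs


class TestAggregation:
    def test_two_contigs_on_one_gene_add(self):
        feats = [make_feature("A", 100, 700)]
        contigs = [
            tq.AssignedContig("c1", 300, 150, 450, 1.0, read_count=4.0),
            tq.AssignedContig("c2", 300, 200, 500, 1.0, read_count=6.0),
        ]
        rows, sink = tq.aggregate_counts(contigs, feats)
        assert rows[0].count == pytest.approx(10.0)
        assert sink == 0.0

    def test_unoverlapped_contig_routes_to_sink(self):
        feats = [make_feature("A", 100, 700)]
        contigs = [tq.AssignedContig("c", 50, 800, 849, 1.0, read_count=3.5)]
        rows, sink = tq.aggregate_counts(contigs, feats)
        assert rows[0].count == 0.0 and sink == 3.5

    def test_matches_brute_force_recomputation(self, rng):
        for _ in range(25):
            feats, contigs = _random_fixture(rng)
            rows, sink = tq.aggregate_counts(contigs, feats)
            got = {r.locus_tag: r.count for r in rows}
            expected = {f.locus_tag: 0.0 for f in feats}
            exp_sink = 0.0
            for c in contigs:
                over = [f for f in feats if f.start <= c.s_end and f.end >= c.s_start]
                if not over:
                    exp_sink += c.read_count
                    continue
                total = sum(f.length_nt for f in over)
                for f in over:
                    expected[f.locus_tag] += c.read_count * f.length_nt / total
            for tag in expected:
                assert got[tag] == pytest.approx(expected[tag], rel=1e-9, abs=1e-12)
            assert sink == pytest.approx(exp_sink, rel=1e-9, abs=1e-12)

    def test_count_conservation(self, rng):
        for _ in range(50):
            feats, contigs = _random_fixture(rng)
            rows, sink = tq.aggregate_counts(contigs, feats)
            total_in = sum(c.read_count for c in contigs)
            total_out = sum(r.count for r in rows) + sink
            assert total_out == pytest.approx(total_in, rel=1e-9)


class TestTPM:
    def test_single_expressed_gene_gets_the_whole_million(self):
        rows = [tq.GeneExpressionRow("A", 900, 5.0), tq.GeneExpressionRow("B", 300, 0.0)]
        out = tq.compute_tpm(rows)
        assert out[0].tpm == pytest.approx(1e6)
        assert out[1].tpm == 0.0

    def test_equal_densities_split_evenly(self):
        rows = [tq.GeneExpressionRow("A", 300, 3.0), tq.GeneExpressionRow("B", 600, 6.0)]
        out = tq.compute_tpm(rows)
        assert out[0].tpm == pytest.approx(5e5)
        assert out[1].tpm == pytest.approx(5e5)

    def test_sum_is_one_million_and_scale_invariant(self, rng):
        rows = [
            tq.GeneExpressionRow(f"g{i}", int(rng.integers(150, 3000)),
                                 float(rng.lognormal(1, 1.5)))
            for i in range(60)
        ]
        out = tq.compute_tpm(rows)
        assert sum(r.tpm for r in out) == pytest.approx(1e6, rel=1e-9)
        scaled = tq.compute_tpm([tq.replace_row(r, count=3.0 * r.count) for r in rows])
        for a, b in zip(out, scaled):
            assert a.tpm == pytest.approx(b.tpm, rel=1e-12)

    def test_all_zero_counts_warn_and_zero(self, caplog):
        rows = [tq.GeneExpressionRow("A", 300, 0.0)]
        with caplog.at_level("WARNING"):
            out = tq.compute_tpm(rows)
        assert out[0].tpm == 0.0


class TestRanking:
    def _rows(self, tpms):
        return [
            tq.GeneExpressionRow(f"g{i}", 900, 1.0, tpm=t) for i, t in enumerate(tpms)
        ]

    def test_descending_order(self):
        out = tq.rank_genes(self._rows([5.0, 2.0, 9.0]))
        assert [r.tpm for r in out] == [9.0, 5.0, 2.0]

    def test_ties_break_by_locus_tag(self):
        out = tq.rank_genes(self._rows([5.0, 5.0, 5.0]))
        assert [r.locus_tag for r in out] == ["g0", "g1", "g2"]

    def test_matches_independent_sort(self, rng):
        rows = self._rows(list(rng.lognormal(1, 1, 50)))
        out = tq.rank_genes(rows)
        expected = sorted(rows, key=lambda r: (-r.tpm, r.locus_tag))
        assert out == expected

    def test_function_filter(self):
        feats = {
            "g0": make_feature("g0", 1, 900, labels={"susC"}),
            "g1": make_feature("g1", 1000, 1900),
        }
        out = tq.rank_genes(self._rows([1.0, 2.0]), {"susC"}, feats)
        assert [r.locus_tag for r in out] == ["g0"]
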