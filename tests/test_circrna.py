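"""Consensus calling, flank resolution, inverted pairs, hotspots."""

import itertools

import numpy as np
import pytest

from repeatrna.circrna import (
    BackspliceJunction,
    CircRNA,
    InvertedRepeatPair,
    consensus_circrnas,
    family_pair_enrichment,
    find_inverted_repeat_pairs,
    flanking_length_test,
    hotspot_genes,
    pooled_flank_lengths,
    random_backsplice_null,
    read_bsj_tsv,
    validate_and_flank,
    write_bsj_tsv,
)
from repeatrna.intervals import GeneModel, GenomicInterval
from repeatrna.repeats import CoverageSummary, RepeatCopy


def bsj(caller, acceptor=100, donor=400, chrom="chr1", strand="+", reads=None):
    return BackspliceJunction(chrom, acceptor, donor, strand, caller, reads)


class TestConsensus:
    def test_three_caller_agreement(self):
        sets = [[bsj("a")], [bsj("b")], [bsj("c")]]
        (circ,) = consensus_circrnas(sets, min_callers=3)
        assert circ.callers == frozenset({"a", "b", "c"})

    def test_brute_force_intersection(self):
        j1, j2, j3 = (
            (100, 400),
            (150, 600),
            (200, 800),
        )
        callsets = {
            "A": [j1, j2, j3],
            "B": [j1, j3],
            "C": [j1, j2, j3],
        }
        sets = [
            [bsj(c, a, d) for a, d in js] for c, js in callsets.items()
        ]
        got = {(c.acceptor, c.donor) for c in consensus_circrnas(sets, 3)}
        oracle = set.intersection(*[set(js) for js in callsets.values()])
        assert got == oracle == {j1, j3}

    def test_single_callset_cannot_reach_three(self):
        assert consensus_circrnas([[bsj("a")]], min_callers=3) == []

    def test_caller_order_invariance(self):
        sets = [[bsj("a"), bsj("a", 10, 20)], [bsj("b")], [bsj("c", 10, 20)]]
        for perm in itertools.permutations(sets):
            got = [c.key for c in consensus_circrnas(list(perm), 2)]
            assert got == [("chr1", 10, 20, "+"), ("chr1", 100, 400, "+")]

    def test_reads_sum_within_not_across_callers(self):
        sets = [
            [bsj("a", reads=3), bsj("a", reads=4)],
            [bsj("b", reads=10)],
        ]
        (circ,) = consensus_circrnas(sets, 2)
        assert circ.read_counts == {"a": 7, "b": 10}

    def test_tsv_round_trip(self):
        js = [bsj("a", 99, 400, reads=5), bsj("a", 10, 20)]
        assert read_bsj_tsv(write_bsj_tsv(js)) == js


class TestValidateAndFlank:
    def test_circle_over_internal_exons(self, four_exon_gene):
        circ = CircRNA("chr1", 300, 600, "+", frozenset({"x"}))
        out = validate_and_flank(circ, [four_exon_gene])
        assert out.splice_site_validated
        assert out.host_gene == "g4"
        assert (out.upstream_intron.start, out.upstream_intron.end) == (200, 300)
        assert (out.downstream_intron.start, out.downstream_intron.end) == (600, 700)

    def test_minus_strand_flanks_mirrored(self):
        exons = tuple(
            GenomicInterval("chr1", s, s + 100, "-") for s in (100, 300, 500, 700)
        )
        gene = GeneModel.from_exons("gm", {"t": exons})
        circ = CircRNA("chr1", 300, 600, "-", frozenset({"x"}))
        out = validate_and_flank(circ, [gene])
        # 5' of the acceptor in transcript orientation = genomic right
        assert (out.upstream_intron.start, out.upstream_intron.end) == (600, 700)
        assert (out.downstream_intron.start, out.downstream_intron.end) == (200, 300)

    def test_terminal_exon_leaves_flank_missing(self, four_exon_gene):
        circ = CircRNA("chr1", 100, 600, "+", frozenset({"x"}))
        out = validate_and_flank(circ, [four_exon_gene])
        assert out.splice_site_validated
        assert out.flank_missing and out.upstream_intron is None

    def test_non_boundary_junction_not_validated(self, four_exon_gene):
        circ = CircRNA("chr1", 305, 600, "+", frozenset({"x"}))
        out = validate_and_flank(circ, [four_exon_gene])
        assert not out.splice_site_validated
        assert out.host_gene is None


class TestRandomNull:
    def test_deterministic_given_seed(self, four_exon_gene):
        a = random_backsplice_null([four_exon_gene], 50, seed=5)
        b = random_backsplice_null([four_exon_gene], 50, seed=5)
        assert [c.key for c in a] == [c.key for c in b]

    def test_all_draws_validated_with_both_flanks(self, four_exon_gene):
        exons = tuple(
            GenomicInterval("chr2", s, s + 50, "+") for s in range(0, 1000, 200)
        )
        genes = [four_exon_gene, GeneModel.from_exons("g5", {"t": exons})]
        draws = random_backsplice_null(genes, 300, seed=1)
        assert all(c.splice_site_validated and c.has_both_flanks for c in draws)

    def test_single_internal_pair_gene_yields_one_junction(self):
        exons = tuple(
            GenomicInterval("chr1", s, s + 100, "+") for s in (0, 200, 400)
        )
        gene = GeneModel.from_exons("g3", {"t": exons})
        draws = random_backsplice_null([gene], 20, seed=0)
        assert {c.key for c in draws} == {("chr1", 200, 300, "+")}

    def test_no_eligible_genes_rejected(self):
        g = GeneModel.from_exons(
            "g1", {"t": (GenomicInterval("chr1", 0, 100, "+"),)}
        )
        with pytest.raises(ValueError):
            random_backsplice_null([g], 5, seed=0)


class TestFlankingLengthTest:
    @pytest.fixture
    def varied_gene(self):
        # intron lengths 100, 350, 1200: nonconstant pooled samples
        coords = [(0, 100), (200, 300), (650, 750), (1950, 2050)]
        exons = tuple(GenomicInterval("chr1", s, e, "+") for s, e in coords)
        return GeneModel.from_exons("gv", {"t": exons})

    def test_identical_groups_not_significant(self, varied_gene):
        circs = random_backsplice_null([varied_gene], 40, seed=2)
        res, means = flanking_length_test(circs, list(circs))
        assert res.p_value == pytest.approx(1.0)
        assert means["observed_mean"] == means["null_mean"]

    def test_means_are_arithmetic_means_of_pooled_lengths(self, varied_gene):
        circs = random_backsplice_null([varied_gene], 10, seed=3)
        _, means = flanking_length_test(circs, circs)
        assert means["observed_mean"] == pytest.approx(
            np.mean(pooled_flank_lengths(circs))
        )


def make_flanked_circ(up_intron, down_intron, acceptor, donor):
    return CircRNA(
        "chr1", acceptor, donor, "+", frozenset({"x"}),
        upstream_intron=GenomicInterval("chr1", *up_intron),
        downstream_intron=GenomicInterval("chr1", *down_intron),
        splice_site_validated=True,
    )


class TestInvertedPairs:
    def test_nearest_opposite_strand_selection(self):
        # junction at 300/400; upstream candidates end at 260 (+) and 295 (-),
        # downstream candidate starts at 405 (+)
        circ = make_flanked_circ((200, 300), (400, 520), 300, 400)
        repeats = [
            RepeatCopy(GenomicInterval("chr1", 210, 260, "+"), "DNA/hAT"),
            RepeatCopy(GenomicInterval("chr1", 250, 295, "-"), "DNA/hAT"),
            RepeatCopy(GenomicInterval("chr1", 405, 500, "+"), "LTR/Gypsy"),
        ]
        pair = find_inverted_repeat_pairs(circ, repeats)
        assert pair is not None
        assert (pair.up.start, pair.up.end, pair.up.strand) == (250, 295, "-")
        assert (pair.down.start, pair.down.strand) == (405, "+")
        assert (pair.up_distance, pair.down_distance) == (5, 5)

    def test_brute_force_equivalence_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            circ = make_flanked_circ((1000, 3000), (5000, 8000), 3000, 5000)
            repeats = []
            for _ in range(int(rng.integers(0, 15))):
                s = int(rng.integers(500, 8500))
                ln = int(rng.integers(30, 900))
                repeats.append(
                    RepeatCopy(
                        GenomicInterval("chr1", s, s + ln,
                                        "+" if rng.random() < 0.5 else "-"),
                        "DNA/hAT",
                    )
                )
            got = find_inverted_repeat_pairs(circ, repeats, 0.5)
            # exhaustive oracle over candidate pairs
            def cands(intron, at_end):
                out = []
                for r in repeats:
                    ov = r.location.overlap_bp(intron)
                    if ov / r.location.length >= 0.5:
                        d = max(0, intron.end - r.end) if at_end else max(
                            0, r.start - intron.start
                        )
                        out.append((d, -ov, r.start, r))
                return out
            up = cands(circ.upstream_intron, True)
            down = cands(circ.downstream_intron, False)
            if not up or not down:
                assert got is None
                continue
            bu, bd = min(up)[-1], min(down)[-1]
            if bu.strand == bd.strand:
                assert got is None
            else:
                assert got is not None
                assert (got.up, got.down) == (bu, bd)
                # emitted pair always satisfies the two rules
                assert got.up.strand != got.down.strand
                assert (
                    got.up.location.overlap_bp(circ.upstream_intron)
                    / got.up.location.length
                    >= 0.5
                )

    def test_missing_flank_gives_none(self):
        circ = CircRNA("chr1", 300, 400, "+", frozenset({"x"}))
        assert find_inverted_repeat_pairs(circ, []) is None

    def test_same_strand_nearest_gives_none(self):
        circ = make_flanked_circ((200, 300), (400, 500), 300, 400)
        repeats = [
            RepeatCopy(GenomicInterval("chr1", 250, 295, "+"), "DNA/hAT"),
            RepeatCopy(GenomicInterval("chr1", 405, 460, "+"), "DNA/hAT"),
        ]
        assert find_inverted_repeat_pairs(circ, repeats) is None

    def test_half_overlap_rule_is_inclusive(self):
        circ = make_flanked_circ((200, 300), (400, 500), 300, 400)
        repeats = [
            # exactly 50% of the repeat inside the upstream intron
            RepeatCopy(GenomicInterval("chr1", 250, 350, "-"), "DNA/hAT"),
            RepeatCopy(GenomicInterval("chr1", 410, 460, "+"), "DNA/hAT"),
        ]
        pair = find_inverted_repeat_pairs(circ, repeats, 0.5)
        assert pair is not None and pair.up_distance == 0


class TestFamilyEnrichment:
    def _circs_with_pairs(self, n, k, family="DNA/hAT"):
        up = RepeatCopy(GenomicInterval("chr1", 10, 60, "+"), family)
        down = RepeatCopy(GenomicInterval("chr1", 100, 160, "-"), family)
        pair = InvertedRepeatPair(up, down, 0, 0)
        out = []
        for i in range(n):
            out.append(
                CircRNA(
                    "chr1", 1000 + 10 * i, 2000 + 10 * i, "+", frozenset({"x"}),
                    inverted_pair=pair if i < k else None,
                )
            )
        return out

    def test_observed_and_expected_counts(self):
        circs = self._circs_with_pairs(200, 30)
        cov = CoverageSummary({"DNA/hAT": 114}, 1000, "raw_sum")
        res = family_pair_enrichment(circs, cov, ["hAT"])
        assert res["hAT"].k == 30
        assert res["hAT"].n == 200
        assert res["hAT"].expected == pytest.approx(200 * 0.114)

    def test_circrna_counts_once_even_if_both_flanks_match(self):
        circs = self._circs_with_pairs(10, 10)
        cov = CoverageSummary({"DNA/hAT": 114}, 1000, "raw_sum")
        assert family_pair_enrichment(circs, cov, ["hAT"])["hAT"].k == 10


class TestHotspots:
    def _circ(self, gene, acceptor):
        return CircRNA(
            "chr1", acceptor, acceptor + 500, "+", frozenset({"x"}),
            host_gene=gene,
        )

    def test_threshold_boundary(self):
        circs = [self._circ("g14", 10 * i) for i in range(14)]
        circs += [self._circ("g15", 10_000 + 10 * i) for i in range(15)]
        assert hotspot_genes(circs, threshold=15) == [("g15", 15)]

    def test_planted_counts_sorted(self):
        circs = (
            [self._circ("g1", 10 * i) for i in range(20)]
            + [self._circ("g2", 5000 + 10 * i) for i in range(15)]
            + [self._circ("g3", 9000 + 10 * i) for i in range(3)]
        )
        assert hotspot_genes(circs) == [("g1", 20), ("g2", 15)]

    def test_duplicate_junctions_count_once(self):
        circs = [self._circ("g", 100)] * 20
        assert hotspot_genes(circs, threshold=2) == []
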