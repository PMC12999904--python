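import pytest

from asterfam.models import AnchorPair, GeneModel, SyntenyBlock
from asterfam.synteny import (
    chain_anchors,
    classify_duplications,
    synteny_conservation_table,
)


def anchor(ra, rb, ca="spA_chr1", cb="spB_chr1", ga=None, gb=None):
    return AnchorPair(ga or f"a{ra}", gb or f"b{rb}", ca, cb, ra, rb)


class TestChainAnchors:
    def test_perfect_diagonal_of_twelve(self):
        anchors = [anchor(i, i) for i in range(1, 13)]
        (blk,) = chain_anchors(anchors)
        assert blk.score == 12
        assert blk.orientation == "same"

    def test_nine_anchors_is_below_the_minimum(self):
        anchors = [anchor(i, i) for i in range(1, 10)]
        assert chain_anchors(anchors) == []

    def test_antidiagonal_of_ten_is_inverted(self):
        anchors = [anchor(i, 11 - i) for i in range(1, 11)]
        (blk,) = chain_anchors(anchors)
        assert blk.score == 10
        assert blk.orientation == "inverted"

    def test_rank_gap_bound_splits_chains(self):
        # two dense runs separated by a 40-rank jump cannot join
        anchors = [anchor(i, i) for i in range(1, 11)]
        anchors += [anchor(i + 50, i + 50) for i in range(1, 11)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 2
        assert all(b.score == 10 for b in blocks)

    def test_emitted_blocks_satisfy_monotonicity_and_gap(self):
        anchors = [anchor(i, i + (i % 3)) for i in range(1, 40)]
        for blk in chain_anchors(anchors):
            ra = [a.rank_a for a in blk.anchors]
            rb = [a.rank_b for a in blk.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            assert rb == sorted(rb, reverse=(blk.orientation == "inverted"))
            for x, y in zip(ra, ra[1:]):
                assert 0 < y - x <= 25

    def test_anchor_used_in_at_most_one_block(self):
        anchors = [anchor(i, i) for i in range(1, 25)]
        blocks = chain_anchors(anchors)
        seen = set()
        for blk in blocks:
            for a in blk.anchors:
                assert (a.gene_a, a.gene_b) not in seen
                seen.add((a.gene_a, a.gene_b))


def gene(gid, chrom, rank, sp="spA"):
    g = GeneModel(
        gene_id=gid, species=sp, chromosome=chrom, start=rank * 1000, end=rank * 1000 + 10,
        strand="+",
    )
    g.rank = rank
    return g


def block(pairs, bid="blk1", sp_a="spA", sp_b="spB"):
    anchors = tuple(
        AnchorPair(a, b, f"{sp_a}_chr1", f"{sp_b}_chr1", i + 1, i + 1)
        for i, (a, b) in enumerate(pairs)
    )
    return SyntenyBlock(bid, sp_a, sp_b, f"{sp_a}_chr1", f"{sp_b}_chr1", anchors, "same")


class TestClassifyDuplications:
    def test_adjacent_homologs_are_tandem(self):
        genes = [gene("g7", "c1", 7), gene("g8", "c1", 8)]
        calls = classify_duplications(genes, [("g7", "g8")], [], [])
        assert {c.mode for c in calls} == {"TD"}

    def test_wgd_outranks_tandem(self):
        genes = [gene("g7", "c1", 7), gene("g8", "c1", 8)]
        blk = block([("g7", "g8")], sp_a="spA", sp_b="spA")
        calls = classify_duplications(genes, [("g7", "g8")], [blk], [])
        assert {c.mode for c in calls} == {"WGD"}

    def test_no_homolog_is_singleton(self):
        calls = classify_duplications([gene("g1", "c1", 1)], [], [], [])
        assert calls[0].mode == "singleton"

    def test_proximal_window(self):
        genes = [gene("g1", "c1", 1), gene("g2", "c1", 5), gene("g3", "c1", 30)]
        calls = {
            c.gene_id: c.mode
            for c in classify_duplications(
                genes, [("g1", "g2"), ("g1", "g3")], [], []
            )
        }
        assert calls["g2"] == "PD"
        assert calls["g3"] == "DSD"  # beyond the proximal window

    def test_transposed_copy_lacks_outgroup_synteny(self):
        genes = [gene("anc", "c1", 1), gene("moved", "c2", 1)]
        outg = block([("anc", "outg1")], sp_a="spA", sp_b="outg")
        calls = {
            c.gene_id: c.mode
            for c in classify_duplications(genes, [("anc", "moved")], [], [outg])
        }
        assert calls["moved"] == "TRD"
        assert calls["anc"] == "DSD"

    def test_modes_partition_the_roster(self):
        genes = [gene(f"g{i}", "c1", i) for i in range(1, 6)]
        calls = classify_duplications(genes, [("g1", "g2")], [], [])
        assert sorted(c.gene_id for c in calls) == sorted(g.gene_id for g in genes)

    def test_unknown_gene_in_pair_rejected(self):
        with pytest.raises(KeyError):
            classify_duplications([gene("g1", "c1", 1)], [("g1", "ghost")], [], [])


class TestSyntenyConservationTable:
    def test_all_conserved(self):
        blk = block([("a1", "b1"), ("a2", "b2")])
        cats = {g: "conserved" for g in ("a1", "a2", "b1", "b2")}
        rows = synteny_conservation_table([blk], cats)
        assert rows[0]["pct_conserved"] == 100.00

    def test_half_conserved_half_rare(self):
        blk = block([("a1", "b1"), ("a2", "b2")])
        cats = {"a1": "conserved", "b1": "conserved", "a2": "rare", "b2": "rare"}
        rows = synteny_conservation_table([blk], cats)
        assert (rows[0]["pct_conserved"], rows[0]["pct_variable"], rows[0]["pct_rare"]) == (
            50.00, 0.00, 50.00,
        )

    def test_empty_blocks_empty_table(self):
        assert synteny_conservation_table([], {}) == []


class TestPlantedRecovery:
    def test_planted_blocks_recovered_exactly(self, small_pipeline):
        _cfg, results, truth = small_pipeline
        planted_cross = [
            frozenset(tuple(a) for a in blk["anchors"])
            for blk in truth.planted_blocks
            if blk["kind"] == "cross"
        ]
        found = [
            frozenset((a.gene_a, a.gene_b) for a in blk.anchors)
            for blk in results["cross_blocks"]
        ]
        assert sorted(map(sorted, planted_cross)) == sorted(map(sorted, found))

    def test_duplication_modes_recovered_exactly(self, small_pipeline):
        _cfg, results, truth = small_pipeline
        got = {c.gene_id: c.mode for c in results["duplication_calls"]}
        assert got == truth.dup_mode
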