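"""Anchor-bounded cluster extraction and gene-order comparison."""

from itertools import combinations

import pytest

from scari import (
    AnchorSpec,
    ClusterError,
    ClusterRegion,
    GeneModel,
    compare_gene_order,
    extract_cluster,
    read_gff3,
)
from scari.synteny import SPLIT_CLUSTER


def gene(gid, seq_id="chr1", start=0, symbol="", strand="+", species="sp"):
    return GeneModel(gid, symbol, (), species, seq_id, start, start + 500, strand, True)


def toy_genes(drop=(), extra=()):
    order = [
        ("RBP5", 1000), ("CLSTN3", 3000), ("PEX5", 5000),
        ("G1", 7000), ("G2", 9000), ("G3", 11000),
        ("CLEC4E", 13000), ("CLEC4D", 15000), ("CLEC6A", 17000),
    ]
    genes = [
        gene(n, start=s, symbol=n if not n.startswith("G") else "")
        for n, s in order
        if n not in drop
    ]
    return genes + list(extra)


class TestExtractCluster:
    def test_candidates_between_anchors(self, toy_gff3):
        genes = read_gff3(toy_gff3, ["chr1"], species="sp")
        region = extract_cluster(genes, AnchorSpec(), {"G1", "G2", "G3"})
        assert region.member_ids() == ["G1", "G2", "G3"]
        assert region.unplaced_members == ()
        assert [g.symbol for g in region.anchors_found["left"]] == ["RBP5", "CLSTN3", "PEX5"]

    def test_missing_one_right_anchor_still_extracts(self):
        # the pig annotation lacks CLEC6A; remaining anchors suffice
        region = extract_cluster(toy_genes(drop=("CLEC6A",)), AnchorSpec(), {"G1", "G2", "G3"})
        assert region.member_ids() == ["G1", "G2", "G3"]
        assert len(region.anchors_found["right"]) == 2

    def test_candidate_on_other_contig_is_unplaced_member(self):
        extra = gene("G4", seq_id="scaf_9", start=100)
        region = extract_cluster(toy_genes(extra=(extra,)), AnchorSpec(), {"G1", "G2", "G3", "G4"})
        assert region.member_ids() == ["G1", "G2", "G3"]
        assert [g.gene_id for g in region.unplaced_members] == ["G4"]

    def test_no_anchors_anywhere_errors(self):
        with pytest.raises(ClusterError, match="not localizable"):
            extract_cluster([gene("G1", start=100)], AnchorSpec(), {"G1"})

    def test_input_order_irrelevant(self, rng):
        genes = toy_genes()
        region = extract_cluster(genes, AnchorSpec(), {"G1", "G2", "G3"})
        shuffled = list(genes)
        rng.shuffle(shuffled)
        region2 = extract_cluster(shuffled, AnchorSpec(), {"G1", "G2", "G3"})
        assert region.member_ids() == region2.member_ids()

    def test_split_cluster_member_flagged_not_dropped(self):
        # a candidate beyond the right anchors (goat-like split cluster)
        extra = gene("G9", start=19000)
        region = extract_cluster(toy_genes(extra=(extra,)), AnchorSpec(), {"G1", "G2", "G3", "G9"})
        assert "G9" in region.member_ids()
        assert SPLIT_CLUSTER in region.flags["G9"]
        assert "G1" not in region.flags

    def test_innermost_anchor_copy_used(self):
        # a duplicated RBP5 copy inside the cluster bounds the members
        extra = gene("RBP5b", start=8000, symbol="RBP5")
        region = extract_cluster(
            toy_genes(extra=(extra,)), AnchorSpec(), {"G1", "G2", "G3"}
        )
        assert SPLIT_CLUSTER in region.flags.get("G1", frozenset())
        assert "G3" not in region.flags


def region_from_order(order, species="a", strands=None):
    strands = strands or {}
    members = tuple(
        gene(g, start=1000 * (i + 1), strand=strands.get(g, "+"), species=species)
        for i, g in enumerate(order)
    )
    return ClusterRegion(
        species=species, seq_id="chr1", members=members,
        unplaced_members=(), anchors_found={"left": (), "right": ()},
    )


def brute_force_lcs(a, b):
    best = 0
    for k in range(len(a), 0, -1):
        for comb in combinations(range(len(a)), k):
            sub = [a[i] for i in comb]
            it = iter(b)
            if all(x in it for x in sub):
                return k
    return best


class TestCompareGeneOrder:
    def test_identical_clusters(self):
        a = region_from_order("ABCDE", "a")
        b = region_from_order("ABCDE", "b")
        oc = compare_gene_order(a, b, {g: g for g in "ABCDE"})
        assert (oc.n_shared, oc.lcs_length) == (5, 5)
        assert oc.tau == pytest.approx(1.0)

    def test_scrambled_order_matches_brute_force_lcs(self):
        a = region_from_order("ABCDE", "a")
        b = region_from_order("AEDCB", "b")
        oc = compare_gene_order(a, b, {g: g for g in "ABCDE"})
        assert oc.lcs_length == brute_force_lcs("ABCDE", "AEDCB") == 2

    def test_disjoint_clusters_flagged(self):
        a = region_from_order("ABC", "a")
        b = region_from_order("XYZ", "b")
        oc = compare_gene_order(a, b, {})
        assert (oc.n_shared, oc.lcs_length, oc.tau) == (0, 0, None)
        assert not oc.defined

    def test_lcs_symmetric(self, rng):
        import random

        for _ in range(20):
            perm = list("ABCDEFG")
            rng.shuffle(perm)
            a = region_from_order("ABCDEFG", "a")
            b = region_from_order("".join(perm), "b")
            m = {g: g for g in "ABCDEFG"}
            assert (
                compare_gene_order(a, b, m).lcs_length
                == compare_gene_order(b, a, m).lcs_length
            )

    def test_full_reversal_gives_tau_minus_one(self):
        a = region_from_order("ABCD", "a")
        b = region_from_order("DCBA", "b")
        oc = compare_gene_order(a, b, {g: g for g in "ABCD"})
        assert oc.tau == pytest.approx(-1.0)
        assert oc.lcs_length >= 1

    def test_strand_flips_counted_separately(self):
        a = region_from_order("ABC", "a")
        b = region_from_order("ABC", "b", strands={"B": "-"})
        oc = compare_gene_order(a, b, {g: g for g in "ABC"})
        assert oc.strand_flips == 1 and oc.lcs_length == 3
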