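"""p/JC distances, neighbor-joining, bipartitions, bootstrap supports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scari import (
    DistanceMatrix,
    MultipleAlignment,
    SaturationError,
    ScariError,
    bipartitions,
    bootstrap_supports,
    distance_matrix_from_alignment,
    jc_distance,
    neighbor_joining,
    p_distance,
)
from scari.reference import additive_matrix, random_binary_tree


class TestPDistance:
    def test_identical_rows_zero(self):
        assert p_distance("ACDE", "ACDE") == 0.0

    def test_one_of_four_differs(self):
        assert p_distance("ACDE", "ACDF") == 0.25

    def test_pairwise_deletion_of_gapped_columns(self):
        assert p_distance("AC-E", "ACDE") == 0.0  # 3 comparable, 0 different

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ScariError, match="comparable"):
            p_distance("A--", "-CD")


class TestJcDistance:
    def test_zero_in_zero_out(self):
        assert jc_distance(0.0) == 0.0

    def test_known_value(self):
        # -0.95 * ln(1 - 0.05/0.95), evaluated to high precision
        assert jc_distance(0.05, b=0.95) == pytest.approx(0.0513638602, abs=1e-9)

    def test_saturation_errors_by_default(self):
        with pytest.raises(SaturationError):
            jc_distance(0.95)

    def test_saturation_cap(self):
        assert jc_distance(0.99, cap=5.0) == 5.0

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=0.0, max_value=0.94), st.floats(min_value=1e-6, max_value=0.0099))
    def test_strictly_increasing_in_p(self, p, dp):
        assert jc_distance(p + dp) > jc_distance(p)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        D = DistanceMatrix(taxa=("A", "B"), d=np.array([[0.0, 0.3], [0.3, 0.0]]))
        t = neighbor_joining(D).tree
        a, b = t.children
        assert a.length + b.length == pytest.approx(0.3)

    def test_three_taxa_three_point_formulas(self):
        D = DistanceMatrix(
            taxa=("A", "B", "C"),
            d=np.array([[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]]),
        )
        lengths = {n.name: n.length for n in neighbor_joining(D).tree.children}
        assert lengths == {
            "A": pytest.approx(0.05),
            "B": pytest.approx(0.15),
            "C": pytest.approx(0.25),
        }

    def test_four_taxon_additive_matrix_recovers_split(self):
        # path distances on ((A:1,B:2):1,(C:3,D:4))
        d = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        t = neighbor_joining(DistanceMatrix(taxa=("A", "B", "C", "D"), d=d))
        assert bipartitions(t.tree) == {frozenset({"A", "B"})}

    def test_consistency_on_random_additive_matrices(self, rng):
        for _ in range(15):
            true = random_binary_tree(int(rng.integers(6, 11)), rng)
            taxa, mat = additive_matrix(true)
            rec = neighbor_joining(DistanceMatrix(taxa=taxa, d=mat))
            assert bipartitions(rec.tree) == bipartitions(true)

    def test_agrees_with_skbio_nj_topology(self, rng):
        import skbio

        for _ in range(10):
            true = random_binary_tree(int(rng.integers(5, 9)), rng)
            taxa, mat = additive_matrix(true)
            ours = neighbor_joining(DistanceMatrix(taxa=taxa, d=mat))
            theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids=list(taxa)))
            assert bipartitions(ours.tree) == bipartitions(theirs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ScariError, match="symmetric"):
            DistanceMatrix(taxa=("A", "B"), d=np.array([[0.0, 1.0], [2.0, 0.0]]))


def _group_alignment(length=100):
    rows = ("A" * length, "A" * length, "C" * length, "C" * length)
    return MultipleAlignment(taxa=("a1", "a2", "c1", "c2"), rows=rows)


class TestBootstrap:
    def test_three_taxa_have_no_internal_bipartitions(self):
        aln = MultipleAlignment(
            taxa=("x", "y", "z"), rows=("AAAA", "AAAC", "AACC")
        )
        pt = bootstrap_supports(aln, n_reps=10, seed=1)
        assert pt.supports == {}

    def test_two_identical_groups_get_full_support(self):
        # p=1 between the groups saturates the correction; the cap keeps the
        # replicate trees buildable and the separating split is in every one
        pt = bootstrap_supports(_group_alignment(), n_reps=50, seed=3, cap=5.0)
        assert pt.supports[frozenset({"a1", "a2"})] == 100.0

    def test_same_seed_reproducible(self):
        a = bootstrap_supports(_group_alignment(), n_reps=25, seed=9, cap=5.0)
        b = bootstrap_supports(_group_alignment(), n_reps=25, seed=9, cap=5.0)
        assert a.supports == b.supports and a.to_newick() == b.to_newick()

    def test_supports_invariant_to_taxon_order(self, rng):
        rows = []
        base = rng.integers(0, 4, size=120)
        for i in range(5):
            r = base.copy()
            idx = rng.integers(0, 120, size=12 + 6 * i)
            r[idx] = (r[idx] + 1 + rng.integers(0, 3, size=len(idx))) % 4
            rows.append("".join("ACDE"[j] for j in r))
        taxa = ("t1", "t2", "t3", "t4", "t5")
        aln = MultipleAlignment(taxa=taxa, rows=tuple(rows))
        perm = (3, 0, 4, 1, 2)
        aln2 = MultipleAlignment(
            taxa=tuple(taxa[i] for i in perm), rows=tuple(rows[i] for i in perm)
        )
        s1 = bootstrap_supports(aln, n_reps=30, seed=5, cap=5.0).supports
        s2 = bootstrap_supports(aln2, n_reps=30, seed=5, cap=5.0).supports
        assert s1 == s2

    def test_supports_within_percent_range(self):
        pt = bootstrap_supports(_group_alignment(), n_reps=20, seed=2, cap=5.0)
        assert all(0.0 <= v <= 100.0 for v in pt.supports.values())

    def test_newick_carries_support_labels(self):
        pt = bootstrap_supports(_group_alignment(), n_reps=10, seed=4, cap=5.0)
        assert ")100" in pt.to_newick()


class TestDistanceMatrixFromAlignment:
    def test_matches_scalar_path(self):
        aln = MultipleAlignment(
            taxa=("u", "v"), rows=("ACDEFGHIKL", "ACDEFGHIKV")
        )
        D = distance_matrix_from_alignment(aln)
        assert D.p[0, 1] == pytest.approx(0.1)
        assert D.d[0, 1] == pytest.approx(jc_distance(0.1))
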