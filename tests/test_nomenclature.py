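"""Reference numbering, strict-ortholog calls, query naming, stability."""

import numpy as np
import pytest

from scari import (
    ClusterRegion,
    GeneModel,
    MultipleAlignment,
    NomenclatureRecord,
    OrthologAssignment,
    OrthologConflictError,
    ReservedNumbers,
    assign_query_names,
    assign_reference_numbers,
    bootstrap_supports,
    call_strict_orthologs,
    copy_number_summary,
    leaf_label,
    reciprocal_nearest_pairs,
    synteny_consistency,
)


def gene(gid, species="cattle", seq_id="chr5", start=0, placed=True):
    return GeneModel(gid, "", (), species, seq_id, start, start + 500, "+", placed)


def region(placed_ids, unplaced_ids=(), species="cattle"):
    members = tuple(
        gene(g, species=species, start=1000 * (i + 1)) for i, g in enumerate(placed_ids)
    )
    unplaced = tuple(
        gene(g, species=species, seq_id=f"scaf_{i+1}", start=100, placed=False)
        for i, g in enumerate(unplaced_ids)
    )
    return ClusterRegion(
        species=species, seq_id="chr5", members=members,
        unplaced_members=unplaced, anchors_found={"left": (), "right": ()},
    )


class TestReferenceNumbers:
    def test_consecutive_when_nothing_reserved(self):
        recs = assign_reference_numbers(region(["a", "b", "c"]))
        assert [r.proposed_symbol for r in recs] == ["SCARI1", "SCARI2", "SCARI3"]
        assert all(r.rationale == "positional" for r in recs)

    def test_reserved_numbers_skipped(self):
        recs = assign_reference_numbers(region(["a", "b", "c"]), ReservedNumbers(frozenset({2})))
        assert [r.proposed_symbol for r in recs] == ["SCARI1", "SCARI3", "SCARI4"]

    def test_unplaced_named_after_placed(self):
        recs = assign_reference_numbers(region(["a", "b"], ["u1"]))
        assert [(r.proposed_symbol, r.rationale) for r in recs] == [
            ("SCARI1", "positional"),
            ("SCARI2", "positional"),
            ("SCARI3", "unplaced"),
        ]

    def test_empty_cluster_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert assign_reference_numbers(region([])) == []


def _two_species_tree(n_pairs=4, support=100.0):
    """A tree of identical cross-species cherries with known supports."""
    length = 120
    rng = np.random.default_rng(7)
    base = rng.integers(0, 20, size=(n_pairs, length))
    for k in range(1, n_pairs):
        idx = rng.integers(0, length, size=40)
        base[k, idx] = (base[k, idx] + 1) % 20
    taxa, rows = [], []
    for k in range(n_pairs):
        s = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in base[k])
        taxa += [leaf_label("cattle", f"r{k+1}"), leaf_label("sheep", f"q{k+1}")]
        rows += [s, s]
    aln = MultipleAlignment(taxa=tuple(taxa), rows=tuple(rows))
    return bootstrap_supports(aln, n_reps=20, seed=1, cap=5.0)


class TestStrictOrthologs:
    def test_identical_pairs_are_strict_with_full_support(self):
        tree = _two_species_tree()
        asg = {a.gene_id: a for a in call_strict_orthologs(tree, "cattle", "sheep")}
        for k in range(1, 5):
            a = asg[f"q{k}"]
            assert a.strict and a.ortholog_group == f"r{k}" and a.support == 100.0

    def test_support_below_threshold_is_novel(self):
        tree = _two_species_tree()
        asg = call_strict_orthologs(tree, "cattle", "sheep", support_threshold=101.0)
        assert all(a.ortholog_group == "novel" for a in asg)

    def test_synteny_discordant_gene_is_novel(self):
        tree = _two_species_tree()
        syn = {f"q{k}": True for k in range(1, 5)}
        syn["q2"] = False
        asg = {a.gene_id: a for a in call_strict_orthologs(tree, "cattle", "sheep", synteny=syn)}
        assert asg["q2"].ortholog_group == "novel"
        assert asg["q1"].strict

    def test_absent_species_errors(self):
        tree = _two_species_tree()
        with pytest.raises(Exception, match="absent"):
            call_strict_orthologs(tree, "cattle", "goat")

    def test_reciprocal_pairs_are_injective(self):
        tree = _two_species_tree()
        pm = reciprocal_nearest_pairs(tree, "cattle", "sheep")
        assert len(set(pm.values())) == len(pm)


class TestSyntenyConsistency:
    def test_concordant_orders_all_true(self):
        ref = region(["r1", "r2", "r3"])
        qry = region(["q1", "q2", "q3"], species="sheep")
        pm = {"q1": "r1", "q2": "r2", "q3": "r3"}
        assert synteny_consistency(ref, qry, pm) == {"q1": True, "q2": True, "q3": True}

    def test_transposed_gene_flagged(self):
        ref = region(["r1", "r2", "r3", "r4"])
        qry = region(["q2", "q1", "q3", "q4"], species="sheep")
        pm = {"q1": "r1", "q2": "r2", "q3": "r3", "q4": "r4"}
        out = synteny_consistency(ref, qry, pm)
        assert sum(not v for v in out.values()) == 1  # one of the swapped pair

    def test_unplaced_gene_vacuously_consistent(self):
        ref = region(["r1", "r2"])
        qry = region(["q1"], ["qu"], species="sheep")
        out = synteny_consistency(ref, qry, {"q1": "r1", "qu": "r2"})
        assert out["qu"] is True


class TestQueryNames:
    def _ref_records(self):
        return [
            NomenclatureRecord("r1", "cattle", "SCARI1", "positional"),
            NomenclatureRecord("r2", "cattle", "SCARI2", "positional"),
            NomenclatureRecord("r3", "cattle", "SCARI3", "positional"),
        ]

    def test_strict_ortholog_inherits_reference_number(self):
        qry = region(["q1"], species="sheep")
        asg = [OrthologAssignment("q1", "r3", 100.0, True)]
        recs = assign_query_names(asg, qry, self._ref_records())
        assert [(r.gene_id, r.proposed_symbol, r.rationale) for r in recs] == [
            ("q1", "SCARI3", "strict_ortholog")
        ]

    def test_positional_and_unplaced_fill_smallest_unused(self):
        qry = region(["q1", "q2"], ["qu"], species="sheep")
        asg = [OrthologAssignment("q1", "r3", 100.0, True)]
        recs = assign_query_names(asg, qry, self._ref_records())
        assert [r.proposed_symbol for r in recs] == ["SCARI3", "SCARI1", "SCARI2"]
        assert [r.rationale for r in recs] == ["strict_ortholog", "positional", "unplaced"]

    def test_conflicting_claims_error(self):
        qry = region(["q1", "q2"], species="sheep")
        asg = [
            OrthologAssignment("q1", "r1", 100.0, True),
            OrthologAssignment("q2", "r1", 100.0, True),
        ]
        with pytest.raises(OrthologConflictError, match="q1.*q2|q2.*q1"):
            assign_query_names(asg, qry, self._ref_records())

    def test_appending_unplaced_gene_keeps_placed_symbols(self):
        asg = [OrthologAssignment("q1", "r2", 100.0, True)]
        qry = region(["q1", "q2"], ["qu1"], species="sheep")
        before = {
            r.gene_id: r.proposed_symbol
            for r in assign_query_names(asg, qry, self._ref_records())
        }
        qry2 = region(["q1", "q2"], ["qu1", "qu2"], species="sheep")
        after = {
            r.gene_id: r.proposed_symbol
            for r in assign_query_names(asg, qry2, self._ref_records())
        }
        placed = {"q1", "q2"}
        assert all(after[g] == before[g] for g in placed)

    def test_determinism_byte_identical(self):
        qry = region(["q1", "q2"], ["qu"], species="sheep")
        asg = [OrthologAssignment("q1", "r1", 90.0, True)]
        a = assign_query_names(asg, qry, self._ref_records())
        b = assign_query_names(asg, qry, self._ref_records())
        assert a == b

    def test_symbols_unique_within_species(self):
        qry = region(["q1", "q2", "q3"], ["u1", "u2"], species="sheep")
        asg = [OrthologAssignment("q2", "r2", 100.0, True)]
        recs = assign_query_names(asg, qry, self._ref_records())
        syms = [r.proposed_symbol for r in recs]
        assert len(set(syms)) == len(syms)


def test_copy_number_summary_on_synthetic_standin():
    # synthetic stand-in for a deposited nomenclature dataset
    recs = [
        NomenclatureRecord("g1", "cattle", "SCARI1", "positional"),
        NomenclatureRecord("g2", "cattle", "SCARI2", "unplaced"),
        NomenclatureRecord("g3", "pig", "SCARI1", "strict_ortholog"),
    ]
    summary = copy_number_summary(recs)
    assert summary == {
        "cattle": {"n_genes": 2, "n_unplaced": 1},
        "pig": {"n_genes": 1, "n_unplaced": 0},
    }
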