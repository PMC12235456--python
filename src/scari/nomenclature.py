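"""Standardized SCARI symbol assignment.

The reference species (cattle for the WC1/SCARI family) is numbered first:
placed cluster members get consecutive numbers in ascending coordinate
order, skipping any reserved numbers, and unplaced members are numbered
last. Query species inherit a reference number wherever a strict ortholog
is found — reciprocal nearest leaves in the bootstrap tree, a sufficiently
supported joining clade, and concordant gene order — and the remaining
genes are numbered consecutively by position, unplaced genes last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, OrthologConflictError, ScariError
from .io import GeneModel, NomenclatureRecord
from .phylogeny import PhyloTree, _canonical, patristic_distances
from .synteny import ClusterRegion

#: leaf labels in pipeline trees are "<species>|<gene_id>"
LEAF_SEP = "|"


def leaf_label(species: str, gene_id: str) -> str:
    return f"{species}{LEAF_SEP}{gene_id}"


def split_leaf_label(label: str) -> tuple[str, str]:
    species, _, gene_id = label.partition(LEAF_SEP)
    if not gene_id:
        raise ScariError(f"leaf label {label!r} lacks species prefix")
    return species, gene_id


@dataclass(frozen=True)
class OrthologAssignment:
    """Phylogeny + synteny verdict for one query gene."""

    gene_id: str
    ortholog_group: str  # reference gene_id or "novel"
    support: float
    synteny_consistent: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.support <= 100.0:
            raise ScariError("support must be in [0, 100]")

    @property
    def strict(self) -> bool:
        return self.ortholog_group != "novel"


@dataclass(frozen=True)
class ReservedNumbers:
    """Numbers withheld from fresh assignment in the reference species
    (kept for gene models expected from future annotation revisions)."""

    numbers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.numbers):
            raise ConfigError("reserved numbers must be positive")

    def __contains__(self, n: int) -> bool:
        return n in self.numbers


def assign_reference_numbers(
    cluster: ClusterRegion,
    reserved: ReservedNumbers | None = None,
    prefix: str = "SCARI",
) -> list[NomenclatureRecord]:
    """Number the reference cluster: placed members in coordinate order,
    skipping reserved numbers; unplaced members last."""
    import warnings

    if reserved is None:
        reserved = ReservedNumbers()
    if not cluster.members and not cluster.unplaced_members:
        warnings.warn(f"empty cluster for {cluster.species}", stacklevel=2)
        return []
    records: list[NomenclatureRecord] = []
    counter = _NumberDispenser(reserved)
    for idx, g in enumerate(cluster.members, start=1):
        n = counter.next()
        records.append(
            NomenclatureRecord(
                gene_id=g.gene_id,
                species=cluster.species,
                proposed_symbol=f"{prefix}{n}",
                rationale="positional",
                evidence=f"reference order_index={idx} on {g.seq_id}",
            )
        )
    for idx, g in enumerate(cluster.unplaced_members, start=1):
        n = counter.next()
        records.append(
            NomenclatureRecord(
                gene_id=g.gene_id,
                species=cluster.species,
                proposed_symbol=f"{prefix}{n}",
                rationale="unplaced",
                evidence=f"unplaced contig {g.seq_id}, named after placed members",
            )
        )
    return records


class _NumberDispenser:
    def __init__(self, reserved: ReservedNumbers, used: set[int] | None = None):
        self._reserved = reserved
        self._used = set(used or ())

    def next(self) -> int:
        n = 1
        while n in self._reserved or n in self._used:
            n += 1
        self._used.add(n)
        return n


# ---------------------------------------------------------------------------
# strict orthologs


def _nearest_maps(
    tree: PhyloTree, ref_species: str, query_species: str
) -> tuple[dict[str, str], dict[str, str]]:
    taxa, dmat = patristic_distances(tree.tree)
    species_of = {t: split_leaf_label(t)[0] for t in taxa}
    ref_leaves = [t for t in taxa if species_of[t] == ref_species]
    query_leaves = [t for t in taxa if species_of[t] == query_species]
    if not ref_leaves:
        raise ScariError(f"species {ref_species!r} absent from tree")
    if not query_leaves:
        raise ScariError(f"species {query_species!r} absent from tree")
    idx = {t: i for i, t in enumerate(taxa)}

    def nearest(leaf: str, pool: list[str]) -> str:
        row = dmat[idx[leaf]]
        return min(pool, key=lambda t: (row[idx[t]], t))

    nearest_ref = {q: nearest(q, ref_leaves) for q in query_leaves}
    nearest_query = {r: nearest(r, query_leaves) for r in ref_leaves}
    return nearest_ref, nearest_query


def reciprocal_nearest_pairs(
    tree: PhyloTree, ref_species: str, query_species: str
) -> dict[str, str]:
    """Reciprocal nearest-leaf pairs (query gene_id -> ref gene_id),
    irrespective of support or synteny."""
    nearest_ref, nearest_query = _nearest_maps(tree, ref_species, query_species)
    return {
        split_leaf_label(q)[1]: split_leaf_label(r)[1]
        for q, r in nearest_ref.items()
        if nearest_query[r] == q
    }


def call_strict_orthologs(
    tree: PhyloTree,
    ref_species: str,
    query_species: str,
    support_threshold: float = 70.0,
    synteny: dict[str, bool] | None = None,
) -> list[OrthologAssignment]:
    """Strict-ortholog calls for every query-species gene in the tree.

    A query gene is a strict ortholog of reference gene r iff (i) the two
    are reciprocal nearest leaves across the two species by patristic
    distance, (ii) a defining clade exists — a clade containing both genes
    and no other gene of either species — with bootstrap support
    >= ``support_threshold`` (the reported support is the best such clade's;
    when the only containing clade is the whole unrooted tree there is no
    internal bipartition to contradict the pair and it counts as support
    100), and (iii) the pair's gene-order context is concordant per
    ``synteny`` (query gene_id -> bool; genes without order context, e.g.
    on unplaced contigs, default to True). Everything else is "novel".

    Requiring a supported clade that excludes every other gene of the two
    species — rather than scoring the very smallest containing clade —
    keeps true 1:1 pairs strict when only the within-group resolution is
    unstable, while still rejecting pairs entangled with lineage-specific
    duplicates.
    """
    synteny = synteny or {}
    nearest_ref, nearest_query = _nearest_maps(tree, ref_species, query_species)
    query_leaves = sorted(nearest_ref)

    both_species_leaves = frozenset(
        t
        for t in (tip.name for tip in tree.tree.tips())
        if split_leaf_label(t)[0] in (ref_species, query_species)
    )
    out: list[OrthologAssignment] = []
    for q in query_leaves:
        q_gene = split_leaf_label(q)[1]
        r = nearest_ref[q]
        reciprocal = nearest_query[r] == q
        support = _pair_clade_support(tree, q, r, both_species_leaves)
        consistent = synteny.get(q_gene, True)
        strict = reciprocal and support >= support_threshold and consistent
        out.append(
            OrthologAssignment(
                gene_id=q_gene,
                ortholog_group=split_leaf_label(r)[1] if strict else "novel",
                support=support,
                synteny_consistent=consistent,
            )
        )
    return out


def _pair_clade_support(
    tree: PhyloTree, leaf_a: str, leaf_b: str, both_species_leaves: frozenset
) -> float:
    """Best support among clades holding the pair and no other gene of the
    two species; 0 when no such clade exists."""
    pair = {leaf_a, leaf_b}
    all_tips = frozenset(t.name for t in tree.tree.tips())
    best = 0.0
    for node in tree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        for s in (side, all_tips - side):
            if pair <= s and (s & both_species_leaves) == pair:
                key = _canonical(side, all_tips - side)
                best = max(best, tree.supports.get(key, 0.0))
    if (all_tips & both_species_leaves) == pair:
        best = 100.0  # whole unrooted tree: no internal split can refute it
    return best


def synteny_consistency(
    ref_cluster: ClusterRegion,
    query_cluster: ClusterRegion,
    pair_map: dict[str, str],
) -> dict[str, bool]:
    """Per-query-gene order concordance used by strict-ortholog calls.

    A placed query gene is concordant iff it belongs to a longest common
    subsequence of the reference and query cluster orderings under
    ``pair_map`` (query gene_id -> reference gene_id). Unplaced query genes
    have no order context and are vacuously concordant.
    """
    ref_rank = {g.gene_id: i for i, g in enumerate(ref_cluster.members)}
    q_order = [
        g.gene_id
        for g in query_cluster.members
        if pair_map.get(g.gene_id) in ref_rank
    ]
    ranks = [ref_rank[pair_map[g]] for g in q_order]
    in_lis = _lis_membership(ranks)
    lis_genes = {q_order[i] for i in in_lis}
    out: dict[str, bool] = {}
    for g in query_cluster.members:
        if g.gene_id in pair_map and pair_map[g.gene_id] in ref_rank:
            out[g.gene_id] = g.gene_id in lis_genes
        else:
            # partner unplaced (or no partner): no order evidence either way
            out[g.gene_id] = True
    for g in query_cluster.unplaced_members:
        out[g.gene_id] = True
    return out


def _lis_membership(ranks: list[int]) -> set[int]:
    """Indices belonging to one canonical longest increasing subsequence."""
    n = len(ranks)
    if n == 0:
        return set()
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ranks[j] < ranks[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    out: set[int] = set()
    while end != -1:
        out.add(end)
        end = prev[end]
    return out


# ---------------------------------------------------------------------------
# query-species naming


def assign_query_names(
    assignments: list[OrthologAssignment],
    query_cluster: ClusterRegion,
    ref_records: list[NomenclatureRecord],
    prefix: str = "SCARI",
) -> list[NomenclatureRecord]:
    """Name a query species' cluster from strict orthologs + position.

    Strict orthologs inherit the reference gene's number; remaining placed
    genes take the smallest unused numbers in ascending coordinate order;
    unplaced genes come last, ordered by (contig name, start). Numbering is
    stable: appending unplaced genes never renumbers placed genes. Two query
    genes claiming the same reference gene is a hard error.
    """
    ref_number = {r.gene_id: r.number(prefix) for r in ref_records}
    by_gene = {a.gene_id: a for a in assignments}

    claimed: dict[str, str] = {}
    for a in assignments:
        if a.strict:
            if a.ortholog_group not in ref_number:
                raise ScariError(
                    f"assignment for {a.gene_id} references unknown gene "
                    f"{a.ortholog_group}"
                )
            if a.ortholog_group in claimed:
                raise OrthologConflictError(
                    f"{claimed[a.ortholog_group]} and {a.gene_id} both claim "
                    f"reference gene {a.ortholog_group}"
                )
            claimed[a.ortholog_group] = a.gene_id

    used = {ref_number[r] for r in claimed}
    records: list[NomenclatureRecord] = []
    dispenser = _NumberDispenser(ReservedNumbers(), used=used)

    def emit(g: GeneModel, placed: bool, order_idx: int) -> None:
        a = by_gene.get(g.gene_id)
        if a is not None and a.strict:
            n = ref_number[a.ortholog_group]
            records.append(
                NomenclatureRecord(
                    gene_id=g.gene_id,
                    species=query_cluster.species,
                    proposed_symbol=f"{prefix}{n}",
                    rationale="strict_ortholog",
                    evidence=(
                        f"ortholog of {a.ortholog_group} "
                        f"(support {a.support:.0f}, synteny ok)"
                    ),
                )
            )
        else:
            n = dispenser.next()
            records.append(
                NomenclatureRecord(
                    gene_id=g.gene_id,
                    species=query_cluster.species,
                    proposed_symbol=f"{prefix}{n}",
                    rationale="positional" if placed else "unplaced",
                    evidence=(
                        f"order_index={order_idx} on {g.seq_id}"
                        if placed
                        else f"unplaced contig {g.seq_id}, named after placed members"
                    ),
                )
            )

    for idx, g in enumerate(query_cluster.members, start=1):
        emit(g, placed=True, order_idx=idx)
    unplaced_sorted = sorted(
        query_cluster.unplaced_members, key=lambda g: (g.seq_id, g.start)
    )
    for idx, g in enumerate(unplaced_sorted, start=1):
        emit(g, placed=False, order_idx=idx)
    return records


# ---------------------------------------------------------------------------
# dataset summaries


def copy_number_summary(records: list[NomenclatureRecord]) -> dict[str, dict[str, int]]:
    """Per-species family copy number and unplaced-gene count."""
    out: dict[str, dict[str, int]] = {}
    for r in records:
        s = out.setdefault(r.species, {"n_genes": 0, "n_unplaced": 0})
        s["n_genes"] += 1
        if r.rationale == "unplaced":
            s["n_unplaced"] += 1
    return out
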