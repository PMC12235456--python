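"""Synteny-anchored cluster extraction and gene-order comparison.

The receptor cluster is located by conserved flanking anchor genes (by
default RBP5/CLSTN3/PEX5 upstream and CLEC4E/CLEC4D/CLEC6A downstream, the
mammalian genes bracketing the WC1/SCARI expansion). Candidate family
members between the innermost anchors on the anchor-richest assembly unit
form the cluster; candidates elsewhere are reported as unplaced members.
Cross-species order conservation is summarised by shared-gene count, longest
common subsequence and a Kendall-style rank concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import kendalltau

from .errors import ClusterError, ConfigError
from .io import GeneModel

#: flag set on members lying outside the innermost anchor interval
SPLIT_CLUSTER = "split_cluster"


@dataclass(frozen=True)
class AnchorSpec:
    """Conserved flanking genes bounding the cluster, per side."""

    left_anchors: tuple[str, ...] = ("RBP5", "CLSTN3", "PEX5")
    right_anchors: tuple[str, ...] = ("CLEC4E", "CLEC4D", "CLEC6A")
    min_anchors_per_side: int = 1

    def __post_init__(self) -> None:
        if not self.left_anchors or not self.right_anchors:
            raise ConfigError("anchor lists must be non-empty")
        if set(self.left_anchors) & set(self.right_anchors):
            raise ConfigError("anchor sides must be disjoint")
        if self.min_anchors_per_side < 1:
            raise ConfigError("min_anchors_per_side must be >= 1")


@dataclass(frozen=True)
class ClusterRegion:
    """Ordered candidate genes between the found anchors on one assembly unit.

    ``members`` are sorted by ascending start coordinate regardless of
    strand; members beyond an intervening anchor carry the ``split_cluster``
    flag instead of being dropped. ``unplaced_members`` are candidates found
    on any other assembly unit, ordered by (seq_id, start).
    """

    species: str
    seq_id: str
    members: tuple[GeneModel, ...]
    unplaced_members: tuple[GeneModel, ...]
    anchors_found: dict[str, tuple[GeneModel, ...]]
    flags: dict[str, frozenset] = field(default_factory=dict)

    def member_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]

    def all_candidates(self) -> list[GeneModel]:
        return list(self.members) + list(self.unplaced_members)

    def to_tsv(self) -> str:
        lines = ["\t".join(
            ("species", "seq_id", "order_index", "gene_id", "strand", "placed", "flags")
        )]
        for idx, g in enumerate(self.members, start=1):
            fl = ",".join(sorted(self.flags.get(g.gene_id, ())))
            lines.append("\t".join(
                (self.species, g.seq_id, str(idx), g.gene_id, g.strand, "true", fl)
            ))
        for idx, g in enumerate(self.unplaced_members, start=len(self.members) + 1):
            fl = ",".join(sorted(self.flags.get(g.gene_id, ())))
            lines.append("\t".join(
                (self.species, g.seq_id, str(idx), g.gene_id, g.strand, "false", fl)
            ))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class OrderConservation:
    """Pairwise gene-order agreement between two clusters."""

    n_shared: int
    lcs_length: int
    tau: float | None  # None when undefined (no or one shared ortholog)
    strand_flips: int = 0

    @property
    def defined(self) -> bool:
        return self.tau is not None


def _symbols_of(gene: GeneModel) -> set[str]:
    return {gene.symbol, *gene.aliases} - {""}


def extract_cluster(
    genes: list[GeneModel],
    spec: AnchorSpec | None = None,
    candidate_ids: set[str] | list[str] = (),
) -> ClusterRegion:
    """Locate the cluster of candidate genes between flanking anchors.

    Anchors are matched by symbol (or alias) on each assembly unit; the unit
    with the most anchors wins (ties broken by name). The innermost anchor
    copies — nearest the candidate genes — bound the cluster; candidates on
    the winning unit but outside those bounds are kept with a
    ``split_cluster`` flag, and candidates on any other unit become
    unplaced members. Input order is irrelevant (genes are sorted
    internally).

    Raises ClusterError when no unit reaches ``min_anchors_per_side`` found
    anchors on both sides.
    """
    if spec is None:
        spec = AnchorSpec()
    candidates = set(candidate_ids)
    if not genes:
        raise ClusterError("cluster not localizable: no genes supplied")
    species = genes[0].species
    left_set, right_set = set(spec.left_anchors), set(spec.right_anchors)

    by_unit: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.seq_id, g.start, g.gene_id)):
        by_unit.setdefault(g.seq_id, []).append(g)

    best_unit = None
    best_count = -1
    for unit in sorted(by_unit):
        ln = [g for g in by_unit[unit] if _symbols_of(g) & left_set]
        rn = [g for g in by_unit[unit] if _symbols_of(g) & right_set]
        if len(ln) < spec.min_anchors_per_side or len(rn) < spec.min_anchors_per_side:
            continue
        count = len(ln) + len(rn)
        if count > best_count:
            best_unit, best_count = unit, count
    if best_unit is None:
        raise ClusterError(
            "cluster not localizable: no assembly unit has "
            f">= {spec.min_anchors_per_side} anchors on each side"
        )

    unit_genes = by_unit[best_unit]
    left_found = tuple(g for g in unit_genes if _symbols_of(g) & left_set)
    right_found = tuple(g for g in unit_genes if _symbols_of(g) & right_set)
    cands_here = [g for g in unit_genes if g.gene_id in candidates]

    # innermost copies: the left anchor nearest the cluster from below, the
    # right anchor nearest from above (robust to tandem anchor duplications)
    right_starts = [g.start for g in right_found]
    inner_left = max(
        (g.end for g in left_found if not right_starts or g.end < min(right_starts)),
        default=min(g.end for g in left_found),
    )
    inner_right = min(
        (g.start for g in right_found if g.start > inner_left),
        default=max(g.start for g in right_found),
    )

    members = tuple(cands_here)
    flags: dict[str, frozenset] = {}
    for g in members:
        if not (inner_left < g.start and g.end < inner_right):
            flags[g.gene_id] = frozenset({SPLIT_CLUSTER})

    unplaced = tuple(
        g
        for unit in sorted(by_unit)
        if unit != best_unit
        for g in by_unit[unit]
        if g.gene_id in candidates
    )
    return ClusterRegion(
        species=species,
        seq_id=best_unit,
        members=members,
        unplaced_members=unplaced,
        anchors_found={"left": left_found, "right": right_found},
        flags=flags,
    )


def _lcs_length(a: list, b: list) -> int:
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[m]


def compare_gene_order(
    a: ClusterRegion, b: ClusterRegion, ortholog_map: dict[str, str]
) -> OrderConservation:
    """Order conservation between two clusters linked by ``ortholog_map``
    (gene_id in a -> gene_id in b).

    Returns shared-ortholog count, the longest common subsequence of the two
    orderings, and Kendall's tau over shared ranks (None when fewer than two
    shared orthologs). Orthologous pairs annotated on opposite strands are
    counted as ``strand_flips``.
    """
    a_order = [g.gene_id for g in a.members]
    b_index = {g.gene_id: i for i, g in enumerate(b.members)}
    b_strand = {g.gene_id: g.strand for g in b.members}
    a_strand = {g.gene_id: g.strand for g in a.members}

    shared_a = [g for g in a_order if ortholog_map.get(g) in b_index]
    n_shared = len(shared_a)
    if n_shared == 0:
        return OrderConservation(n_shared=0, lcs_length=0, tau=None)

    partner_ranks = [b_index[ortholog_map[g]] for g in shared_a]
    lcs = _lcs_length(sorted(partner_ranks), partner_ranks)
    flips = sum(
        1 for g in shared_a if a_strand[g] != b_strand[ortholog_map[g]]
    )
    if n_shared < 2:
        tau = None
    else:
        tau = float(kendalltau(range(n_shared), partner_ranks).statistic)
    return OrderConservation(
        n_shared=n_shared, lcs_length=lcs, tau=tau, strand_flips=flips
    )
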