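"""Distance-based phylogenetics: p-distance, Jukes-Cantor correction,
neighbor-joining, and bootstrap supports.

Distances are computed on aligned amino-acid sequences with pairwise
deletion of gapped columns. The Jukes-Cantor correction uses the 20-state
generalization, d = -b * ln(1 - p/b) with b = 19/20, which assumes equal
exchange rates between all residues. Trees are unrooted (stored as a
trifurcation at the last join) with nonnegative branch lengths; bootstrap
supports are percentages of column-resampled replicates containing each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import skbio

from .alignment import MultipleAlignment
from .errors import ConfigError, SaturationError, ScariError

logger = logging.getLogger(__name__)

#: 20-state Jukes-Cantor correction constant for proteins
JC_B_PROTEIN = 19.0 / 20.0

_GAP = ord("-")


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise corrected distances over an ordered taxon list.

    ``d`` is symmetric with zero diagonal; ``p`` optionally holds the
    underlying proportion-of-differing-sites matrix; ``b`` the correction
    constant.
    """

    taxa: tuple[str, ...]
    d: np.ndarray
    p: np.ndarray | None = None
    b: float = JC_B_PROTEIN

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ScariError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ScariError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ScariError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ScariError("distances must be nonnegative")

    def to_tsv(self) -> str:
        lines = ["\t".join(("",) + self.taxa)]
        for i, t in enumerate(self.taxa):
            lines.append("\t".join([t] + [f"{x:.6g}" for x in self.d[i]]))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree plus bootstrap supports per internal bipartition.

    Bipartitions are canonical frozensets of tip names (the lexicographically
    smaller side); supports are percentages in [0, 100] and are also written
    into internal node names for Newick export.
    """

    tree: skbio.TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(t.name for t in self.tree.tips()))

    def to_newick(self) -> str:
        from .io import write_newick

        return write_newick(self.tree)


# ---------------------------------------------------------------------------
# distances


def p_distance(row_i: str, row_j: str) -> float:
    """Proportion of differing sites under pairwise deletion of gap columns."""
    if len(row_i) != len(row_j):
        raise ScariError("rows must have equal (aligned) length")
    a = np.frombuffer(row_i.encode(), dtype=np.uint8)
    b = np.frombuffer(row_j.encode(), dtype=np.uint8)
    comparable = (a != _GAP) & (b != _GAP)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ScariError("no comparable columns between rows")
    mism = int(((a != b) & comparable).sum())
    return mism / n_comp


def jc_distance(p: float, b: float = JC_B_PROTEIN, cap: float | None = None) -> float:
    """Jukes-Cantor corrected distance d = -b * ln(1 - p/b).

    For p at or beyond the saturation bound b, raises SaturationError unless
    a ``cap`` is configured, in which case the cap is returned (and any
    finite correction exceeding the cap is truncated to it).
    """
    if not 0.0 <= p <= 1.0:
        raise ScariError(f"proportion p={p} outside [0,1]")
    if p >= b:
        if cap is not None:
            return cap
        raise SaturationError(f"p={p:.4f} >= b={b:.4f}: distance saturated")
    d = -b * math.log1p(-p / b)
    if cap is not None:
        d = min(d, cap)
    return d


def distance_matrix_from_alignment(
    aln: MultipleAlignment, b: float = JC_B_PROTEIN, cap: float | None = None
) -> DistanceMatrix:
    """All pairwise JC distances from an alignment, pairwise-deletion p."""
    enc = np.vstack(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    )
    valid = enc != _GAP
    both = valid[:, None, :] & valid[None, :, :]
    n_comp = both.sum(axis=2)
    if np.any(n_comp[~np.eye(len(aln.taxa), dtype=bool)] == 0):
        bad = np.argwhere((n_comp == 0) & ~np.eye(len(aln.taxa), dtype=bool))[0]
        raise ScariError(
            f"no comparable columns between {aln.taxa[bad[0]]} and {aln.taxa[bad[1]]}"
        )
    mism = ((enc[:, None, :] != enc[None, :, :]) & both).sum(axis=2)
    with np.errstate(invalid="ignore"):
        p = np.where(n_comp > 0, mism / np.maximum(n_comp, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    d = np.zeros_like(p)
    n = len(aln.taxa)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(float(p[i, j]), b=b, cap=cap)
    return DistanceMatrix(taxa=aln.taxa, d=d, p=p, b=b)


# ---------------------------------------------------------------------------
# neighbor-joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Standard neighbor-joining (Q-criterion agglomeration).

    Deterministic: Q ties are broken by the lexicographically smallest taxon
    pair (each internal node is keyed by its smallest descendant leaf name).
    Negative branch lengths are clamped to 0 and the deficit logged. The
    result is rooted at the final trifurcation but represents an unrooted
    tree.
    """
    n = len(D.taxa)
    if n < 2:
        raise ScariError("need at least 2 taxa")
    if len(set(D.taxa)) != n:
        raise ScariError("duplicate taxon names")
    d = D.d.astype(np.float64).copy()
    nodes = [skbio.TreeNode(name=t) for t in D.taxa]
    keys = list(D.taxa)

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.debug("clamped negative branch %s: %.6g", what, x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if Q[i, j] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, keys[i]), clamp(lj, keys[j])
        parent = skbio.TreeNode()
        a, b_ = nodes[i], nodes[j]
        a.length, b_.length = li, lj
        parent.extend([a, b_])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    root = skbio.TreeNode()
    if len(nodes) == 2:
        l0 = d[0, 1] / 2.0
        nodes[0].length = l0
        nodes[1].length = d[0, 1] - l0
        root.extend(nodes)
    else:
        dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
        nodes[0].length = clamp((dab + dac - dbc) / 2.0, keys[0])
        nodes[1].length = clamp((dab + dbc - dac) / 2.0, keys[1])
        nodes[2].length = clamp((dac + dbc - dab) / 2.0, keys[2])
        root.extend(nodes)
    return PhyloTree(tree=root)


# ---------------------------------------------------------------------------
# bipartitions & bootstrap


def bipartitions(tree: skbio.TreeNode) -> set[frozenset]:
    """Canonical internal bipartitions (nontrivial splits) of an unrooted tree.

    Each split is represented by the lexicographically smaller side as a
    frozenset of tip names.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        comp = all_tips - side
        if len(side) < 2 or len(comp) < 2:
            continue
        out.add(_canonical(side, comp))
    return out


def _canonical(side: frozenset, comp: frozenset) -> frozenset:
    return min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))


def bootstrap_supports(
    aln: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    b: float = JC_B_PROTEIN,
    cap: float | None = None,
) -> PhyloTree:
    """NJ tree from the full alignment plus bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is rebuilt p -> JC -> NJ; a bipartition's support is the percentage of
    replicates whose tree contains it. Replicate r draws from an independent
    stream derived from (seed, r), so results are reproducible and invariant
    to taxon input order.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    D = distance_matrix_from_alignment(aln, b=b, cap=cap)
    main = neighbor_joining(D)
    splits = bipartitions(main.tree)
    counts = {s: 0 for s in splits}
    L = aln.length
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, L, size=L)
        rep_aln = aln.subsample_columns(idx)
        rep_D = distance_matrix_from_alignment(rep_aln, b=b, cap=cap)
        rep_splits = bipartitions(neighbor_joining(rep_D).tree)
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    _annotate_supports(main.tree, supports)
    return PhyloTree(tree=main.tree, supports=supports)


def _annotate_supports(tree: skbio.TreeNode, supports: dict[frozenset, float]) -> None:
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = _canonical(side, all_tips - side)
        if key in supports:
            node.name = str(int(round(supports[key])))


def patristic_distances(tree: skbio.TreeNode) -> tuple[tuple[str, ...], np.ndarray]:
    """Tip-to-tip path-length distances, taxa sorted for determinism."""
    dm = tree.tip_tip_distances()
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    taxa = tuple(dm.ids[i] for i in order)
    mat = dm.data[np.ix_(order, order)]
    return taxa, mat
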