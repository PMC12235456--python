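"""Naive reference implementations used for validation.

These deliberately re-derive results by exhaustive enumeration or direct
construction, independently of the optimised production code, so they can
serve as oracles in tests and in the acceptance checks. They are far too
slow for real inputs.
"""

from __future__ import annotations

import numpy as np
import skbio

from .alignment import ScoringScheme
from .motif import DomainHit, MotifTemplate
from .io import ProteinRecord


# ---------------------------------------------------------------------------
# alignment: exhaustive enumeration over all global alignments


def score_alignment(ra: str, rb: str, scheme: ScoringScheme) -> float:
    """Score one explicit gapped alignment under affine run costs
    (open + (g-1)*extend per run; terminal runs free when free_end_gaps)."""
    assert len(ra) == len(rb)
    cols = list(zip(ra, rb))
    runs: list[tuple[str, int, int]] = []  # (kind, start, end) gap runs
    score = 0.0
    k = 0
    while k < len(cols):
        ca, cb = cols[k]
        if ca != "-" and cb != "-":
            score += scheme.score(ca, cb)
            k += 1
            continue
        kind = "a" if ca == "-" else "b"
        start = k
        while k < len(cols) and (cols[k][0] if kind == "a" else cols[k][1]) == "-":
            k += 1
        runs.append((kind, start, k))
    for kind, start, end in runs:
        g = end - start
        if scheme.free_end_gaps and (start == 0 or end == len(cols)):
            continue
        score -= scheme.gap_open + (g - 1) * scheme.gap_extend
    return score


def enumerate_best_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Maximum score over every possible global alignment of a and b,
    generated explicitly; tractable only for short sequences."""
    best = -np.inf
    stack = [("", "", 0, 0)]
    while stack:
        ra, rb, i, j = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score_alignment(ra, rb, scheme))
            continue
        if i < len(a) and j < len(b):
            stack.append((ra + a[i], rb + b[j], i + 1, j + 1))
        if i < len(a):
            stack.append((ra + a[i], rb + "-", i + 1, j))
        if j < len(b):
            stack.append((ra + "-", rb + b[j], i, j + 1))
    return float(best)


# ---------------------------------------------------------------------------
# motif: exhaustive position-by-position matcher


def exhaustive_scan(protein: ProteinRecord, template: MotifTemplate) -> list[DomainHit]:
    """Left-greedy SRCR scan by direct search.

    At each start position (ascending) the lexicographically-smallest gap
    vector forming a complete cysteine chain is sought by depth-first
    search; an accepted match must not exceed max_domain_len, and scanning
    resumes after it.
    """
    seq = protein.sequence
    spacings = template.cysteine_spacings
    hits: list[DomainHit] = []
    pos = 0
    s = 0
    while s < len(seq):
        if s < pos or seq[s] != "C":
            s += 1
            continue
        end = _dfs_chain(seq, s, spacings, 0)
        if end is None or (end - s) > template.max_domain_len:
            s += 1
            continue
        hits.append(
            DomainHit(
                protein_id=protein.protein_id,
                start=s + 1,
                end=end,
                n_cysteines_matched=len(spacings) + 1,
            )
        )
        pos = end
        s = end
    return hits


def _dfs_chain(seq: str, c_pos: int, spacings, level: int) -> int | None:
    if level == len(spacings):
        return c_pos + 1  # 1-based end of the last cysteine
    lo, hi = spacings[level]
    for g in range(lo, hi + 1):
        nxt = c_pos + 1 + g
        if nxt >= len(seq):
            break
        if seq[nxt] == "C":
            end = _dfs_chain(seq, nxt, spacings, level + 1)
            if end is not None:
                return end
    return None


# ---------------------------------------------------------------------------
# phylogeny: random binary trees and additive matrices


def random_binary_tree(n_taxa: int, rng: np.random.Generator,
                       min_bl: float = 0.05, max_bl: float = 1.0) -> skbio.TreeNode:
    """Random topology by repeated random joins; branch lengths U[min,max]."""
    nodes = [skbio.TreeNode(name=f"T{i + 1}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_bl, max_bl))
        b.length = float(rng.uniform(min_bl, max_bl))
        parent = skbio.TreeNode()
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = skbio.TreeNode()
    for n in nodes:
        n.length = float(rng.uniform(min_bl, max_bl))
    root.extend(nodes)
    return root


def additive_matrix(tree: skbio.TreeNode) -> tuple[tuple[str, ...], np.ndarray]:
    """Exact leaf-to-leaf path lengths of a tree (an additive matrix)."""
    dm = tree.tip_tip_distances()
    order = sorted(range(len(dm.ids)), key=lambda i: dm.ids[i])
    taxa = tuple(dm.ids[i] for i in order)
    return taxa, dm.data[np.ix_(order, order)]
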