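"""Global protein alignment with affine gaps and free end gaps.

Pairwise alignment is the Gotoh three-state dynamic programme under a
substitution matrix (Blosum62 by default). ``free_end_gaps`` gives
semi-global behaviour: leading and trailing gap runs cost nothing, which is
the right mode for comparing receptor proteins whose domain counts differ.
A gap run of length g costs ``gap_open + (g-1) * gap_extend``.

Multiple alignment is progressive: a 3-mer-identity guide tree (built with
the package's neighbor-joining), then profile-profile merges scored by the
average pairwise substitution score, with "once a gap, always a gap".

Traceback is deterministic: ties resolve diagonal > up > left, and among
co-optimal end points the corner is preferred, then the shortest trailing
gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigError, ScariError

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_CHAR_TO_IDX = {c: i for i, c in enumerate(ALPHABET)}
_NEG = -1e30


def _blosum62_matrix() -> np.ndarray:
    """Blosum62 restricted to the 20 aa + X, as a dense integer table."""
    bl = substitution_matrices.load("BLOSUM62")
    n = len(ALPHABET)
    m = np.zeros((n, n), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            m[i, j] = bl[a, b]
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix + affine gap penalties.

    Penalties are nonnegative magnitudes (they are subtracted). With
    ``x_score_zero`` the ambiguous residue X scores 0 against everything
    instead of using the matrix's X row.
    """

    matrix: np.ndarray
    gap_open: int = 12
    gap_extend: int = 3
    free_end_gaps: bool = True
    alphabet: str = ALPHABET
    x_score_zero: bool = False

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be nonnegative")
        if self.matrix.shape != (len(self.alphabet), len(self.alphabet)):
            raise ConfigError("matrix shape does not match alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ConfigError("substitution matrix must be symmetric")

    @classmethod
    def blosum62(
        cls,
        gap_open: int = 12,
        gap_extend: int = 3,
        free_end_gaps: bool = True,
        x_score_zero: bool = False,
    ) -> "ScoringScheme":
        m = _blosum62_matrix()
        if x_score_zero:
            m = m.copy()
            xi = ALPHABET.index("X")
            m[xi, :] = 0.0
            m[:, xi] = 0.0
        return cls(
            matrix=m,
            gap_open=gap_open,
            gap_extend=gap_extend,
            free_end_gaps=free_end_gaps,
            x_score_zero=x_score_zero,
        )

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.array([_CHAR_TO_IDX[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            raise ScariError(f"residue {exc.args[0]!r} has no matrix entry") from exc

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[_CHAR_TO_IDX[a], _CHAR_TO_IDX[b]])


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped rows over named taxa; de-gapping row i gives back
    the i-th input sequence."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ScariError("taxa/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ScariError("alignment rows must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ScariError("duplicate taxon names")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degap(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def to_fasta(self) -> str:
        from .io import write_fasta

        return write_fasta(list(zip(self.taxa, self.rows)))

    def subsample_columns(self, idx: np.ndarray) -> "MultipleAlignment":
        rows = tuple("".join(r[j] for j in idx) for r in self.rows)
        return MultipleAlignment(taxa=self.taxa, rows=rows)


@dataclass(frozen=True)
class PairwiseAlignment:
    score: float
    aligned_a: str
    aligned_b: str


# ---------------------------------------------------------------------------
# core DP engine (shared by pairwise and profile-profile alignment)


def _align_core(S: np.ndarray, gap_open: float, gap_extend: float, free: bool):
    """Gotoh DP over a precomputed (n x m) column-score matrix.

    Returns (score, moves) with moves a list of 'D' (consume both), 'U'
    (consume a row of S's first axis against a gap), 'L' (the other way),
    ordered from the start of the alignment.
    """
    n, m = S.shape
    op, ex = float(gap_open), float(gap_extend)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b: 'U'
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a: 'L'
    M[0, 0] = 0.0
    i_idx = np.arange(1, n + 1, dtype=np.float64)
    j_idx = np.arange(1, m + 1, dtype=np.float64)
    X[1:, 0] = 0.0 if free else -(op + (i_idx - 1) * ex)
    Y[0, 1:] = 0.0 if free else -(op + (j_idx - 1) * ex)
    jext = (j_idx - 1) * ex
    for i in range(1, n + 1):
        M[i, 1:] = S[i - 1, :] + np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]]
        )
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] - op, X[i - 1, 1:] - ex, Y[i - 1, 1:] - op]
        )
        # Y within-row recurrence via running max:
        # Y[i,j] = max_{k<j} (max(M,X)[i,k] + ex*k) - op - ex*(j-1)
        Z = np.maximum(M[i, :], X[i, :])
        run = np.maximum.accumulate(Z + np.arange(m + 1) * ex)
        Y[i, 1:] = run[:-1] - op - jext

    best_all = np.maximum.reduce([M, X, Y])
    if free:
        score = max(best_all[:, m].max(), best_all[n, :].max())
    else:
        score = best_all[n, m]

    moves = _traceback(M, X, Y, S, op, ex, free, score)
    return score, moves


def _traceback(M, X, Y, S, op, ex, free, score):
    n, m = S.shape
    tol = 1e-6

    def close(a, b):
        return abs(a - b) <= tol

    # end cell: prefer the corner, then the last column bottom-up (shortest
    # trailing 'U' run), then the last row right-to-left (shortest 'L' run).
    tail: list[str] = []
    ei, ej = n, m
    if free and not close(max(M[n, m], X[n, m], Y[n, m]), score):
        found = False
        for i in range(n - 1, -1, -1):
            if close(max(M[i, m], X[i, m], Y[i, m]), score):
                ei, ej = i, m
                tail = ["U"] * (n - i)
                found = True
                break
        if not found:
            for j in range(m - 1, -1, -1):
                if close(max(M[n, j], X[n, j], Y[n, j]), score):
                    ei, ej = n, j
                    tail = ["L"] * (m - j)
                    break

    i, j = ei, ej
    state = "M"
    target = max(M[i, j], X[i, j], Y[i, j])
    for s, mat in (("M", M), ("X", X), ("Y", Y)):  # diagonal > up > left
        if close(mat[i, j], target):
            state = s
            break
    moves: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            moves.extend(["L"] * j)
            break
        if j == 0:
            if state == "M":  # only reachable at (0,0)
                break
            moves.extend(["U"] * i)
            break
        if state == "M":
            v = M[i, j] - S[i - 1, j - 1]
            moves.append("D")
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("X", X), ("Y", Y)):
                if close(mat[i, j], v):
                    state = s
                    break
        elif state == "X":
            v = X[i, j]
            moves.append("U")
            if close(M[i - 1, j] - op, v):
                state = "M"
            elif close(X[i - 1, j] - ex, v):
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            v = Y[i, j]
            moves.append("L")
            zi = max(M[i, j - 1], X[i, j - 1])
            if close(zi - op, v):
                state = "M" if close(M[i, j - 1], zi) else "X"
            else:
                state = "Y"
            j -= 1
    moves.reverse()
    moves.extend(tail)
    return moves


# ---------------------------------------------------------------------------
# pairwise


def align_pair(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global (optionally free-end-gap) alignment of two proteins.

    Returns the integer optimal score and one optimal alignment, chosen
    deterministically (diagonal > up > left).
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    if not a or not b:
        raise ScariError("sequences must be non-empty")
    ea, eb = scheme.encode(a), scheme.encode(b)
    S = scheme.matrix[np.ix_(ea, eb)]
    score, moves = _align_core(S, scheme.gap_open, scheme.gap_extend, scheme.free_end_gaps)
    ra, rb = [], []
    i = j = 0
    for mv in moves:
        if mv == "D":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif mv == "U":
            ra.append(a[i]); rb.append("-"); i += 1
        else:
            ra.append("-"); rb.append(b[j]); j += 1
    return PairwiseAlignment(score=float(score), aligned_a="".join(ra), aligned_b="".join(rb))


# ---------------------------------------------------------------------------
# progressive multiple alignment


class _Profile:
    """Rows + per-column residue counts for profile-profile alignment."""

    __slots__ = ("names", "rows", "counts")

    def __init__(self, names: list[str], rows: list[str], counts: np.ndarray):
        self.names = names
        self.rows = rows
        self.counts = counts  # (L, |alphabet|), gaps excluded

    @classmethod
    def from_seq(cls, name: str, seq: str, scheme: ScoringScheme) -> "_Profile":
        enc = scheme.encode(seq)
        counts = np.zeros((len(seq), len(scheme.alphabet)))
        counts[np.arange(len(seq)), enc] = 1.0
        return cls([name], [seq], counts)

    @property
    def n_seqs(self) -> int:
        return len(self.rows)


def _merge_profiles(p: _Profile, q: _Profile, scheme: ScoringScheme) -> _Profile:
    # average pairwise substitution score between columns; gap pairs score 0
    S = (p.counts @ scheme.matrix @ q.counts.T) / (p.n_seqs * q.n_seqs)
    _, moves = _align_core(S, scheme.gap_open, scheme.gap_extend, scheme.free_end_gaps)
    a_alph = len(scheme.alphabet)
    new_rows_p = [[] for _ in p.rows]
    new_rows_q = [[] for _ in q.rows]
    new_counts = np.zeros((len(moves), a_alph))
    i = j = 0
    for col, mv in enumerate(moves):
        if mv in ("D", "U"):
            for r, out in zip(p.rows, new_rows_p):
                out.append(r[i])
            new_counts[col] += p.counts[i]
            i += 1
        else:
            for out in new_rows_p:
                out.append("-")
        if mv in ("D", "L"):
            for r, out in zip(q.rows, new_rows_q):
                out.append(r[j])
            new_counts[col] += q.counts[j]
            j += 1
        else:
            for out in new_rows_q:
                out.append("-")
    rows = ["".join(r) for r in new_rows_p] + ["".join(r) for r in new_rows_q]
    return _Profile(p.names + q.names, rows, new_counts)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 minus the shared-k-mer fraction (multiset, over the smaller count)."""
    from collections import Counter

    ka = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    kb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    denom = min(sum(ka.values()), sum(kb.values()))
    if denom == 0:
        return 1.0
    shared = sum(min(ka[w], kb[w]) for w in ka)
    return 1.0 - shared / denom


def progressive_msa(
    seqs: list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    k: int = 3,
) -> MultipleAlignment:
    """Progressive multiple alignment in guide-tree order.

    The guide tree comes from neighbor-joining on 3-mer-identity distances;
    profiles are merged postorder with sum-of-pairs column scoring. Gaps,
    once introduced, are never removed ("once a gap, always a gap").
    """
    if scheme is None:
        scheme = ScoringScheme.blosum62()
    if not seqs:
        raise ScariError("no sequences to align")
    names = [n for n, _ in seqs]
    if len(set(names)) != len(names):
        raise ScariError("duplicate sequence names")
    if len(seqs) == 1:
        return MultipleAlignment(taxa=(names[0],), rows=(seqs[0][1],))
    by_name = dict(seqs)
    if len(seqs) == 2:
        pw = align_pair(seqs[0][1], seqs[1][1], scheme)
        return MultipleAlignment(
            taxa=tuple(names), rows=(pw.aligned_a, pw.aligned_b)
        )

    from .phylogeny import DistanceMatrix, neighbor_joining

    nn = len(seqs)
    d = np.zeros((nn, nn))
    for i in range(nn):
        for j in range(i + 1, nn):
            d[i, j] = d[j, i] = _kmer_distance(seqs[i][1], seqs[j][1], k)
    guide = neighbor_joining(DistanceMatrix(taxa=tuple(names), d=d))

    def build(node) -> _Profile:
        if node.is_tip():
            return _Profile.from_seq(node.name, by_name[node.name], scheme)
        children = [build(c) for c in node.children]
        prof = children[0]
        for c in children[1:]:
            prof = _merge_profiles(prof, c, scheme)
        return prof

    prof = build(guide.tree)
    order = {n: i for i, n in enumerate(prof.names)}
    rows = tuple(prof.rows[order[n]] for n in names)
    return MultipleAlignment(taxa=tuple(names), rows=rows)
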