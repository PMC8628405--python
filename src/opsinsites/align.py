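"""Global protein alignment with affine gap costs and a progressive MSA.

The pairwise aligner is a Needleman-Wunsch-Gotoh dynamic program over three
states (match, gap-in-query, gap-in-reference).  A gap of k columns costs
``gap_open + k * gap_extend`` (opening and first extension both charged), and
terminal gaps are penalized like internal ones: the alignment is truly global
end-to-end, which is what reference-numbering site mapping requires.

Tie-breaking in the traceback is deterministic: at equal score a diagonal step
is preferred, then a gap in the query, then a gap in the reference.

``X`` is accepted as a wildcard that scores 0 against everything; any other
non-alphabet character is rejected with the offending symbol and position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .errors import AlignmentError, InvalidSequenceError

#: Canonical 20-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Wildcard residue (ambiguous translation product); scores 0 vs anything.
WILDCARD = "X"
GAP = "-"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
# Extended symbol set used for profile columns: 20 aa + X + gap.
_EXT_SYMBOLS = AMINO_ACIDS + WILDCARD + GAP
_EXT_INDEX = {a: i for i, a in enumerate(_EXT_SYMBOLS)}


def validate_protein(seq: str, name: str = "sequence") -> None:
    """Raise :class:`InvalidSequenceError` if *seq* has a symbol outside the
    20-letter alphabet (``X`` tolerated)."""
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_INDEX and ch != WILDCARD:
            raise InvalidSequenceError(
                f"{name}: illegal residue {ch!r} at position {pos}"
            )


class SubstitutionMatrix:
    """Symmetric amino-acid scoring table over the 20-letter alphabet.

    Diagonal dominance is *not* assumed anywhere: only symmetry and
    completeness over all 400 ordered pairs are required.
    """

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (20, 20):
            raise ValueError("scores must be a 20x20 array over AMINO_ACIDS")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.scores = scores
        self.name = name
        # Extended 22x22 table: X and gap rows/columns are 0.
        ext = np.zeros((22, 22), dtype=np.float64)
        ext[:20, :20] = scores
        self._ext = ext

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """The BLOSUM62 table (loaded from Biopython's packaged data)."""
        raw = substitution_matrices.load("BLOSUM62")
        m = np.empty((20, 20), dtype=np.float64)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = raw[a, b]
        return cls(m, name="BLOSUM62")

    def score(self, a: str, b: str) -> float:
        """Score of an aligned residue pair; X scores 0 against anything."""
        if a == WILDCARD or b == WILDCARD:
            return 0.0
        return float(self.scores[_AA_INDEX[a], _AA_INDEX[b]])

    def pair_matrix(self, a: str, b: str) -> np.ndarray:
        """Cross-score matrix S[i, j] = score(a[i], b[j])."""
        ia = np.array([_EXT_INDEX[c] for c in a], dtype=np.intp)
        ib = np.array([_EXT_INDEX[c] for c in b], dtype=np.intp)
        return self._ext[np.ix_(ia, ib)] if len(ia) and len(ib) else np.zeros(
            (len(ia), len(ib))
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of one query against one reference."""

    query_id: str
    ref_id: str
    aligned_query: str
    aligned_ref: str
    score: float

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_ref):
            raise AlignmentError("aligned strings must have equal length")
        for qa, ra in zip(self.aligned_query, self.aligned_ref):
            if qa == GAP and ra == GAP:
                raise AlignmentError("gap-in-both column in alignment")

    @property
    def query(self) -> str:
        return self.aligned_query.replace(GAP, "")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")


@dataclass
class MSA:
    """A multiple sequence alignment: ordered (id, gapped row) pairs."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate ids in MSA")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("MSA rows have unequal lengths")
        if self.rows and self.column_count:
            for j in range(self.column_count):
                if all(r[j] == GAP for _, r in self.rows):
                    raise AlignmentError(f"all-gap column at index {j}")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        for i, r in self.rows:
            if i == seq_id:
                return r
        raise KeyError(seq_id)

    def subset(self, keep_ids: Sequence[str]) -> "MSA":
        """Row subset in the given order; columns untouched."""
        keep = list(keep_ids)
        have = dict(self.rows)
        missing = [k for k in keep if k not in have]
        if missing:
            raise KeyError(f"ids not in MSA: {missing}")
        return MSA(rows=[(k, have[k]) for k in keep])


@njit(cache=True)
def _affine_dp(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    """Three-state Gotoh DP over a precomputed cross-score matrix.

    Returns (score, ops) where ops[k] is 0 for a diagonal column, 1 for a
    gap-in-first-sequence column and 2 for a gap-in-second-sequence column,
    in alignment order.  Tie order everywhere: 0 > 1 > 2.
    """
    n, m = S.shape
    NEG = -1e300
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        X[0, j] = -(gap_open + j * gap_extend)
        pX[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        Y[i, 0] = -(gap_open + i * gap_extend)
        pY[i, 0] = 2 if i > 1 else 0
    reopen = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            pM[i, j] = p

            best = M[i, j - 1] - reopen
            p = 0
            if X[i, j - 1] - gap_extend > best:
                best = X[i, j - 1] - gap_extend
                p = 1
            if Y[i, j - 1] - reopen > best:
                best = Y[i, j - 1] - reopen
                p = 2
            X[i, j] = best
            pX[i, j] = p

            best = M[i - 1, j] - reopen
            p = 0
            if X[i - 1, j] - reopen > best:
                best = X[i - 1, j] - reopen
                p = 1
            if Y[i - 1, j] - gap_extend > best:
                best = Y[i - 1, j] - gap_extend
                p = 2
            Y[i, j] = best
            pY[i, j] = p

    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    ops = np.empty(n + m, np.int8)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        ops[k] = state
        if state == 0:
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            j -= 1
        else:
            state = pY[i, j]
            i -= 1
        k += 1
    return score, ops[:k][::-1].copy()


def alignment_score(
    aligned_a: str,
    aligned_b: str,
    sm: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Affine-gap objective evaluated directly on a finished alignment.

    Substitution scores are summed over residue-residue columns; every maximal
    run of k gap columns in either row costs ``gap_open + k * gap_extend``.
    Kept deliberately independent of the DP so it can audit its output.
    """
    if len(aligned_a) != len(aligned_b):
        raise AlignmentError("aligned strings must have equal length")
    total = 0.0
    for x, y in zip(aligned_a, aligned_b):
        if x != GAP and y != GAP:
            total += sm.score(x, y)
    for row in (aligned_a, aligned_b):
        run = 0
        for ch in row:
            if ch == GAP:
                run += 1
            elif run:
                total -= gap_open + run * gap_extend
                run = 0
        if run:
            total -= gap_open + run * gap_extend
    return total


def exhaustive_best_score(
    a: str,
    b: str,
    sm: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global affine-gap score by explicit enumeration.

    Walks the full tree of global alignments (no memoization, no shared
    recurrences with the DP) and scores each finished alignment with
    :func:`alignment_score`.  Exponential; intended for sequences of length
    <= ~7 where it serves as the reference oracle.
    """
    best = -math.inf
    stack = [(0, 0, "", "")]
    while stack:
        i, j, ra, rb = stack.pop()
        if i == len(a) and j == len(b):
            s = alignment_score(ra, rb, sm, gap_open, gap_extend)
            if s > best:
                best = s
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, ra + a[i], rb + b[j]))
        if j < len(b):
            stack.append((i, j + 1, ra + GAP, rb + b[j]))
        if i < len(a):
            stack.append((i + 1, j, ra + a[i], rb + GAP))
    return best


def nw_align(
    query: str,
    ref: str,
    sm: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    ref_id: str = "ref",
) -> PairwiseAlignment:
    """Optimal global alignment of *query* against *ref*.

    A k-column gap costs ``gap_open + k * gap_extend``; defaults 11/1 with
    BLOSUM62, the standard protein setting.
    """
    if sm is None:
        sm = SubstitutionMatrix.blosum62()
    if not query and not ref:
        raise AlignmentError("both sequences are empty")
    if gap_extend < 0 or gap_open < gap_extend:
        raise AlignmentError("require gap_open >= gap_extend >= 0")
    validate_protein(query, "query")
    validate_protein(ref, "ref")
    S = sm.pair_matrix(query, ref)
    score, ops = _affine_dp(S, float(gap_open), float(gap_extend))
    qa, ra = [], []
    i = j = 0
    for op in ops:
        if op == 0:
            qa.append(query[i])
            ra.append(ref[j])
            i += 1
            j += 1
        elif op == 1:
            qa.append(GAP)
            ra.append(ref[j])
            j += 1
        else:
            qa.append(query[i])
            ra.append(GAP)
            i += 1
    return PairwiseAlignment(
        query_id=query_id,
        ref_id=ref_id,
        aligned_query="".join(qa),
        aligned_ref="".join(ra),
        score=float(score),
    )


def pdistance(row_a: str, row_b: str) -> float:
    """Fraction of mismatching columns among columns non-gap in both rows."""
    if len(row_a) != len(row_b):
        raise AlignmentError("rows must have equal length")
    shared = 0
    diff = 0
    for x, y in zip(row_a, row_b):
        if x != GAP and y != GAP:
            shared += 1
            if x != y:
                diff += 1
    if shared == 0:
        raise AlignmentError("no shared non-gap columns")
    return diff / shared


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _profile_counts(rows: list[str]) -> np.ndarray:
    out = np.zeros((len(rows[0]), 22), dtype=np.float64)
    for r in rows:
        for j, ch in enumerate(r):
            out[j, _EXT_INDEX[ch]] += 1.0
    return out


def _merge_profiles(
    prof_a: list[tuple[str, str]],
    prof_b: list[tuple[str, str]],
    sm: SubstitutionMatrix,
    gap_open: float,
    gap_extend: float,
) -> list[tuple[str, str]]:
    """Profile-profile alignment: column score is the mean pairwise residue
    score between the two profiles' columns (gaps and X scoring 0).  Existing
    gaps are never reopened (once-a-gap-always-a-gap): new gaps are inserted
    as whole columns into one side."""
    rows_a = [r for _, r in prof_a]
    rows_b = [r for _, r in prof_b]
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    S = (ca @ sm._ext @ cb.T) / (len(rows_a) * len(rows_b))
    _, ops = _affine_dp(S, float(gap_open), float(gap_extend))
    new_a = [[] for _ in rows_a]
    new_b = [[] for _ in rows_b]
    i = j = 0
    for op in ops:
        take_a = op in (0, 2)
        take_b = op in (0, 1)
        for k, r in enumerate(rows_a):
            new_a[k].append(r[i] if take_a else GAP)
        for k, r in enumerate(rows_b):
            new_b[k].append(r[j] if take_b else GAP)
        if take_a:
            i += 1
        if take_b:
            j += 1
    merged = [(sid, "".join(chars)) for (sid, _), chars in zip(prof_a, new_a)]
    merged += [(sid, "".join(chars)) for (sid, _), chars in zip(prof_b, new_b)]
    return merged


def progressive_msa(
    seqs: Sequence[tuple[str, str]],
    sm: SubstitutionMatrix | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> MSA:
    """Progressive multiple alignment guided by an NJ tree on p-distances.

    All pairs are first aligned with :func:`nw_align`; the p-distances of
    those alignments feed neighbor joining, and profiles are merged following
    the guide tree in post-order with profile-profile alignment.
    """
    from .phylo import _nj_core  # local import to avoid a cycle

    if sm is None:
        sm = SubstitutionMatrix.blosum62()
    seqs = list(seqs)
    if len(seqs) < 2:
        raise AlignmentError("progressive_msa requires >= 2 sequences")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AlignmentError(f"duplicate ids: {dupes}")
    for sid, s in seqs:
        validate_protein(s, sid)
    if len(seqs) == 2:
        a = nw_align(
            seqs[0][1], seqs[1][1], sm, gap_open, gap_extend,
            query_id=ids[0], ref_id=ids[1],
        )
        return MSA(rows=[(ids[0], a.aligned_query), (ids[1], a.aligned_ref)])

    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = nw_align(seqs[i][1], seqs[j][1], sm, gap_open, gap_extend)
            D[i, j] = D[j, i] = pdistance(a.aligned_query, a.aligned_ref)
    edges, center, _ = _nj_core(ids, D)

    adj: dict[int, list[int]] = {}
    for u, v, _len in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def build(node: int, parent: int) -> list[tuple[str, str]]:
        kids = [k for k in adj[node] if k != parent]
        if not kids:  # leaf; leaf ids are 0..n-1 in input order
            return [(ids[node], seqs[node][1])]
        prof = build(kids[0], node)
        for k in kids[1:]:
            prof = _merge_profiles(prof, build(k, node), sm, gap_open, gap_extend)
        return prof

    merged = build(center, -1)
    order = {sid: k for k, sid in enumerate(ids)}
    merged.sort(key=lambda row: order[row[0]])
    return MSA(rows=merged)


def sum_of_pairs_score(
    msa: MSA, sm: SubstitutionMatrix, gap_open: float, gap_extend: float
) -> float:
    """Sum over all row pairs of the affine objective on the induced pairwise
    alignments (gap-in-both columns dropped per pair)."""
    total = 0.0
    rows = [r for _, r in msa.rows]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = [], []
            for x, y in zip(rows[i], rows[j]):
                if x == GAP and y == GAP:
                    continue
                a.append(x)
                b.append(y)
            total += alignment_score("".join(a), "".join(b), sm, gap_open, gap_extend)
    return total
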