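"""Family alignment: build or ingest a multiple alignment of LRR domains.

The repeats-by-positions grid is defined on one *reference* protein; every
other homolog contributes one residue (or gap) per grid cell through the
columns of a multiple sequence alignment.  This module provides

* a deterministic progressive aligner (pairwise global Needleman-Wunsch /
  Gotoh with affine gaps, neighbor-joining guide tree on pairwise identity
  distances, profile-profile merges in tree order), and
* a validated pass-through for pre-aligned input, and
* the mapping from reference grid cells to alignment columns.

Gap cost model: a gap run of length g costs ``gap_open + (g - 1) * gap_extend``
(defaults 10 and 0.5).  Terminal gaps are penalized like internal ones.
Profile columns are scored by the average substitution score over all
residue pairs drawn one from each column; pairs involving a gap contribute 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .scoring import GAP_CHARS, SubstitutionMatrix

__all__ = [
    "MASKED",
    "FamilyAlignment",
    "align_pair",
    "align_family",
    "load_alignment",
    "map_cells_to_columns",
]

#: Sentinel alignment column for grid cells with no residue (HOLEs).
MASKED = -1

_NEG = -1e30


@dataclass
class FamilyAlignment:
    """Two or more aligned homologous sequences plus the designated
    reference whose repeats define the grid."""

    records: List[Tuple[str, str]]
    reference_id: str

    def __post_init__(self):
        if len(self.records) < 2:
            raise ValueError("a family alignment needs at least 2 sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            bad = sorted({rid for rid, seq in self.records})
            raise ValueError(f"aligned sequences have unequal lengths: {bad}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.reference_id not in ids:
            raise ValueError(f"reference id {self.reference_id!r} not among records")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def aligned(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return "".join(c for c in self.aligned(rid) if c not in GAP_CHARS)


# ---------------------------------------------------------------------------
# profile-profile Gotoh alignment
# ---------------------------------------------------------------------------


def _column_counts(profile: Sequence[Tuple[str, str]], matrix: SubstitutionMatrix):
    """Per-column residue counts over the matrix alphabet (gaps dropped)."""
    L = len(profile[0][1])
    counts = np.zeros((L, len(matrix.alphabet)), dtype=float)
    for _, seq in profile:
        for i, c in enumerate(seq):
            if c in GAP_CHARS:
                continue
            counts[i, matrix._idx(c)] += 1.0
    return counts


def _profile_scores(pa, pb, matrix: SubstitutionMatrix) -> np.ndarray:
    """Column-vs-column score matrix: average pair score, gap pairs -> 0."""
    ca = _column_counts(pa, matrix)
    cb = _column_counts(pb, matrix)
    na, nb = len(pa), len(pb)
    return (ca @ matrix.entries @ cb.T) / float(na * nb)


def _gotoh_fill(S: np.ndarray, gap_open: float, gap_extend: float):
    """Fill the three Gotoh state matrices row-by-row (vectorized columns).

    M[i, j]: columns i of A and j of B aligned (1-based); E: gap in A
    (consuming B columns); F: gap in B.  E and F may follow each other, so
    the optimum equals the brute-force optimum over all alignments.
    """
    L1, L2 = S.shape
    M = np.full((L1 + 1, L2 + 1), _NEG)
    E = np.full((L1 + 1, L2 + 1), _NEG)
    F = np.full((L1 + 1, L2 + 1), _NEG)
    M[0, 0] = 0.0
    j = np.arange(1, L2 + 1)
    E[0, 1:] = -(gap_open + (j - 1) * gap_extend)
    i = np.arange(1, L1 + 1)
    F[1:, 0] = -(gap_open + (i - 1) * gap_extend)
    ext = gap_extend
    for r in range(1, L1 + 1):
        prevM, prevE, prevF = M[r - 1], E[r - 1], F[r - 1]
        M[r, 1:] = S[r - 1] + np.maximum.reduce([prevM[:-1], prevE[:-1], prevF[:-1]])
        F[r, 1:] = np.maximum.reduce(
            [prevM[1:] - gap_open, prevF[1:] - ext, prevE[1:] - gap_open]
        )
        # E depends on M/F of the same row at earlier columns:
        # E[r, j] = max_{k<j} (base[k] - gap_open - (j-1-k) * ext)
        base = np.maximum(M[r], F[r])
        c = base + ext * np.arange(L2 + 1)
        running = np.maximum.accumulate(c[:-1])
        E[r, 1:] = np.maximum(
            E[r, 1:], running - gap_open - ext * np.arange(L2)
        )
    return M, E, F


def _gotoh_traceback(M, E, F, S, gap_open, gap_extend):
    """Recover one optimal alignment as a list of (i, j) column pairs with
    -1 for gaps; deterministic preference M > E > F on ties."""
    L1, L2 = S.shape
    i, j = L1, L2
    tol = 1e-6
    state, best = "M", M[i, j]
    if E[i, j] > best + tol:
        state, best = "E", E[i, j]
    if F[i, j] > best + tol:
        state, best = "F", F[i, j]
    tabs = {"M": M, "E": E, "F": F}
    path = []
    while i > 0 or j > 0:
        if state == "M":
            # M[i, j] = S[i-1, j-1] + max(M, E, F)[i-1, j-1]
            path.append((i - 1, j - 1))
            target = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            opts = [("M", M[i, j]), ("E", E[i, j]), ("F", F[i, j])]
        elif state == "E":
            # E[i, j] from M/F[i, j-1] - open or E[i, j-1] - extend
            path.append((-1, j - 1))
            target = E[i, j]
            j -= 1
            opts = [("M", M[i, j] - gap_open), ("E", E[i, j] - gap_extend),
                    ("F", F[i, j] - gap_open)]
        else:
            # F[i, j] from M/E[i-1, j] - open or F[i-1, j] - extend
            path.append((i - 1, -1))
            target = F[i, j]
            i -= 1
            opts = [("M", M[i, j] - gap_open), ("F", F[i, j] - gap_extend),
                    ("E", E[i, j] - gap_open)]
        if i == 0 and j == 0:
            break
        for nxt, val in opts:
            if abs(val - target) <= tol:
                state = nxt
                break
        else:  # pragma: no cover - fill and traceback share one recurrence
            raise AssertionError("inconsistent traceback")
    path.reverse()
    return path


def _merge_profiles(pa, pb, matrix, gap_open, gap_extend):
    """Align two profiles and return (merged profile, score)."""
    S = _profile_scores(pa, pb, matrix)
    M, E, F = _gotoh_fill(S, gap_open, gap_extend)
    score = float(max(M[-1, -1], E[-1, -1], F[-1, -1]))
    path = _gotoh_traceback(M, E, F, S, gap_open, gap_extend)
    rows_a = ["" for _ in pa]
    rows_b = ["" for _ in pb]
    for ia, ib in path:
        for k, (_, seq) in enumerate(pa):
            rows_a[k] += seq[ia] if ia >= 0 else "-"
        for k, (_, seq) in enumerate(pb):
            rows_b[k] += seq[ib] if ib >= 0 else "-"
    merged = [(rid, rows_a[k]) for k, (rid, _) in enumerate(pa)]
    merged += [(rid, rows_b[k]) for k, (rid, _) in enumerate(pb)]
    return merged, score


def align_pair(
    a: str,
    b: str,
    matrix: Optional[SubstitutionMatrix] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
):
    """Optimal global alignment of two sequences.

    Returns ``(aligned_a, aligned_b, score)``; the score is the exhaustive
    dynamic-programming optimum under the module's affine gap model.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    matrix = matrix or SubstitutionMatrix.load("BLOSUM62")
    merged, score = _merge_profiles([("a", a)], [("b", b)], matrix, gap_open, gap_extend)
    return merged[0][1], merged[1][1], score


def _identity_distance(aligned_a: str, aligned_b: str) -> float:
    """1 - fractional identity over columns where both rows have residues."""
    both = [(x, y) for x, y in zip(aligned_a, aligned_b)
            if x not in GAP_CHARS and y not in GAP_CHARS]
    if not both:
        return 1.0
    ident = sum(1 for x, y in both if x == y)
    return 1.0 - ident / len(both)


def _guide_tree_order(ids: Sequence[str], dist: np.ndarray):
    """Neighbor-joining guide tree; returns a nested-tuple merge plan.

    Ids are processed in lexicographic order throughout so the plan (and
    hence the final alignment) is independent of input order.
    """
    if len(ids) == 2:
        return (ids[0], ids[1])
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(dist, ids))

    def plan(node):
        if node.is_tip():
            return node.name
        sub = [plan(ch) for ch in node.children]
        # deterministic child order: by smallest leaf name under each child
        def first_leaf(p):
            return p if isinstance(p, str) else first_leaf(p[0])
        sub.sort(key=first_leaf)
        out = sub[0]
        for nxt in sub[1:]:
            out = (out, nxt)
        return out

    return plan(tree)


def align_family(
    sequences: Sequence[Tuple[str, str]],
    reference_id: Optional[str] = None,
    matrix: Optional[SubstitutionMatrix] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> FamilyAlignment:
    """Progressive multiple alignment of two or more unaligned sequences.

    Pairwise identity distances feed a neighbor-joining guide tree; profiles
    are merged bottom-up in tree order.  All tie-breaking is lexicographic
    by sequence id, so permuting the input order yields the same alignment
    (records are reported in input order).
    """
    if len(sequences) < 2:
        raise ValueError("align_family needs at least 2 sequences")
    ids = [rid for rid, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    for rid, seq in sequences:
        if not seq:
            raise ValueError(f"empty sequence {rid!r}")
        bad = set(seq.upper()) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"non-residue characters in {rid!r}: {sorted(bad)}")
    matrix = matrix or SubstitutionMatrix.load("BLOSUM62")
    by_id = {rid: seq.upper() for rid, seq in sequences}
    order = sorted(by_id)  # lexicographic processing order

    # pairwise identity distances from optimal pairwise alignments
    n = len(order)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aa, bb, _ = align_pair(by_id[order[i]], by_id[order[j]],
                                   matrix, gap_open, gap_extend)
            dist[i, j] = dist[j, i] = _identity_distance(aa, bb)

    plan = _guide_tree_order(order, dist)

    def build(node):
        if isinstance(node, str):
            return [(node, by_id[node])]
        pa = build(node[0])
        pb = build(node[1])
        merged, _ = _merge_profiles(pa, pb, matrix, gap_open, gap_extend)
        return merged

    profile = {rid: seq for rid, seq in build(plan)}
    records = [(rid, profile[rid]) for rid in ids]  # restore input order
    ref = reference_id if reference_id is not None else ids[0]
    return FamilyAlignment(records=records, reference_id=ref)


def load_alignment(
    records: Sequence[Tuple[str, str]],
    reference_id: Optional[str] = None,
) -> FamilyAlignment:
    """Validated pass-through for pre-aligned records (aligned FASTA or
    Clustal input); the alignment step is skipped."""
    if len(records) < 2:
        raise ValueError("a family alignment needs at least 2 sequences")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        bad = sorted(rid for rid, seq in records
                     if len(seq) != len(records[0][1]))
        raise ValueError(f"ragged alignment; offending ids: {bad}")
    records = [(rid, seq.upper()) for rid, seq in records]
    ref = reference_id if reference_id is not None else records[0][0]
    return FamilyAlignment(records=list(records), reference_id=ref)


def map_cells_to_columns(annotation, alignment: FamilyAlignment) -> np.ndarray:
    """Map each reference grid cell to its alignment column.

    Returns an integer matrix over all motif positions: entry [r, p-1] is
    the alignment column holding the reference residue of repeat r+1, motif
    position p, or MASKED for HOLE cells.  Downstream callers slice the
    variable columns out of this full map.
    """
    ref_row = alignment.aligned(alignment.reference_id)
    ref_seq = alignment.ungapped(alignment.reference_id)
    seq_to_col = [i for i, c in enumerate(ref_row) if c not in GAP_CHARS]
    if not annotation.repeats:
        return np.full((0, 0), MASKED, dtype=int)
    n_pos = max(max(rep.cells) for rep in annotation.repeats)
    out = np.full((len(annotation.repeats), n_pos), MASKED, dtype=int)
    for r, rep in enumerate(annotation.repeats):
        for pos, idx in rep.cells.items():
            if idx is None:
                continue
            if idx >= len(ref_seq):
                raise ValueError(
                    f"annotation index {idx + 1} beyond reference length {len(ref_seq)}"
                )
            out[r, pos - 1] = seq_to_col[idx]
    return out
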