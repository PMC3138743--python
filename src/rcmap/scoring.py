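"""Per-cell conservation scores across a family of homologs.

Two score stages are computed for every grid cell (one solvent-exposed
variable position of one repeat):

* raw mode -- the plain average pairwise substitution-matrix score over all
  unordered pairs of family members at that cell;
* weighted mode -- the same average over normalized pair scores
  ``w(a, b) = clip((S(a,b) - S_min) / (min(S(a,a), S(b,b)) - S_min), 0, 1)``,
  which maps residue identity to 1 and the most dissimilar substitution in
  the matrix to 0, giving the red-to-blue heat-map scale fixed endpoints.

The default matrix is BLOSUM62; BLOSUM65 and the other members of the BLOSUM
family are available by name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "GAP_CHARS",
    "SubstitutionMatrix",
    "ConservationGrid",
    "substitution_score",
    "normalized_pair_score",
    "cell_conservation",
    "score_grid",
]

GAP_CHARS = frozenset("-.")
_STANDARD = "ACDEFGHIKLMNPQRSTVWY"


class SubstitutionMatrix:
    """A symmetric integer substitution matrix over the residue alphabet.

    ``global_min`` is the minimum entry over the 20 standard residues; it is
    the divergence floor of the normalized pair score.
    """

    def __init__(self, matrix_id: str, alphabet: str, entries: np.ndarray):
        entries = np.asarray(entries, dtype=float)
        if entries.shape != (len(alphabet), len(alphabet)):
            raise ValueError("entries shape does not match alphabet")
        if not np.allclose(entries, entries.T):
            raise ValueError(f"substitution matrix {matrix_id} is not symmetric")
        self.matrix_id = matrix_id
        self.alphabet = alphabet
        self.entries = entries
        self._index = {c: i for i, c in enumerate(alphabet)}
        std = [self._index[c] for c in _STANDARD if c in self._index]
        if len(std) < 20:
            raise ValueError(f"matrix {matrix_id} does not cover the 20 standard residues")
        sub = entries[np.ix_(std, std)]
        self.global_min = float(sub.min())
        diag = np.diag(sub)
        if (sub > diag[:, None]).any():
            warnings.warn(
                f"matrix {matrix_id}: some off-diagonal entries exceed the "
                "diagonal; identity may not be the maximal score"
            )

    @classmethod
    def load(cls, matrix_id: str = "BLOSUM62") -> "SubstitutionMatrix":
        """Load a named matrix (biopython's set, then biotite's database)."""
        name = matrix_id.upper()
        try:
            from Bio.Align import substitution_matrices

            arr = substitution_matrices.load(name)
            return cls(name, str(arr.alphabet), np.asarray(arr))
        except FileNotFoundError:
            pass
        from biotite.sequence import ProteinSequence
        from biotite.sequence.align import SubstitutionMatrix as BtMatrix

        alph = ProteinSequence.alphabet
        try:
            bt = BtMatrix(alph, alph, name)
        except FileNotFoundError as exc:
            raise ValueError(f"unknown substitution matrix {matrix_id!r}") from exc
        return cls(name, "".join(alph.get_symbols()), bt.score_matrix())

    def _idx(self, a: str) -> int:
        a = a.upper()
        i = self._index.get(a)
        if i is None:
            i = self._index.get("X")
            if i is None:
                raise ValueError(f"residue {a!r} not in matrix {self.matrix_id}")
        return i

    def score(self, a: str, b: str) -> float:
        return float(self.entries[self._idx(a), self._idx(b)])

    def self_score(self, a: str) -> float:
        i = self._idx(a)
        return float(self.entries[i, i])


def substitution_score(a: str, b: str, matrix: SubstitutionMatrix) -> float:
    """Symmetric matrix lookup; unknown residues fall back to 'X'."""
    return matrix.score(a, b)


def normalized_pair_score(a: str, b: str, matrix: SubstitutionMatrix) -> float:
    """Normalized pairwise similarity in [0, 1]; any gap pair scores 0."""
    if a in GAP_CHARS or b in GAP_CHARS:
        return 0.0
    s = matrix.score(a, b)
    floor = matrix.global_min
    denom = min(matrix.self_score(a), matrix.self_score(b)) - floor
    if denom <= 0:
        return 0.0
    return float(np.clip((s - floor) / denom, 0.0, 1.0))


def cell_conservation(
    residues: Sequence[str],
    matrix: SubstitutionMatrix,
    mode: str = "weighted",
    gap_policy: str = "score",
) -> Optional[float]:
    """Mean pairwise score over all unordered pairs of family residues at
    one cell.

    ``gap_policy="score"`` treats a gap as maximal divergence (raw: the
    matrix minimum; weighted: 0); ``"exclude"`` drops gap pairs from the
    average and returns None (masked) when no pair survives.
    """
    if len(residues) < 2:
        raise ValueError("cell conservation needs at least 2 symbols")
    if mode not in ("raw", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = []
    for a, b in combinations(residues, 2):
        gap = a in GAP_CHARS or b in GAP_CHARS
        if gap and gap_policy == "exclude":
            continue
        if mode == "raw":
            vals.append(matrix.global_min if gap else matrix.score(a, b))
        else:
            vals.append(normalized_pair_score(a, b, matrix))
    if not vals:
        return None
    # summation over sorted values: bit-identical under member permutation
    return float(np.mean(sorted(vals)))


@dataclass
class ConservationGrid:
    """repeats x variable-positions matrix of per-cell conservation scores.

    ``mask`` is True where a cell carries a score; masked cells (HOLEs,
    unaligned columns) carry NaN in ``scores``.  ``column_positions`` are the
    1-based motif positions labelling the grid columns.
    """

    scores: np.ndarray
    mask: np.ndarray
    mode: str
    matrix_id: str
    column_positions: tuple

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != self.mask.shape:
            raise ValueError("scores and mask shapes differ")
        if self.mode == "weighted":
            vals = self.scores[self.mask]
            if vals.size and ((vals < -1e-9).any() or (vals > 1 + 1e-9).any()):
                raise ValueError("weighted scores must lie in [0, 1]")

    @property
    def shape(self):
        return self.scores.shape


def score_grid(
    alignment,
    cellmap: np.ndarray,
    matrix: SubstitutionMatrix,
    mode: str = "weighted",
    gap_policy: str = "score",
    variable_columns: Optional[Iterable[int]] = None,
) -> ConservationGrid:
    """Score every unmasked grid cell across the whole family.

    ``cellmap`` holds the alignment column for each (repeat, variable
    position) cell of the reference, with -1 for masked cells.  The score of
    a cell is the pairwise average over the residues that each family member
    carries in that column.  Pair enumeration is unordered, so the grid is
    invariant to the input order of family members.
    """
    cellmap = np.asarray(cellmap)
    rows = [seq for _, seq in alignment.records]
    scores = np.full(cellmap.shape, np.nan)
    mask = np.zeros(cellmap.shape, dtype=bool)
    for r in range(cellmap.shape[0]):
        for c in range(cellmap.shape[1]):
            col = cellmap[r, c]
            if col < 0:
                continue
            symbols = [row[col] for row in rows]
            val = cell_conservation(symbols, matrix, mode=mode, gap_policy=gap_policy)
            if val is None:
                continue
            scores[r, c] = val
            mask[r, c] = True
    cols = tuple(variable_columns) if variable_columns is not None else tuple(
        range(1, cellmap.shape[1] + 1)
    )
    return ConservationGrid(
        scores=scores, mask=mask, mode=mode, matrix_id=matrix.matrix_id,
        column_positions=cols,
    )
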