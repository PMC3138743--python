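"""Consensus-motif parsing and leucine-rich-repeat (LRR) detection.

An LRR domain is a solenoid in which each repeat of ~20-30 residues forms one
turn.  The consensus residues of the repeat motif (mostly leucines and other
hydrophobics) are buried in the core, while the non-consensus ("x") positions
are solvent-exposed.  This module parses repeat consensus motifs, scans a
protein sequence for repeats matching a motif, and classifies motif positions
into buried consensus columns versus exposed variable columns -- the rows and
columns of the conservation grid built downstream.

Coordinates: sequence indices are 0-based in memory and 1-based in files and
labels; motif positions are always 1-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AA20",
    "HOLE",
    "RELAXED_LEUCINE",
    "MOTIF_PRESETS",
    "MotifToken",
    "ConsensusMotif",
    "PositionClasses",
    "Repeat",
    "RepeatAnnotation",
    "parse_consensus",
    "classify_positions",
    "detect_repeats",
    "apply_curation",
    "cell_label",
    "parse_cell_label",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobic residues accepted at consensus 'L' positions under the relaxed
#: matching option (standard LRR practice: the "L" slots tolerate I/V/F/M).
RELAXED_LEUCINE = frozenset("LIVFM")

#: A repeat cell whose motif position has no residue in the sequence
#: (deletion within an irregular repeat).
HOLE = None

#: Named motif presets: the generic 24-residue LRR consensus and the plant
#: extracellular LRR consensus (a cyclic rotation of the same architecture).
MOTIF_PRESETS = {
    "lrr24": "xxLxxLxxLxxLxLxxNxLxGxIP",
    "plant": "xxLxLxxNxLt/sGxIPxxLxxLxxL",
}

# The beta-strand/beta-turn segment of one repeat: its five wildcard positions
# form the concave, usually ligand-binding face of the solenoid.
_BETA_PATTERN = ("L", "x", "x", "L", "x", "L", "x", "x", "N")


@dataclass(frozen=True)
class MotifToken:
    """One motif position: a fixed residue, an alternative set, or a wildcard.

    ``residues`` is ``None`` for a wildcard ('x') position, otherwise the
    frozenset of allowed residues (one member for a fixed position, several
    for an alternative group such as T|S).
    """

    residues: Optional[frozenset]

    @property
    def is_wildcard(self) -> bool:
        return self.residues is None

    @property
    def kind(self) -> str:
        if self.residues is None:
            return "wildcard"
        return "alternative" if len(self.residues) > 1 else "fixed"

    def __str__(self) -> str:
        if self.residues is None:
            return "x"
        return "/".join(sorted(self.residues))


@dataclass(frozen=True)
class ConsensusMotif:
    """A tokenized repeat consensus motif.

    ``beta_columns`` are the (1-based) wildcard positions inside the
    beta-strand/beta-turn segment, located by matching ``L-x-x-L-x-L-x-x-N``
    against the motif treated cyclically (the repeat phase of a printed
    motif is arbitrary).
    """

    text: str
    tokens: tuple
    beta_columns: tuple

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def wildcard_columns(self) -> tuple:
        return tuple(i + 1 for i, t in enumerate(self.tokens) if t.is_wildcard)

    @property
    def consensus_residues(self) -> frozenset:
        out = set()
        for t in self.tokens:
            if t.residues is not None:
                out.update(t.residues)
        return frozenset(out)

    def n_consensus_tokens(self) -> int:
        return sum(1 for t in self.tokens if not t.is_wildcard)


@dataclass(frozen=True)
class PositionClasses:
    """Partition of motif positions into exposed (variable) and buried
    (consensus) columns, with the beta sub-region carried through."""

    variable_columns: tuple
    consensus_columns: tuple
    beta_columns: tuple


def parse_consensus(motif_text: str) -> ConsensusMotif:
    """Parse a motif string such as ``xxLxxLxxLxxLxLxxNxLxGxIP``.

    Accepted characters: residue letters (fixed positions), ``x``/``X``
    (wildcards), and ``a/b`` alternative groups (e.g. ``t/s``).

    Raises
    ------
    ValueError
        on empty input or an illegal character.
    """
    if not motif_text:
        raise ValueError("empty consensus motif")
    tokens = []
    i = 0
    n = len(motif_text)
    while i < n:
        c = motif_text[i]
        if c in "xX" and not (i + 1 < n and motif_text[i + 1] == "/"):
            tokens.append(MotifToken(None))
            i += 1
            continue
        if not c.isalpha() or c.upper() not in AA20:
            raise ValueError(f"illegal motif character {c!r} at position {i + 1}")
        group = [c.upper()]
        i += 1
        while i + 1 < n and motif_text[i] == "/":
            alt = motif_text[i + 1]
            if not alt.isalpha() or alt.upper() not in AA20:
                raise ValueError(f"illegal motif character {alt!r} at position {i + 2}")
            group.append(alt.upper())
            i += 2
        tokens.append(MotifToken(frozenset(group)))
    if len(tokens) < 6:
        raise ValueError(f"motif has only {len(tokens)} positions; need at least 6")
    if not any(t.is_wildcard for t in tokens):
        warnings.warn("motif has no wildcard positions; the conservation grid will be empty")
    beta = _find_beta_columns(tokens)
    return ConsensusMotif(text=motif_text, tokens=tuple(tokens), beta_columns=beta)


def _find_beta_columns(tokens: Sequence[MotifToken]) -> tuple:
    """Locate the five beta-region wildcards by cyclic pattern match."""
    n = len(tokens)

    def fits(tok: MotifToken, want: str) -> bool:
        if want == "x":
            return tok.is_wildcard
        return tok.residues == frozenset(want)

    for offset in range(n):
        if all(fits(tokens[(offset + k) % n], w) for k, w in enumerate(_BETA_PATTERN)):
            cols = sorted(
                ((offset + k) % n) + 1
                for k, w in enumerate(_BETA_PATTERN)
                if w == "x"
            )
            return tuple(cols)
    warnings.warn("no L-x-x-L-x-L-x-x-N segment found; beta region left empty")
    return ()


def classify_positions(motif: ConsensusMotif) -> PositionClasses:
    """Split motif positions into solvent-exposed variable columns and buried
    consensus columns (the two structural classes of the repeat)."""
    variable = motif.wildcard_columns
    consensus = tuple(p for p in range(1, motif.length + 1) if p not in set(variable))
    return PositionClasses(
        variable_columns=variable,
        consensus_columns=consensus,
        beta_columns=motif.beta_columns,
    )


# ---------------------------------------------------------------------------
# repeat detection
# ---------------------------------------------------------------------------


@dataclass
class Repeat:
    """One detected repeat: motif position (1-based) -> sequence index
    (0-based) or HOLE."""

    cells: dict
    flag: str = "regular"  # regular | irregular | curated

    def mapped_indices(self):
        return [v for _, v in sorted(self.cells.items()) if v is not HOLE]

    @property
    def start(self) -> int:
        idx = self.mapped_indices()
        return idx[0] if idx else -1


@dataclass
class RepeatAnnotation:
    """Ordered (N→C) repeats of one sequence."""

    sequence_id: str
    repeats: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        prev = -1
        for k, rep in enumerate(self.repeats, start=1):
            for pos in sorted(rep.cells):
                idx = rep.cells[pos]
                if idx is HOLE:
                    continue
                if idx <= prev:
                    raise ValueError(
                        f"repeat {k} of {self.sequence_id}: sequence index {idx + 1} "
                        f"(motif position {pos}) breaks N->C ordering"
                    )
                prev = idx

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def _token_match_set(tok: MotifToken, relaxed_leucine: bool) -> frozenset:
    assert tok.residues is not None
    res = set(tok.residues)
    if relaxed_leucine and "L" in res:
        res |= RELAXED_LEUCINE
    return frozenset(res)


def _match_window(seq, s, tokens, match_sets, indel_budget):
    """Align motif tokens to ``seq[s:]`` allowing up to ``indel_budget``
    indels; maximize the number of matched consensus tokens.

    Returns (matches, indels, window_len, cells) for the best alignment or
    None if no alignment fits. Insertions are only allowed strictly inside
    the repeat (between consumed tokens), so flanking junk is never absorbed.
    """
    m = len(tokens)
    B = indel_budget
    W = min(m + B, len(seq) - s)
    if W < m - B:
        return None
    NEG = -1
    # dp[j][k][i]: consensus matches after consuming j tokens, k residues,
    # i indels.  moves: 1=diag, 2=token deletion (HOLE), 3=residue insertion.
    dp = [[[NEG] * (B + 1) for _ in range(W + 1)] for _ in range(m + 1)]
    mv = [[[0] * (B + 1) for _ in range(W + 1)] for _ in range(m + 1)]
    dp[0][0][0] = 0
    for j in range(m + 1):
        for k in range(W + 1):
            for i in range(B + 1):
                if j == 0 and k == 0 and i == 0:
                    continue
                best, move = NEG, 0
                if j > 0 and k > 0 and dp[j - 1][k - 1][i] != NEG:
                    gain = 0
                    ms = match_sets[j - 1]
                    if ms is not None and seq[s + k - 1] in ms:
                        gain = 1
                    cand = dp[j - 1][k - 1][i] + gain
                    if cand > best:
                        best, move = cand, 1
                if j > 0 and i > 0 and dp[j - 1][k][i - 1] > best:
                    best, move = dp[j - 1][k][i - 1], 2
                # insertion: only between tokens (0 < j < m)
                if 0 < j < m and k > 0 and i > 0 and dp[j][k - 1][i - 1] > best:
                    best, move = dp[j][k - 1][i - 1], 3
                dp[j][k][i] = best
                mv[j][k][i] = move
    # pick best end state: max matches, then fewest indels, then window
    # length closest to the motif length (shorter preferred on ties)
    end = None
    for k in range(W + 1):
        for i in range(B + 1):
            v = dp[m][k][i]
            if v == NEG:
                continue
            key = (v, -i, -abs(k - m), -k)
            if end is None or key > end[0]:
                end = (key, k, i)
    if end is None:
        return None
    _, k, i = end
    matches, indels, wlen = dp[m][k][i], i, k
    # traceback to recover motif position -> sequence index mapping
    cells = {}
    j, kk, ii = m, k, i
    while not (j == 0 and kk == 0 and ii == 0):
        move = mv[j][kk][ii]
        if move == 1:
            cells[j] = s + kk - 1
            j, kk = j - 1, kk - 1
        elif move == 2:
            cells[j] = HOLE
            j, ii = j - 1, ii - 1
        elif move == 3:
            kk, ii = kk - 1, ii - 1
        else:  # pragma: no cover - dp always reconstructable
            raise AssertionError("broken traceback")
    return matches, indels, wlen, cells


def detect_repeats(
    sequence: str,
    motif: ConsensusMotif,
    min_match_fraction: float = 0.6,
    indel_budget: int = 2,
    relaxed_leucine: bool = True,
    sequence_id: str = "query",
) -> RepeatAnnotation:
    """Greedy left-to-right scan for repeats matching ``motif``.

    At each candidate offset the motif is aligned to the sequence allowing at
    most ``indel_budget`` insertions/deletions; the window is accepted as a
    repeat when at least ``min_match_fraction`` of the fixed/alternative
    consensus tokens match (with L accepting any of {L,I,V,F,M} under
    ``relaxed_leucine``).  Accepted repeats are non-overlapping and ordered.

    A sequence with no acceptable window yields an empty annotation with a
    warning; a sequence shorter than the motif raises ``ValueError``.
    """
    sequence = sequence.upper()
    if not re.fullmatch(f"[{AA20}X]*", sequence):
        bad = sorted(set(sequence) - set(AA20 + "X"))
        raise ValueError(f"non-residue characters in sequence: {bad}")
    if len(sequence) < motif.length:
        raise ValueError(
            f"sequence length {len(sequence)} is shorter than the motif ({motif.length})"
        )
    if not 0 < min_match_fraction <= 1:
        raise ValueError("min_match_fraction must be in (0, 1]")
    tokens = motif.tokens
    match_sets = [
        None if t.is_wildcard else _token_match_set(t, relaxed_leucine) for t in tokens
    ]
    n_cons = motif.n_consensus_tokens()
    repeats = []
    s = 0
    min_w = max(1, motif.length - indel_budget)
    while s + min_w <= len(sequence):
        hit = _match_window(sequence, s, tokens, match_sets, indel_budget)
        if hit is not None:
            matches, indels, wlen, cells = hit
            if n_cons > 0 and matches / n_cons >= min_match_fraction:
                flag = "regular" if indels == 0 else "irregular"
                repeats.append(Repeat(cells=cells, flag=flag))
                s += wlen
                continue
        s += 1
    if not repeats:
        warnings.warn(f"no repeats matching the motif found in {sequence_id}")
    return RepeatAnnotation(sequence_id=sequence_id, repeats=repeats)


def apply_curation(
    annotation: RepeatAnnotation,
    curation_rows: Iterable,
) -> RepeatAnnotation:
    """Overwrite annotation cells from hand-curation rows.

    Rows are ``(sequence_id, repeat_index, motif_position, sequence_index)``
    with 1-based repeat/motif coordinates, a 0-based sequence index, and
    ``HOLE`` (None) for a deleted cell.  Affected repeats are flagged
    ``curated``; ordering invariants are re-validated and a violation raises
    ``ValueError`` naming the offending repeat.
    """
    new_repeats = [Repeat(cells=dict(r.cells), flag=r.flag) for r in annotation.repeats]
    for seq_id, rep_idx, pos, idx in curation_rows:
        if seq_id != annotation.sequence_id:
            raise ValueError(f"curation row for unknown sequence {seq_id!r}")
        if not 1 <= rep_idx <= len(new_repeats):
            raise ValueError(f"curation row references missing repeat {rep_idx}")
        rep = new_repeats[rep_idx - 1]
        rep.cells[int(pos)] = idx
        rep.flag = "curated"
    return RepeatAnnotation(sequence_id=annotation.sequence_id, repeats=new_repeats)


def cell_label(repeat_index: int, beta_position: int) -> str:
    """Format the "N.M" label of a beta-region cell: repeat N, M-th of the
    five beta-region variable positions (e.g. ``"2.3"``)."""
    if not 1 <= beta_position <= 5:
        raise ValueError(f"beta position {beta_position} outside 1..5")
    if repeat_index < 1:
        raise ValueError(f"repeat index {repeat_index} must be >= 1")
    return f"{repeat_index}.{beta_position}"


def parse_cell_label(label: str) -> tuple:
    """Inverse of :func:`cell_label`."""
    m = re.fullmatch(r"(\d+)\.(\d)", label.strip())
    if not m:
        raise ValueError(f"malformed cell label {label!r}")
    r, b = int(m.group(1)), int(m.group(2))
    cell_label(r, b)  # range-checks, raises on violation
    return r, b
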