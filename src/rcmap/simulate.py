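"""Synthetic LRR families with known ground truth.

The generator emits a star-topology family: one perfect repeat realization
of a consensus motif, copied to every other member with independent
per-cell resampling of the solvent-exposed (variable) positions at a
background mutation rate, except inside a designated patch of cells that is
resampled at its own (default zero) rate.  Consensus positions are never
touched, so repeat detection stays exact and the patch is the only
systematically conserved surface region -- a controllable stand-in for a
ligand-binding site.

All randomness flows from one integer seed through a counter-based
generator (numpy Philox), so families are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Tuple

import numpy as np

from .motif import AA20, ConsensusMotif

__all__ = [
    "FamilySpec",
    "perfect_repeat_sequence",
    "generate_family",
    "block_patch",
    "variable_alphabet",
]

#: Robinson-Robinson amino-acid background frequencies (order of AA20),
#: used only when frequency-weighted resampling is requested.
_NATURAL_FREQS = {
    "A": 0.0780, "C": 0.0192, "D": 0.0536, "E": 0.0629, "F": 0.0386,
    "G": 0.0738, "H": 0.0226, "I": 0.0514, "K": 0.0595, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0584, "V": 0.0644, "W": 0.0131, "Y": 0.0321,
}


def variable_alphabet(motif: ConsensusMotif) -> str:
    """Residues available at wildcard positions: the 20 standard residues
    minus the motif's own consensus residues (keeps wildcard draws from
    mimicking consensus positions and confusing the detector)."""
    allowed = [a for a in AA20 if a not in motif.consensus_residues]
    if not allowed:
        raise ValueError("motif consensus uses all 20 residues")
    return "".join(allowed)


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family.

    ``patch`` cells are (repeat_index, motif_position), 1-based, and must be
    wildcard positions within the grid; rates are per-cell resampling
    probabilities in [0, 1].
    """

    n_repeats: int
    n_sequences: int
    motif: ConsensusMotif
    background_mutation_rate: float
    patch: FrozenSet[Tuple[int, int]] = frozenset()
    patch_mutation_rate: float = 0.0
    seed: int = 0
    natural_frequencies: bool = False

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_sequences < 2:
            raise ValueError("n_sequences must be >= 2")
        for rate in (self.background_mutation_rate, self.patch_mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"mutation rate {rate} outside [0, 1]")
        wild = set(self.motif.wildcard_columns)
        for rep, pos in self.patch:
            if not 1 <= rep <= self.n_repeats:
                raise ValueError(f"patch repeat {rep} outside 1..{self.n_repeats}")
            if pos not in wild:
                raise ValueError(f"patch position {pos} is not a wildcard column")


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=int(seed)))


def _draw_variable(rng: np.random.Generator, alphabet: str, natural: bool) -> str:
    if natural:
        p = np.array([_NATURAL_FREQS[a] for a in alphabet])
        p = p / p.sum()
        return alphabet[int(rng.choice(len(alphabet), p=p))]
    return alphabet[int(rng.integers(len(alphabet)))]


def perfect_repeat_sequence(
    motif: ConsensusMotif,
    n_repeats: int,
    seed: int = 0,
    natural_frequencies: bool = False,
) -> str:
    """Concatenate ``n_repeats`` realizations of the motif.

    Fixed tokens emit their residue, alternative tokens pick uniformly among
    their alternatives, wildcards pick from the non-consensus residue
    alphabet; deterministic per seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = _rng(seed)
    alphabet = variable_alphabet(motif)
    out = []
    for _ in range(n_repeats):
        for tok in motif.tokens:
            if tok.is_wildcard:
                out.append(_draw_variable(rng, alphabet, natural_frequencies))
            else:
                choices = sorted(tok.residues)
                out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def generate_family(spec: FamilySpec):
    """Generate a synthetic family and return ``(records, patch)``.

    ``records`` is a list of (id, sequence); member 1 is the perfect repeat
    realization and the others carry independent per-cell resampling at the
    background rate (patch cells at the patch rate).  The returned patch is
    the ground-truth contact set in (repeat_index, motif_position) form.
    """
    rng = _rng(spec.seed)
    base_seed = int(rng.integers(2 ** 31))
    base = perfect_repeat_sequence(
        spec.motif, spec.n_repeats, seed=base_seed,
        natural_frequencies=spec.natural_frequencies,
    )
    alphabet = variable_alphabet(spec.motif)
    m = spec.motif.length
    wild = spec.motif.wildcard_columns
    patch = frozenset(spec.patch)
    records = [("member_1", base)]
    for k in range(2, spec.n_sequences + 1):
        seq = list(base)
        for rep in range(1, spec.n_repeats + 1):
            for pos in wild:
                rate = (spec.patch_mutation_rate if (rep, pos) in patch
                        else spec.background_mutation_rate)
                u = rng.random()
                if u < rate:
                    seq[(rep - 1) * m + pos - 1] = _draw_variable(
                        rng, alphabet, spec.natural_frequencies
                    )
        records.append((f"member_{k}", "".join(seq)))
    return records, patch


def block_patch(
    motif: ConsensusMotif,
    top_repeat: int,
    left_variable_index: int,
    n_rows: int = 3,
    n_cols: int = 3,
) -> FrozenSet[Tuple[int, int]]:
    """A rectangular patch of variable cells.

    ``left_variable_index`` is a 0-based index into the motif's ordered
    wildcard columns, so the patch spans ``n_cols`` *adjacent grid columns*
    (which need not be adjacent motif positions).
    """
    wild = motif.wildcard_columns
    if left_variable_index < 0 or left_variable_index + n_cols > len(wild):
        raise ValueError("patch columns outside the variable-column range")
    cols = wild[left_variable_index:left_variable_index + n_cols]
    return frozenset(
        (rep, pos)
        for rep in range(top_repeat, top_repeat + n_rows)
        for pos in cols
    )
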