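"""Validation statistics: decile ranking, contact enrichment, t-test.

Known LRR-ligand contact residues (the white asterisks overlaid on the heat
maps, taken from solved crystal structures or, for synthetic families, from
the generator's ground-truth patch) are used to ask whether high-scoring
cells are enriched for functional sites:

* all unmasked scores of a map are ranked in descending order and split
  into deciles (decile 1 = highest);
* the contact cells' decile histogram is tallied per score stage (raw
  pairwise, weighted pairwise, regional);
* contact-cell scores are compared against all other cells with a
  pooled-variance Student's t-test, one-sided for contact > other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .regional import rank_cells

__all__ = [
    "ContactAnnotation",
    "EnrichmentResult",
    "decile_assign",
    "contact_enrichment",
    "contact_ttest",
]


@dataclass(frozen=True)
class ContactAnnotation:
    """Grid cells annotated as LRR-ligand contact points.

    Cells are (repeat_index, motif_position), both 1-based, matching the
    columns of the contact TSV."""

    cells: frozenset

    def __post_init__(self):
        object.__setattr__(self, "cells", frozenset(tuple(c) for c in self.cells))

    def grid_indices(self, column_positions: Sequence[int]) -> List[Tuple[int, int]]:
        """Convert to 0-based (row, column) grid coordinates."""
        colmap = {pos: i for i, pos in enumerate(column_positions)}
        out = []
        for rep, pos in sorted(self.cells):
            if pos not in colmap:
                raise ValueError(
                    f"contact motif position {pos} is not a variable column"
                )
            out.append((rep - 1, colmap[pos]))
        return out

    def validate(self, map_or_grid, column_positions: Sequence[int]) -> None:
        mask = np.asarray(map_or_grid.mask, dtype=bool)
        for r, c in self.grid_indices(column_positions):
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
                raise ValueError(f"contact cell ({r + 1}, {c + 1}) outside the grid")
            if not mask[r, c]:
                raise ValueError(f"contact cell ({r + 1}, {c + 1}) is masked")


def decile_assign(map_or_grid, direction: str = "conserved") -> np.ndarray:
    """Assign each unmasked cell its decile (1 = highest scores).

    Cells are sorted (descending for ``conserved``) with positional
    tie-breaking; the cell at 1-based rank r of n receives decile
    ``ceil(10 r / n)``.  Masked cells get 0.  Requires >= 10 unmasked cells.
    """
    mask = np.asarray(map_or_grid.mask, dtype=bool)
    n = int(mask.sum())
    if n < 10:
        raise ValueError(f"decile assignment needs >= 10 unmasked cells, got {n}")
    order = rank_cells(map_or_grid, direction=direction)
    out = np.zeros(mask.shape, dtype=int)
    for rank, (r, c) in enumerate(order, start=1):
        out[r, c] = math.ceil(10 * rank / n)
    return out


@dataclass
class EnrichmentResult:
    """Per-stage decile histograms of contact cells plus the contact-vs-
    other test on the final (regional) map."""

    histograms: Dict[str, np.ndarray]
    top_decile_fraction: Dict[str, float]
    top_two_decile_fraction: Dict[str, float]
    n_contact: int
    n_other: int
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    p_value_two_sided: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "histograms": {k: v.tolist() for k, v in self.histograms.items()},
            "top_decile_fraction": dict(self.top_decile_fraction),
            "top_two_decile_fraction": dict(self.top_two_decile_fraction),
            "n_contact": self.n_contact,
            "n_other": self.n_other,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "p_value_two_sided": self.p_value_two_sided,
        }


def contact_enrichment(
    stage_maps: Dict[str, object],
    contacts: ContactAnnotation,
    column_positions: Sequence[int],
    direction: str = "conserved",
) -> EnrichmentResult:
    """Tally contact cells per decile for each score stage.

    ``stage_maps`` maps stage names (conventionally ``raw``, ``weighted``,
    ``regional``) to grid-like objects sharing one shape and mask.  Decile
    counts sum to the number of contacts in every stage.
    """
    if not contacts.cells:
        raise ValueError("empty contact set")
    first = next(iter(stage_maps.values()))
    contacts.validate(first, column_positions)
    idx = contacts.grid_indices(column_positions)
    histograms = {}
    top1 = {}
    top2 = {}
    for name, m in stage_maps.items():
        dec = decile_assign(m, direction=direction)
        hist = np.zeros(10, dtype=int)
        for r, c in idx:
            hist[dec[r, c] - 1] += 1
        histograms[name] = hist
        top1[name] = hist[0] / len(idx)
        top2[name] = (hist[0] + hist[1]) / len(idx)
    n_total = int(np.asarray(first.mask).sum())
    result = EnrichmentResult(
        histograms=histograms,
        top_decile_fraction=top1,
        top_two_decile_fraction=top2,
        n_contact=len(idx),
        n_other=n_total - len(idx),
    )
    if "regional" in stage_maps:
        t, p1, p2 = contact_ttest(stage_maps["regional"], contacts, column_positions)
        result.t_statistic, result.p_value, result.p_value_two_sided = t, p1, p2
    return result


def contact_ttest(
    map_or_grid,
    contacts: ContactAnnotation,
    column_positions: Sequence[int],
) -> Tuple[float, float, float]:
    """Pooled-variance Student's t-test of contact vs all other unmasked
    scores, one-sided for contact > other.

    Returns ``(t, p_one_sided, p_two_sided)``.
    """
    contacts.validate(map_or_grid, column_positions)
    idx = set(contacts.grid_indices(column_positions))
    mask = np.asarray(map_or_grid.mask, dtype=bool)
    scores = np.asarray(map_or_grid.scores, dtype=float)
    contact_scores = []
    other_scores = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c]:
                continue
            (contact_scores if (r, c) in idx else other_scores).append(scores[r, c])
    if len(contact_scores) < 2 or len(other_scores) < 2:
        raise ValueError("t-test needs >= 2 cells in each group")
    res = stats.ttest_ind(contact_scores, other_scores, equal_var=True,
                          alternative="greater")
    res2 = stats.ttest_ind(contact_scores, other_scores, equal_var=True)
    return float(res.statistic), float(res.pvalue), float(res2.pvalue)
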