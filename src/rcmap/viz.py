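"""Heat-map rendering of regional conservation maps.

Rows are repeats top-to-bottom N->C; columns are the variable motif
positions, labelled with their position numbers.  Dark red marks the most
conserved regions and blue the most divergent (per-map relative scale by
default, fixed [0, 1] with ``absolute_scale``); the five beta-strand /
beta-turn columns -- the usual ligand-binding concave face -- are delimited
by bold vertical lines, annotated contact cells carry white asterisks, and
masked cells are grey.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .evaluation import ContactAnnotation
from .motif import ConsensusMotif

__all__ = ["render_heatmap"]


def render_heatmap(
    map_like,
    motif: ConsensusMotif,
    contacts: Optional[ContactAnnotation] = None,
    out="map.png",
    absolute_scale: bool = False,
    title: Optional[str] = None,
    dpi: int = 150,
):
    """Render a grid/map to an image file (PNG or SVG by extension).

    Rendering is deterministic: the same map yields a byte-identical file.
    """
    scores = np.asarray(map_like.scores, dtype=float)
    mask = np.asarray(map_like.mask, dtype=bool)
    if scores.size == 0 or not mask.any():
        raise ValueError("cannot render an empty map")
    cols = list(getattr(map_like, "column_positions", ())) or list(
        range(1, scores.shape[1] + 1)
    )
    data = np.ma.masked_array(scores, mask=~mask)
    if absolute_scale:
        vmin, vmax = 0.0, 1.0
    else:
        vmin, vmax = float(data.min()), float(data.max())
        if vmin == vmax:  # flat map: one-colour panel
            vmin, vmax = vmin - 0.5, vmax + 0.5
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.65")

    rows = scores.shape[0]
    fig_h = max(2.0, 0.28 * rows + 1.2)
    fig_w = max(3.0, 0.45 * len(cols) + 1.6)
    with plt.rc_context({"svg.hashsalt": "rcm"}):
        fig, ax = plt.subplots(figsize=(fig_w, fig_h))
        im = ax.imshow(data, cmap=cmap, vmin=vmin, vmax=vmax,
                       aspect="auto", interpolation="nearest")
        ax.set_xticks(range(len(cols)), [str(c) for c in cols], fontsize=8)
        ax.xaxis.tick_top()
        ax.set_yticks(range(rows), [str(r) for r in range(1, rows + 1)], fontsize=8)
        ax.set_ylabel("repeat")
        # bold lines around the beta-strand/beta-turn columns
        beta_idx = [i for i, p in enumerate(cols) if p in set(motif.beta_columns)]
        if beta_idx:
            runs = []
            start = prev = beta_idx[0]
            for i in beta_idx[1:]:
                if i == prev + 1:
                    prev = i
                    continue
                runs.append((start, prev))
                start = prev = i
            runs.append((start, prev))
            for lo, hi in runs:
                ax.axvline(lo - 0.5, color="black", lw=2.0)
                ax.axvline(hi + 0.5, color="black", lw=2.0)
        if contacts is not None:
            for r, c in contacts.grid_indices(cols):
                ax.text(c, r, "*", color="white", ha="center", va="center",
                        fontsize=12, fontweight="bold")
        if title:
            ax.set_title(title, fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.8, label="regional conservation")
        fig.savefig(out, dpi=dpi, bbox_inches="tight",
                    metadata=_no_date_metadata(out))
        plt.close(fig)
    return Path(out)


def _no_date_metadata(out) -> dict:
    """Strip volatile metadata so renders are byte-reproducible."""
    suffix = Path(out).suffix.lower()
    if suffix == ".svg":
        return {"Date": None}
    return {}
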