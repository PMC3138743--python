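"""File formats: FASTA/Clustal input, TSV score grids, contacts, curation,
and the JSON run manifest.

All tables are plain TSV so they diff and round-trip exactly: score grids
have one row per repeat and one column per variable motif position (header
gives the motif position numbers), masked cells written as ``NA``; contact
and curation tables use 1-based coordinates with ``-`` for HOLE.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from .evaluation import ContactAnnotation
from .motif import HOLE, Repeat, RepeatAnnotation
from .scoring import GAP_CHARS

__all__ = [
    "read_sequences",
    "read_clustal",
    "write_fasta",
    "write_grid_tsv",
    "read_grid_tsv",
    "write_annotation_tsv",
    "read_annotation_tsv",
    "read_curation_tsv",
    "write_contacts_tsv",
    "read_contacts_tsv",
    "write_histogram_tsv",
    "file_digest",
    "write_manifest",
    "read_manifest",
]

_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


def read_sequences(path, aligned: bool = False) -> List[Tuple[str, str]]:
    """Read a FASTA file into (id, sequence) records.

    Residues are upper-cased and a trailing ``*`` is stripped.  Duplicate
    ids, empty files and (in unaligned mode) gap characters are errors.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path.name}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - _RESIDUES - GAP_CHARS
        if bad:
            raise ValueError(
                f"non-residue characters {sorted(bad)} in {rec.id!r}"
            )
        if not aligned and any(c in GAP_CHARS for c in seq):
            raise ValueError(
                f"{rec.id!r} contains gap characters; pass aligned input "
                "explicitly (--aligned)"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def read_clustal(path) -> List[Tuple[str, str]]:
    """Read a Clustal ``.aln`` file into aligned (id, sequence) records."""
    aln = AlignIO.read(str(path), "clustal")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# score grids
# ---------------------------------------------------------------------------


def write_grid_tsv(grid_like, path) -> None:
    """Write a score grid/map: rows repeats (1-based index column), columns
    variable motif positions, masked cells as NA."""
    scores = np.asarray(grid_like.scores, dtype=float)
    mask = np.asarray(grid_like.mask, dtype=bool)
    cols = list(grid_like.column_positions) or list(range(1, scores.shape[1] + 1))
    df = pd.DataFrame(
        np.where(mask, scores, np.nan),
        index=pd.RangeIndex(1, scores.shape[0] + 1, name="repeat"),
        columns=[str(c) for c in cols],
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_grid_tsv(path):
    """Read a grid TSV back into ``(scores, mask, column_positions)``."""
    df = pd.read_csv(path, sep="\t", index_col="repeat", na_values=["NA"])
    scores = df.to_numpy(dtype=float)
    mask = ~np.isnan(scores)
    cols = tuple(int(c) for c in df.columns)
    return scores, mask, cols


# ---------------------------------------------------------------------------
# repeat annotations and curation
# ---------------------------------------------------------------------------


def write_annotation_tsv(annotation: RepeatAnnotation, path) -> None:
    """Serialize an annotation (1-based seq_index, ``-`` for HOLE, plus the
    per-repeat flag so round-trips are exact)."""
    rows = []
    for k, rep in enumerate(annotation.repeats, start=1):
        for pos in sorted(rep.cells):
            idx = rep.cells[pos]
            rows.append({
                "seq_id": annotation.sequence_id,
                "repeat_index": k,
                "motif_position": pos,
                "seq_index": "-" if idx is HOLE else idx + 1,
                "flag": rep.flag,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> RepeatAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty annotation table {path}")
    seq_ids = df["seq_id"].unique()
    if len(seq_ids) != 1:
        raise ValueError("annotation table must describe a single sequence")
    repeats = []
    for k, sub in df.groupby(df["repeat_index"].astype(int), sort=True):
        cells = {}
        flags = set(sub.get("flag", pd.Series(["regular"])).fillna("regular"))
        for _, row in sub.iterrows():
            idx = row["seq_index"]
            cells[int(row["motif_position"])] = (
                HOLE if idx == "-" else int(idx) - 1
            )
        repeats.append(Repeat(cells=cells, flag=sorted(flags)[0]))
    return RepeatAnnotation(sequence_id=str(seq_ids[0]), repeats=repeats)


def read_curation_tsv(path) -> List[Tuple[str, int, int, Optional[int]]]:
    """Read hand-curation rows: seq_id, repeat_index, motif_position,
    seq_index (1-based, ``-`` = HOLE) -> 0-based rows for apply_curation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for _, row in df.iterrows():
        idx = row["seq_index"]
        rows.append((
            str(row["seq_id"]),
            int(row["repeat_index"]),
            int(row["motif_position"]),
            HOLE if idx == "-" else int(idx) - 1,
        ))
    return rows


# ---------------------------------------------------------------------------
# contacts and histograms
# ---------------------------------------------------------------------------


def write_contacts_tsv(contacts: ContactAnnotation, path) -> None:
    df = pd.DataFrame(sorted(contacts.cells),
                      columns=["repeat_index", "motif_position"])
    df.to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path) -> ContactAnnotation:
    df = pd.read_csv(path, sep="\t")
    cells = frozenset(
        (int(r), int(p))
        for r, p in zip(df["repeat_index"], df["motif_position"])
    )
    if not cells:
        raise ValueError(f"no contact cells in {path}")
    return ContactAnnotation(cells=cells)


def write_histogram_tsv(histograms: dict, path) -> None:
    """Decile histograms per score stage, one row per decile."""
    df = pd.DataFrame({k: np.asarray(v, dtype=int) for k, v in histograms.items()},
                      index=pd.RangeIndex(1, 11, name="decile"))
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
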