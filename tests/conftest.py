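import numpy as np
import pytest

import rcmap as rc


@pytest.fixture(scope="session")
def lrr24():
    return rc.parse_consensus(rc.MOTIF_PRESETS["lrr24"])


@pytest.fixture(scope="session")
def plant():
    return rc.parse_consensus(rc.MOTIF_PRESETS["plant"])


@pytest.fixture(scope="session")
def blosum62():
    return rc.SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def small_family(lrr24):
    """A 4-member synthetic family (8 repeats) with a 3x3 conserved patch."""
    spec = rc.FamilySpec(
        n_repeats=8, n_sequences=4, motif=lrr24,
        background_mutation_rate=0.5, patch=rc.block_patch(lrr24, 3, 5),
        seed=42,
    )
    records, patch = rc.generate_family(spec)
    return records, patch, spec


def family_stage_maps(records, motif, matrix, reference_id=None,
                      kernel_preset="default"):
    """Detect + align + score + smooth one family; returns the three stage
    maps and the grid column labels.  Shared helper for tests."""
    aln = rc.align_family(records, reference_id=reference_id, matrix=matrix)
    ref_seq = aln.ungapped(aln.reference_id)
    ann = rc.detect_repeats(ref_seq, motif, sequence_id=aln.reference_id)
    classes = rc.classify_positions(motif)
    full = rc.map_cells_to_columns(ann, aln)
    var_idx = [p - 1 for p in classes.variable_columns if p <= full.shape[1]]
    cellmap = full[:, var_idx]
    cols = tuple(classes.variable_columns[: len(var_idx)])
    raw = rc.score_grid(aln, cellmap, matrix, mode="raw", variable_columns=cols)
    weighted = rc.score_grid(aln, cellmap, matrix, mode="weighted",
                             variable_columns=cols)
    regional = rc.regional_map(weighted, rc.make_kernel(kernel_preset))
    return {"raw": raw, "weighted": weighted, "regional": regional}, cols


def random_masked_grid(rng, max_rows=40, max_cols=14, mask_p=0.1):
    """Random weighted-mode grid with a random validity mask (>=1 valid)."""
    rows = int(rng.integers(5, max_rows + 1))
    cols = int(rng.integers(5, max_cols + 1))
    scores = rng.random((rows, cols))
    mask = rng.random((rows, cols)) > mask_p
    if not mask.any():
        mask[0, 0] = True
    scores[~mask] = np.nan
    return rc.ConservationGrid(scores=scores, mask=mask, mode="weighted",
                               matrix_id="BLOSUM62",
                               column_positions=tuple(range(1, cols + 1)))


def brute_force_window(scores, mask, weights):
    """Independent windowed-mean oracle: truncate at edges and masked cells,
    renormalize surviving weights."""
    rows, cols = scores.shape
    k = weights.shape[0] // 2
    out = np.full((rows, cols), np.nan)
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            num = den = 0.0
            for dr in range(-k, k + 1):
                for dc in range(-k, k + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                        w = weights[dr + k, dc + k]
                        num += w * scores[rr, cc]
                        den += w
            out[r, c] = num / den
    return out
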