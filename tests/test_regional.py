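"""Window kernels and the center-weighted regional map vs a brute-force
window oracle."""

import numpy as np
import pytest

import rcmap as rc
from conftest import brute_force_window, random_masked_grid


class TestMakeKernel:
    def test_default_5x5_weights(self):
        k = rc.make_kernel("default", size=5)
        assert k.weights.shape == (5, 5)
        assert k.weights[2, 2] == 4
        assert k.weights.sum() == 36  # 4 + 8*2 + 16*1
        assert (k.weights > 0).all()

    def test_center_only(self):
        k = rc.make_kernel("center_only", size=5)
        assert k.weights[2, 2] == 1
        assert k.weights.sum() == 1

    def test_uniform(self):
        assert (rc.make_kernel("uniform", size=3).weights == 1).all()

    def test_center_dominates(self):
        for preset in ("default", "uniform", "center_only"):
            w = rc.make_kernel(preset, size=5).weights
            assert w[2, 2] >= w.max()

    @pytest.mark.parametrize("kwargs", [
        {"size": 4}, {"preset": "gaussian", "sigma": 0},
        {"preset": "gaussian"}, {"preset": "nosuch"},
    ])
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            rc.make_kernel(**{"preset": "default", **kwargs})


def _grid(scores, mask=None):
    scores = np.asarray(scores, dtype=float)
    if mask is None:
        mask = np.ones_like(scores, dtype=bool)
    return rc.ConservationGrid(scores=scores, mask=mask, mode="raw",
                               matrix_id="BLOSUM62",
                               column_positions=tuple(range(1, scores.shape[1] + 1)))


class TestRegionalMap:
    def test_constant_grid_constant_map(self):
        for preset in ("default", "uniform", "gaussian"):
            kernel = rc.make_kernel(preset, size=5,
                                    sigma=1.5 if preset == "gaussian" else None)
            grid = _grid(np.full((12, 14), 0.37))
            m = rc.regional_map(grid, kernel)
            assert np.allclose(m.scores, 0.37)

    def test_uniform_interior_single_spike(self):
        scores = np.zeros((11, 11))
        scores[5, 5] = 1.0
        m = rc.regional_map(_grid(scores), rc.make_kernel("uniform", 5))
        assert m.scores[5, 5] == pytest.approx(1 / 25)

    def test_uniform_corner_truncated_window(self):
        scores = np.zeros((11, 11))
        scores[0, 0] = 1.0
        m = rc.regional_map(_grid(scores), rc.make_kernel("uniform", 5))
        assert m.scores[0, 0] == pytest.approx(1 / 9)  # 3x3 surviving window

    @pytest.mark.parametrize("preset", ["uniform", "default", "gaussian"])
    def test_oracle_equivalence_100_random_grids(self, preset):
        kernel = rc.make_kernel(preset, size=5,
                                sigma=1.2 if preset == "gaussian" else None)
        rng = np.random.default_rng(17)
        for _ in range(100):
            grid = random_masked_grid(rng)
            m = rc.regional_map(grid, kernel)
            expect = brute_force_window(np.nan_to_num(grid.scores), grid.mask,
                                        kernel.weights)
            got = np.where(m.mask, m.scores, np.nan)
            assert np.allclose(got, expect, atol=1e-12, equal_nan=True)

    def test_center_only_reduces_to_cell_grid(self):
        rng = np.random.default_rng(3)
        grid = random_masked_grid(rng)
        m = rc.regional_map(grid, rc.make_kernel("center_only", 5))
        np.testing.assert_array_equal(
            np.where(m.mask, m.scores, np.nan),
            np.where(grid.mask, grid.scores, np.nan),
        )

    def test_scores_bounded_by_window_support(self):
        rng = np.random.default_rng(23)
        kernel = rc.make_kernel("default", 5)
        for _ in range(20):
            grid = random_masked_grid(rng)
            m = rc.regional_map(grid, kernel)
            rows, cols = grid.shape
            for r in range(rows):
                for c in range(cols):
                    if not m.mask[r, c]:
                        continue
                    window = [
                        grid.scores[rr, cc]
                        for rr in range(max(0, r - 2), min(rows, r + 3))
                        for cc in range(max(0, c - 2), min(cols, c + 3))
                        if grid.mask[rr, cc]
                    ]
                    assert min(window) - 1e-12 <= m.scores[r, c] <= max(window) + 1e-12

    def test_smoothing_variance_ordering(self):
        # flatter kernels smooth more: variance rises with center-weighting
        rng = np.random.default_rng(5)
        deltas = []
        for _ in range(20):
            grid = random_masked_grid(rng, mask_p=0.0)
            var = {
                preset: np.var(rc.regional_map(grid, rc.make_kernel(preset, 5)).scores)
                for preset in ("uniform", "default", "center_only")
            }
            deltas.append((var["uniform"] <= var["default"] + 1e-12,
                           var["default"] <= var["center_only"] + 1e-12))
        assert np.mean([d[0] for d in deltas]) >= 0.9
        assert np.mean([d[1] for d in deltas]) >= 0.9

    def test_masked_center_stays_masked(self):
        scores = np.random.default_rng(1).random((8, 8))
        mask = np.ones((8, 8), dtype=bool)
        mask[3, 3] = False
        m = rc.regional_map(_grid(scores, mask), rc.make_kernel("default", 5))
        assert not m.mask[3, 3]
        assert np.isnan(m.scores[3, 3])

    def test_oversized_kernel_warns(self):
        with pytest.warns(UserWarning):
            rc.regional_map(_grid(np.ones((3, 3))), rc.make_kernel("uniform", 9))

    def test_all_masked_errors(self):
        grid = rc.ConservationGrid(
            scores=np.full((5, 5), np.nan), mask=np.zeros((5, 5), bool),
            mode="weighted", matrix_id="x", column_positions=tuple(range(1, 6)))
        with pytest.raises(ValueError):
            rc.regional_map(grid, rc.make_kernel())


class TestRankCells:
    def test_distinct_scores_strict_order(self):
        scores = np.arange(20, dtype=float).reshape(4, 5)
        order = rc.rank_cells(_grid(scores), "conserved")
        ranked = [scores[rc_] for rc_ in order]
        assert ranked == sorted(ranked, reverse=True)

    def test_all_equal_positional_tiebreak(self):
        order = rc.rank_cells(_grid(np.ones((3, 4))), "conserved")
        assert order == [(r, c) for r in range(3) for c in range(4)]

    def test_divergent_reverses_up_to_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            grid = random_masked_grid(rng)
            up = rc.rank_cells(grid, "divergent")
            down = rc.rank_cells(grid, "conserved")
            assert [grid.scores[x] for x in up] == \
                sorted([grid.scores[x] for x in down])
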