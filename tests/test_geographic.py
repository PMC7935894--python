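"""Binary thresholding, stability comparison and MOP extrapolation risk."""

import numpy as np
import pytest

import paleoniche as pn
from paleoniche.envspace import EnvMatrix
from paleoniche.errors import InvalidParameterError
from paleoniche.geographic import BinaryMap, SuitabilityGrid
from paleoniche.scenario import GridTransform

TFM = GridTransform(0.0, 0.0, 1.0)


def _grid(scores, mask=None):
    scores = np.asarray(scores, dtype=float)
    mask = np.ones_like(scores, dtype=bool) if mask is None else mask
    return SuitabilityGrid(scores, mask, TFM)


def _points_at(grid, cells):
    n_rows = grid.scores.shape[0]
    return [(f"p{i}", c + 0.5, n_rows - r - 0.5) for i, (r, c) in enumerate(cells)]


class TestThresholdBinary:
    def test_interpolated_percentile_threshold(self):
        """20 occurrence scores 0.05..1.00: the 5th percentile is 0.0975, so a
        0.09 cell drops out and a 0.10 cell stays suitable."""
        occ_scores = np.round(np.arange(1, 21) * 0.05, 2)
        grid_vals = np.concatenate([occ_scores, [0.09, 0.10, 0.5, 0.5]])
        grid = _grid(grid_vals.reshape(4, 6))
        cells = [(i // 6, i % 6) for i in range(20)]
        binary = pn.threshold_binary(grid, _points_at(grid, cells), percentile=5)
        assert binary.threshold == pytest.approx(0.0975)
        assert binary.values[3, 2] == 0   # the 0.09 cell
        assert binary.values[3, 3] == 1   # the 0.10 cell

    def test_equal_scores_all_suitable(self):
        grid = _grid(np.full((4, 4), 0.4))
        binary = pn.threshold_binary(grid, _points_at(grid, [(0, 0), (1, 1)]), 5)
        assert binary.values[grid.mask].all()

    @pytest.mark.parametrize("seed", range(3))
    def test_occurrence_omission_bounded_by_construction(self, seed):
        rng = np.random.default_rng(seed)
        grid = _grid(rng.random((20, 20)))
        cells = [tuple(c) for c in rng.integers(0, 20, size=(30, 2))]
        cells = list(dict.fromkeys(cells))
        pts = _points_at(grid, cells)
        binary = pn.threshold_binary(grid, pts, percentile=5)
        occ_scores = grid.values_at(pts)
        omission = (occ_scores < binary.threshold).mean()
        assert omission <= 0.05 + 1 / len(cells)

    def test_no_points_error(self):
        with pytest.raises(InvalidParameterError):
            pn.threshold_binary(_grid(np.ones((4, 4))), [], 5)


class TestCompareBinary:
    def _bin(self, values, mask=None):
        values = np.asarray(values, dtype=np.uint8)
        mask = np.ones_like(values, dtype=bool) if mask is None else mask
        return BinaryMap(values, mask, TFM, 0.5, "test")

    def test_identical_maps_no_change(self, rng):
        v = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        cmp = pn.compare_binary(self._bin(v), self._bin(v))
        assert cmp.counts["lost"] == 0 and cmp.counts["gained"] == 0

    def test_single_cell_lost(self):
        a = np.ones((3, 3), dtype=np.uint8)
        b = a.copy()
        b[1, 1] = 0
        cmp = pn.compare_binary(self._bin(a), self._bin(b))
        assert cmp.counts["lost"] == 1 and cmp.counts["gained"] == 0

    def test_counts_partition_valid_cells(self, rng):
        mask = rng.random((8, 8)) > 0.2
        a = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        b = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        cmp = pn.compare_binary(self._bin(a, mask), self._bin(b, mask))
        assert sum(cmp.counts.values()) == int(mask.sum())

    def test_antisymmetry(self, rng):
        a = (rng.random((10, 10)) > 0.4).astype(np.uint8)
        b = (rng.random((10, 10)) > 0.6).astype(np.uint8)
        fwd = pn.compare_binary(self._bin(a), self._bin(b))
        rev = pn.compare_binary(self._bin(b), self._bin(a))
        assert fwd.counts["lost"] == rev.counts["gained"]
        assert fwd.counts["gained"] == rev.counts["lost"]

    def test_mask_mismatch_rejected(self, rng):
        m1 = np.ones((4, 4), dtype=bool)
        m2 = m1.copy()
        m2[0, 0] = False
        v = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(InvalidParameterError, match="mask"):
            pn.compare_binary(self._bin(v, m1), self._bin(v, m2))


class TestMOP:
    def _env(self, values):
        return EnvMatrix(np.atleast_2d(values), ("v1", "v2"), "raw")

    def test_identical_cell_has_similarity_one(self, rng):
        """With the reference fraction selecting one nearest neighbour, a
        transfer cell equal to a calibration point has distance 0 and
        similarity exactly 1."""
        calib = self._env(rng.standard_normal((100, 2)))
        transfer = self._env(np.vstack([calib.values[:1], calib.values + 5.0]))
        sim, strict = pn.mop(calib, transfer, reference_percent=0.01)
        assert sim[0] == pytest.approx(1.0)

    def test_out_of_range_flags_strict_extrapolation(self, rng):
        calib = self._env(rng.random((50, 2)))
        transfer = self._env(np.array([[0.5, 0.5], [-3.0, 0.5]]))
        _, strict = pn.mop(calib, transfer)
        assert not strict[0] and strict[1]

    def test_similarity_monotone_along_ray(self, rng):
        """Moving a transfer cell away from the calibration cloud along a ray
        never increases its MOP similarity."""
        calib = self._env(rng.standard_normal((200, 2)))
        ray = np.column_stack([np.linspace(0, 10, 21), np.zeros(21)])
        sim, _ = pn.mop(calib, self._env(ray), reference_percent=0.1)
        assert np.all(np.diff(sim) <= 1e-12)

    def test_grid_output_aligned(self, scenario_pair, background):
        _, glacial = scenario_pair
        grid = pn.mop(background, glacial, 0.1)
        assert grid.similarity.shape == glacial.mask.shape
        assert grid.similarity[glacial.mask].max() <= 1.0
        # strict extrapolation implies some variable out of calibration range
        lo = background.values.min(axis=0)
        hi = background.values.max(axis=0)
        env, rows, cols = glacial.env_table()
        flagged = grid.strict_extrapolation[rows, cols]
        outside = ((env < lo) | (env > hi)).any(axis=1)
        assert np.array_equal(flagged, outside)

    def test_empty_calibration_rejected(self):
        with pytest.raises(InvalidParameterError):
            pn.mop(EnvMatrix(np.empty((0, 2)), ("v1", "v2")), self._env([[0.0, 0.0]]))
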