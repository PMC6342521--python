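"""Depth calibration, rescaling, 3D labeling, singlet normalization."""

import collections

import numpy as np
import pytest

import gutfloc as g
from gutfloc.errors import EstimationError, SegmentationError
from gutfloc.segmentation import _CONNECTIVITY_RANK

VOX = (0.354, 0.39, 0.39)

_NEIGHBOR_OFFSETS = {
    conn: [
        (dz, dy, dx)
        for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
        and abs(dz) + abs(dy) + abs(dx) <= {6: 1, 18: 2, 26: 3}[conn]
    ]
    for conn in (6, 18, 26)
}


def flood_fill_component_sizes(binary, connectivity):
    """Independent reference labeling: breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    sizes = []
    offsets = _NEIGHBOR_OFFSETS[connectivity]
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        count = 0
        while queue:
            z, y, x = queue.pop()
            count += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < binary.shape[i] for i in range(3)) \
                        and binary[p] and not seen[p]:
                    seen[p] = True
                    queue.append(p)
        sizes.append(count)
    return sorted(sizes)


def _uniform_stack(n_slices=24, side=32, fg_value=30000, bg_value=500):
    """Stack with one bright 4x6x6 block per slice region, constant in depth."""
    v = np.full((n_slices, side, side), bg_value, dtype=np.uint16)
    v[:, 8:14, 8:14] = fg_value
    return g.ImageStack(v, VOX)


class TestCalibration:
    def test_depth_uniform_stack_gives_constant_lines(self):
        cal = g.calibrate_anchor_slices(_uniform_stack(), g.SegmentationConfig())
        assert np.allclose(cal.slice_max, cal.slice_max[0])
        assert np.allclose(cal.slice_min, cal.slice_min[0])
        assert cal.anchor_indices == (9, 14)

    def test_linear_decay_recovered(self):
        """Foreground median decaying 30000 -> 15000 over depth is recovered
        within 5% on every slice."""
        n = 40
        v = np.full((n, 32, 32), 500, dtype=np.uint16)
        line = np.linspace(30000, 15000, n)
        for i in range(n):
            v[i, 10:16, 10:16] = int(line[i])
        cal = g.calibrate_anchor_slices(g.ImageStack(v, VOX), g.SegmentationConfig())
        assert np.all(np.abs(cal.slice_max - line) / line < 0.05)

    def test_anchor_statistics_match_direct_measurement(self):
        stack = _uniform_stack()
        cfg = g.SegmentationConfig()
        cal = g.calibrate_anchor_slices(stack, cfg)
        from skimage.filters import threshold_otsu
        for idx in cal.anchor_indices:
            sl = stack.voxels[idx].astype(float)
            fg = sl > threshold_otsu(sl)
            assert cal.slice_max[idx] == pytest.approx(np.median(sl[fg]))
            bg = sl[~fg]
            assert cal.slice_min[idx] == pytest.approx(bg.mean() / 3 + 2 * bg.max() / 3)

    def test_uniform_stack_has_no_usable_anchor(self):
        from gutfloc.segmentation import CalibrationError
        v = np.full((24, 32, 32), 500, dtype=np.uint16)
        with pytest.raises(CalibrationError):
            g.calibrate_anchor_slices(g.ImageStack(v, VOX), g.SegmentationConfig())
        # the full chain degrades gracefully: empty table plus a warning
        with pytest.warns(UserWarning):
            out = g.aggregate_table_from_stack(g.ImageStack(v, VOX))
        assert len(out) == 0

    def test_nominal_anchor_without_objects_steps_inward(self):
        """A stack whose 10th slice is empty still calibrates, using the
        nearest slice that actually contains foreground."""
        v = np.full((30, 32, 32), 500, dtype=np.uint16)
        v[12:25, 8:14, 8:14] = 30000  # objects only in the middle/back
        cal = g.calibrate_anchor_slices(g.ImageStack(v, VOX), g.SegmentationConfig())
        assert cal.anchor_indices[0] >= 12
        assert np.all(cal.slice_min < cal.slice_max)

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError):
            g.ImageStack(np.zeros((10, 32, 32), dtype=np.uint16), VOX)


class TestRescale:
    def test_rank_order_preserved_within_band(self, rng):
        stack = _uniform_stack()
        cal = g.calibrate_anchor_slices(stack, g.SegmentationConfig())
        out = g.rescale_stack(stack, cal)
        sl_in = stack.voxels[5].astype(float)
        sl_out = out.voxels[5].astype(float)
        inside = (sl_in > cal.slice_min[5]) & (sl_in < cal.slice_max[5])
        order_in = np.argsort(sl_in[inside], kind="stable")
        assert np.all(np.diff(sl_out[inside][order_in]) >= 0)

    def test_all_background_maps_to_zero(self):
        stack = _uniform_stack()
        cal = g.CalibrationProfile(
            slice_max=np.full(stack.n_slices, 40000.0),
            slice_min=np.full(stack.n_slices, 35000.0),
        )
        out = g.rescale_stack(stack, cal)
        assert out.voxels.max() == 0

    def test_constant_calibration_equals_global_stretch(self, rng):
        """Oracle: with flat calibration lines, rescaling is one global
        linear stretch of the whole stack."""
        v = rng.integers(1000, 30000, size=(24, 16, 16)).astype(np.uint16)
        stack = g.ImageStack(v, VOX)
        lo, hi = 2000.0, 25000.0
        cal = g.CalibrationProfile(slice_max=np.full(24, hi), slice_min=np.full(24, lo))
        out = g.rescale_stack(stack, cal)
        expected = np.round(
            (np.clip(v.astype(float), lo, hi) - lo) / (hi - lo) * 65535
        ).astype(np.uint16)
        assert np.array_equal(out.voxels, expected)


class TestLabeling:
    def _two_cube_stack(self, gap_vector):
        v = np.zeros((24, 40, 40), dtype=np.uint16)
        v[2:7, 2:7, 2:7] = 60000
        z0, y0, x0 = 2 + np.array(gap_vector)
        v[z0:z0 + 5, y0:y0 + 5, x0:x0 + 5] = 60000
        return g.ImageStack(v, VOX)

    def test_two_disjoint_cubes(self):
        stack = self._two_cube_stack((0, 0, 12))
        vols = g.label_aggregates(stack, g.SegmentationConfig())
        assert len(vols) == 2
        assert np.allclose(vols, 125 * stack.voxel_volume)

    def test_corner_touching_cubes_depend_on_connectivity(self):
        stack = self._two_cube_stack((5, 5, 5))  # touch at a single corner pair
        assert len(g.label_aggregates(stack, g.SegmentationConfig(connectivity=26))) == 1
        assert len(g.label_aggregates(stack, g.SegmentationConfig(connectivity=6))) == 2

    def test_digitized_sphere_volume(self):
        r = 5
        zz, yy, xx = np.mgrid[:24, :24, :24]
        ball = ((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= r * r
        v = np.where(ball, 60000, 100).astype(np.uint16)
        vols = g.label_aggregates(g.ImageStack(v, (1.0, 1.0, 1.0)), g.SegmentationConfig())
        assert len(vols) == 1
        assert vols[0] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.10)

    def test_voxel_conservation(self, rng):
        """Every foreground voxel lands in exactly one object."""
        v = (rng.random((24, 32, 32)) < 0.2).astype(np.uint16) * 60000
        stack = g.ImageStack(v, VOX)
        vols = g.label_aggregates(stack, g.SegmentationConfig())
        n_fg = int((v > 0).sum())
        assert sum(vols) / stack.voxel_volume == pytest.approx(n_fg)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_against_flood_fill_oracle(self, connectivity, rng):
        """scipy-based labeling must agree exactly with an independent
        flood-fill on small random and exhaustive tiny instances."""
        # exhaustive over all 2x2x2 occupancy patterns
        for code in range(256):
            bits = np.array([(code >> k) & 1 for k in range(8)], dtype=bool)
            binary = bits.reshape(2, 2, 2)
            _, counts = g.connected_component_volumes(binary, connectivity)
            assert sorted(counts.tolist()) == flood_fill_component_sizes(binary, connectivity)
        # random denser instances up to 32³
        for density in (0.05, 0.3, 0.6):
            binary = rng.random((32, 32, 32)) < density
            _, counts = g.connected_component_volumes(binary, connectivity)
            assert sorted(counts.tolist()) == flood_fill_component_sizes(binary, connectivity)

    def test_slice_order_invariance(self, rng):
        v = (rng.random((24, 24, 24)) < 0.15).astype(np.uint16) * 50000
        stack = g.ImageStack(v, VOX)
        flipped = g.ImageStack(v[::-1].copy(), VOX)
        a = np.sort(g.label_aggregates(stack, g.SegmentationConfig()))
        b = np.sort(g.label_aggregates(flipped, g.SegmentationConfig()))
        assert np.allclose(a, b)


class TestSingletEstimate:
    def test_explicit_value_passthrough(self):
        cfg = g.SegmentationConfig(singlet_volume=0.52)
        assert g.singlet_volume_estimate(np.array([1.0, 2.0]), cfg) == 0.52

    def test_mode_of_singlet_population(self, rng):
        vols = np.concatenate([
            rng.normal(0.5, 0.03, 100).clip(0.3),   # singlets
            rng.normal(5.0, 0.5, 10).clip(3.0),     # large aggregates
        ])
        est = g.singlet_volume_estimate(vols, g.SegmentationConfig())
        assert est == pytest.approx(0.5, rel=0.10)

    def test_all_singlets_gives_median(self, rng):
        vols = rng.normal(0.5, 0.02, 60).clip(0.4)
        est = g.singlet_volume_estimate(vols, g.SegmentationConfig())
        assert est == pytest.approx(np.median(vols), rel=0.05)

    def test_too_few_objects_in_auto_mode(self):
        with pytest.raises(EstimationError):
            g.singlet_volume_estimate(np.ones(5), g.SegmentationConfig())


class TestFullChain:
    def test_singlet_only_stack_gives_all_ones(self, rng):
        spec = g.FixtureSpec(size_law="point", law_params={"value": 1},
                             n_aggregates=60, stack_shape=(40, 160, 160),
                             volume_um=(14.0, 62.0, 62.0), seed=2)
        table = g.sample_aggregate_sizes(spec)
        stack, _ = g.render_stack(table, spec)
        out = g.aggregate_table_from_stack(stack)
        assert len(out) == 60
        assert np.all(out.sizes == 1.0)
        assert g.volume_weighted_mean(out) == 1.0

    def test_known_composition_recovered(self):
        """Mixed fixture {1, 5, 20}: recovered ⟨N⟩ within 15% of truth."""
        sizes = np.array([1.0] * 80 + [5.0] * 12 + [20.0] * 2)
        spec = g.FixtureSpec(size_law="point", law_params={"value": 1},
                             n_aggregates=len(sizes), stack_shape=(56, 256, 256),
                             volume_um=(20.0, 100.0, 100.0), seed=5)
        stack, _ = g.render_stack(g.AggregateTable(sizes), spec)
        out = g.aggregate_table_from_stack(stack)
        truth = g.volume_weighted_mean(g.AggregateTable(sizes))
        assert g.volume_weighted_mean(out) == pytest.approx(truth, rel=0.15)

    def test_background_only_stack_warns_and_returns_empty(self, rng):
        v = rng.normal(800, 120, size=(24, 48, 48)).clip(0).astype(np.uint16)
        with pytest.warns(UserWarning):
            out = g.aggregate_table_from_stack(g.ImageStack(v, VOX))
        assert len(out) == 0
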