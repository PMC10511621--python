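"""Patch-pyramid geometry: level sizes, bounds, extraction, nesting."""

import numpy as np
import pytest
from scipy.stats import kstest

from patchwork3d.grid import VolumeGrid
from patchwork3d.pyramid import (
    PatchPyramidConfig,
    PatchSpec,
    draw_nested_child,
    extract_patch,
    level_sizes,
    patch_bounds,
    validate_chain,
)


class TestLevelSizes:
    def test_default_ladder(self):
        sizes = level_sizes(PatchPyramidConfig())
        assert sizes[0] == (150.0, 150.0 / 32)
        assert sizes[0][1] == pytest.approx(4.6875, abs=0)
        assert sizes[-1][0] == 32.0
        assert sizes[-1][1] == pytest.approx(1.0, abs=0)
        # intermediate level follows the geometric progression
        assert sizes[1][0] == pytest.approx(np.sqrt(150.0 * 32.0), rel=1e-12)
        assert sizes[1][1] == pytest.approx(np.sqrt(150.0 * 32.0) / 32, rel=1e-12)

    @pytest.mark.parametrize("n_levels", [2, 3, 4, 6])
    def test_spacing_strictly_decreases(self, n_levels):
        sizes = level_sizes(PatchPyramidConfig(n_levels=n_levels))
        spacings = [sp for _, sp in sizes]
        assert all(a > b for a, b in zip(spacings, spacings[1:]))
        assert all(abs(s / m - sp) < 1e-12 for (s, sp), m in zip(sizes, [32] * n_levels))

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            PatchPyramidConfig(n_levels=0)
        with pytest.raises(ValueError):
            PatchPyramidConfig(coarsest_fov_mm=20.0)  # finest (32 mm) >= coarsest


class TestPatchBounds:
    def test_symmetric_box(self):
        lo, hi = patch_bounds(PatchSpec(0, (0, 0, 0), 32.0))
        assert np.allclose(lo, -16) and np.allclose(hi, 16)

    def test_offset_box_and_side_length(self):
        spec = PatchSpec(1, (10.0, 0.0, 0.0), 2.0)
        lo, hi = patch_bounds(spec)
        assert lo[0] == pytest.approx(9.0) and hi[0] == pytest.approx(11.0)
        assert np.allclose(hi - lo, spec.size_mm)

    def test_nonfinite_center_rejected(self):
        with pytest.raises(ValueError):
            PatchSpec(0, (np.nan, 0, 0), 32.0)


def _brute_force_trilinear(data, coords, fill=0.0):
    """Independent trilinear oracle: loop over every sample point."""
    out = np.empty(coords.shape[1:])
    for idx in np.ndindex(out.shape):
        x, y, z = (coords[ax][idx] for ax in range(3))
        acc = 0.0
        x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wx = 1 - abs(x - (x0 + dx))
                    wy = 1 - abs(y - (y0 + dy))
                    wz = 1 - abs(z - (z0 + dz))
                    i, j, k = x0 + dx, y0 + dy, z0 + dz
                    if 0 <= i < data.shape[0] and 0 <= j < data.shape[1] and 0 <= k < data.shape[2]:
                        v = data[i, j, k]
                    else:
                        v = fill
                    acc += wx * wy * wz * v
        out[idx] = acc
    return out


class TestExtractPatch:
    def test_constant_volume(self):
        vol = VolumeGrid(np.full((40, 40, 40), 5.0, dtype=np.float32))
        patch = extract_patch(vol, PatchSpec(0, (20.0, 20.0, 20.0), 20.0), "image", 16)
        assert np.allclose(patch, 5.0)

    def test_aligned_subblock_is_bitwise_copy(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(48, 48, 48)).astype(np.float32)
        vol = VolumeGrid(data)
        # patch spacing 1 mm, matrix 32, lo at voxel edge 7.5 -> start index 8
        spec = PatchSpec(0, (23.5, 23.5, 23.5), 32.0)
        patch = extract_patch(vol, spec, "image", 32)
        assert patch.dtype == data.dtype
        assert np.array_equal(patch, data[8:40, 8:40, 8:40])

    def test_matches_brute_force_trilinear_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(20, 20, 20)).astype(np.float64)
        vol = VolumeGrid(data)
        spec = PatchSpec(0, (9.3, 10.7, 8.1), 13.7)
        patch = extract_patch(vol, spec, "image", 8)
        lo, _ = patch_bounds(spec)
        sp = spec.size_mm / 8
        ax = [(lo[d] + (np.arange(8) + 0.5) * sp) for d in range(3)]
        cx, cy, cz = np.meshgrid(*ax, indexing="ij")
        oracle = _brute_force_trilinear(data, np.stack([cx, cy, cz]))
        assert np.abs(patch - oracle).max() <= 1e-6

    def test_linear_ramp_at_offset(self):
        x = np.arange(30, dtype=np.float64)
        data = np.broadcast_to(x[:, None, None], (30, 30, 30)).copy()
        vol = VolumeGrid(data)
        spec = PatchSpec(0, (15.25, 15.0, 15.0), 10.0)
        patch = extract_patch(vol, spec, "image", 10)
        lo, _ = patch_bounds(spec)
        expected_x = lo[0] + (np.arange(10) + 0.5) * 1.0
        assert np.abs(patch[:, 5, 5] - expected_x).max() <= 1e-9

    def test_label_mode_nearest(self):
        data = np.zeros((10, 10, 10), dtype=np.uint8)
        data[4:6, 4:6, 4:6] = 2
        vol = VolumeGrid(data)
        patch = extract_patch(vol, PatchSpec(0, (4.5, 4.5, 4.5), 4.0), "label", 4)
        assert set(np.unique(patch)) <= {0, 2}

    def test_bad_mode(self):
        vol = VolumeGrid(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            extract_patch(vol, PatchSpec(0, (2, 2, 2), 2.0), "banana")


class TestNestedChildren:
    def test_equal_size_forces_center(self):
        cfg = PatchPyramidConfig()
        parent = PatchSpec(1, (10.0, 20.0, 30.0), 32.0)  # same size as the finest level
        child = draw_nested_child(parent, cfg, np.random.default_rng(0))
        assert np.allclose(child.center_mm, parent.center_mm)

    def test_containment_over_many_draws(self):
        cfg = PatchPyramidConfig()
        rng = np.random.default_rng(7)
        root = PatchSpec(0, (0.0, 0.0, 0.0), 150.0)
        for _ in range(2000):
            chain = [root]
            for _level in range(cfg.n_levels - 1):
                chain.append(draw_nested_child(chain[-1], cfg, rng))
            validate_chain(chain, cfg)  # raises on any containment violation

    def test_child_center_uniform(self):
        cfg = PatchPyramidConfig(n_levels=2)
        rng = np.random.default_rng(3)
        root = PatchSpec(0, (0.0, 0.0, 0.0), 150.0)
        slack = 0.5 * (150.0 - 32.0)
        centers = np.array(
            [draw_nested_child(root, cfg, rng).center_mm for _ in range(10_000)]
        )
        for ax in range(3):
            p = kstest(centers[:, ax], "uniform", args=(-slack, 2 * slack)).pvalue
            assert p > 0.01

    def test_finest_level_cannot_branch(self):
        cfg = PatchPyramidConfig()
        finest = PatchSpec(cfg.n_levels - 1, (0, 0, 0), 32.0)
        with pytest.raises(ValueError):
            draw_nested_child(finest, cfg, np.random.default_rng(0))


class TestGridRoundTrip:
    def test_world_voxel_inverse(self):
        vol = VolumeGrid(np.zeros((5, 6, 7)), spacing=(2.0, 2.0, 1.5), origin=(-3.0, 1.0, 0.5))
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 50, size=(100, 3))
        back = vol.voxel_to_world(vol.world_to_voxel(pts))
        assert np.abs(back - pts).max() <= 1e-9
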