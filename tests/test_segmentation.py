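import numpy as np
import pytest
from scipy import ndimage

from histovasc.segmentation import (
    SegmentationConfig,
    close_and_fill,
    contour_support_filter,
    despeckle,
    fuse,
    local_cutoff,
    moore_trace,
    otsu_cutoff,
    prepare,
    segment_contours,
    segment_interiors,
    segment_stack,
    temporal_consistency,
)


def _disc(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ring(shape, cy, cx, r_out, thickness):
    return _disc(shape, cy, cx, r_out) & ~_disc(shape, cy, cx, r_out - thickness)


class TestPrepare:
    def test_constant_image_stays_flat(self):
        img = np.full((64, 64, 3), 128, dtype=np.uint8)
        out = prepare(img)
        assert out.min() >= 0 and out.max() <= 1
        assert out.var() < 1e-6

    def test_median_removes_isolated_speck(self):
        img = np.full((32, 32), 0.9)
        img[16, 16] = 0.1
        cfg = SegmentationConfig(median_kernel_px=3)
        out = prepare((img * 255).astype(np.uint8), cfg)
        assert abs(out[16, 16] - out[0, 0]) < 0.05

    def test_output_range_and_dtype(self, small_phantom):
        _, _, slices, _ = small_phantom
        out = prepare(slices[0])
        assert out.dtype == float
        assert 0.0 <= out.min() and out.max() <= 1.0


class TestInteriorThreshold:
    def test_mid_gray_gives_empty(self):
        assert not segment_interiors(np.full((8, 8), 0.5)).any()

    def test_full_white_gives_full(self):
        assert segment_interiors(np.ones((8, 8))).all()

    def test_otsu_attains_exhaustive_scan_maximum(self, rng):
        """The recalibration threshold maximizes the between-class variance:
        an exhaustive scan over all 256 histogram splits finds no better one
        (ties are possible on the empty valley between modes, so the check is
        on the attained variance, not the split index)."""
        img = np.clip(
            np.concatenate([rng.normal(0.3, 0.05, 2000), rng.normal(0.8, 0.05, 2000)]),
            0,
            1,
        )
        got = otsu_cutoff(img)

        hist, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2

        def split_variance(k):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                return -np.inf
            m0 = (hist[:k] * centers[:k]).sum() / w0
            m1 = (hist[k:] * centers[k:]).sum() / w1
            return w0 * w1 * (m0 - m1) ** 2

        best = max(split_variance(k) for k in range(1, 256))
        k_got = int(np.searchsorted(centers, got, side="right"))
        assert split_variance(k_got) == pytest.approx(best, rel=1e-9)
        # and the threshold separates the two constructed modes
        assert 0.4 < got < 0.7


class TestLocalCutoff:
    def test_constant_tile_returns_mean(self):
        assert local_cutoff(np.full((10, 10), 0.37), x=5.0) == pytest.approx(0.37)

    def test_bimodal_tile_population_sigma(self):
        tile = np.array([0.0] * 50 + [100.0] * 50)
        # mu 50, population sigma 50 -> mu + 1*sigma = 100
        assert local_cutoff(tile, x=1.0) == pytest.approx(100.0)

    def test_x_zero_gives_mean(self, rng):
        tile = rng.random((16, 16))
        assert local_cutoff(tile, x=0.0) == pytest.approx(tile.mean())

    def test_empty_tile_rejected(self):
        with pytest.raises(ValueError):
            local_cutoff(np.empty((0, 0)), x=1.0)


class TestContourThreshold:
    def test_flat_image_gives_empty(self):
        assert not segment_contours(np.full((64, 64), 0.7)).any()

    def test_dark_rings_recovered(self, small_phantom):
        cfg_p, _, slices, truth = small_phantom
        scfg = SegmentationConfig()
        gray = prepare(slices[0], scfg)
        ring = truth.vessel_masks[0] & ~truth.lumen_masks[0]
        conts = segment_contours(gray, scfg)
        assert (conts & ring).sum() / ring.sum() >= 0.9

    def test_tiling_grid_shift_stability(self, small_phantom):
        """Shifting the tile grid by half a tile changes few of the marked
        pixels once the despeckle step has removed isolated noise marks
        (the pipeline always despeckles the raw contour mask)."""
        _, _, slices, _ = small_phantom
        scfg = SegmentationConfig(tile_px=128)
        gray = prepare(slices[0], scfg)
        a = despeckle(segment_contours(gray, scfg), scfg.despeckle_n)
        pad = 64
        shifted = np.pad(gray, ((pad, 0), (pad, 0)), mode="reflect")
        b = despeckle(segment_contours(shifted, scfg)[pad:, pad:], scfg.despeckle_n)
        changed = np.logical_xor(a, b).sum()
        assert changed < 0.05 * max(a.sum(), 1)


def _bbox_despeckle_oracle(mask, n):
    """Exhaustive per-component bounding-box check via BFS labeling,
    independent of the implementation's scipy path."""
    mask = mask.astype(bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    out = mask.copy()
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack, comp = [(sy, sx)], []
            seen[sy, sx] = True
            while stack:
                y, x = stack.pop()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            ys = [c[0] for c in comp]
            xs = [c[1] for c in comp]
            if (max(ys) - min(ys) + 1) <= n and (max(xs) - min(xs) + 1) <= n:
                for y, x in comp:
                    out[y, x] = False
    return out


class TestDespeckle:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not despeckle(mask, 3).any()

    def test_component_longer_than_window_kept(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 2:7] = True  # bounding box 5x1 with n=4
        np.testing.assert_array_equal(despeckle(mask, 4), mask)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_bbox_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.3
        np.testing.assert_array_equal(despeckle(mask, 4), _bbox_despeckle_oracle(mask, 4))


class TestMooreTrace:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        np.testing.assert_array_equal(moore_trace(mask), [[2, 2]])

    def test_square_boundary(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        traced = {tuple(p) for p in moore_trace(mask)}
        expected = {
            (y, x)
            for y in range(2, 6)
            for x in range(2, 6)
            if y in (2, 5) or x in (2, 5)
        }
        assert traced == expected

    def test_disc_boundary_is_thin_ring(self):
        mask = _disc((32, 32), 16, 16, 10)
        traced = moore_trace(mask)
        inner = ndimage.binary_erosion(mask, np.ones((3, 3)))
        boundary_set = {tuple(p) for p in np.argwhere(mask & ~inner)}
        assert {tuple(p) for p in traced} <= {tuple(p) for p in np.argwhere(mask)}
        # every 4-connected-boundary pixel is visited
        strict_boundary = mask & ~ndimage.binary_erosion(mask, ndimage.generate_binary_structure(2, 1))
        assert {tuple(p) for p in np.argwhere(strict_boundary)} <= {tuple(p) for p in traced} | boundary_set


class TestContourSupport:
    def test_fully_enclosed_disc_kept(self):
        interiors = _disc((64, 64), 32, 32, 10)
        contours = _ring((64, 64), 32, 32, 14, 3)
        kept, discarded = contour_support_filter(interiors, contours)
        np.testing.assert_array_equal(kept, interiors)
        assert not discarded.any()

    def test_no_contour_support_discarded(self):
        interiors = _disc((64, 64), 32, 32, 10)
        kept, discarded = contour_support_filter(interiors, np.zeros((64, 64), bool))
        assert not kept.any()
        np.testing.assert_array_equal(discarded, interiors)

    def test_half_ring_passes_45_percent_rule(self):
        interiors = _disc((64, 64), 32, 32, 10)
        yy = np.mgrid[:64, :64][0]
        half_ring = _ring((64, 64), 32, 32, 14, 3) & (yy <= 32)
        kept, _ = contour_support_filter(interiors, half_ring)
        np.testing.assert_array_equal(kept, interiors)

    def test_small_arc_fails_45_percent_rule(self):
        interiors = _disc((64, 64), 32, 32, 10)
        yy, xx = np.mgrid[:64, :64]
        quarter = _ring((64, 64), 32, 32, 14, 3) & (yy <= 32) & (xx <= 32)
        kept, discarded = contour_support_filter(interiors, quarter)
        assert not kept.any()
        np.testing.assert_array_equal(discarded, interiors)


class TestTemporalConsistency:
    def _masks(self):
        shape = (64, 64)
        persistent = _disc(shape, 20, 20, 6)
        return shape, persistent

    def test_structure_in_all_three_kept(self):
        shape, persistent = self._masks()
        out = temporal_consistency([persistent] * 3)
        np.testing.assert_array_equal(out, persistent)

    def test_center_only_structure_removed(self):
        shape, persistent = self._masks()
        lone = _disc(shape, 45, 45, 5)
        center = persistent | lone
        out = temporal_consistency([persistent, center, persistent])
        np.testing.assert_array_equal(out, persistent)

    def test_both_neighbor_structure_added_within_offset(self):
        shape, persistent = self._masks()
        a = persistent | _disc(shape, 45, 42, 5)
        c = persistent | _disc(shape, 45, 48, 5)  # 6 px away from a's copy
        out = temporal_consistency([a, persistent, c])
        added = out & ~persistent
        assert added.any()
        cy, cx = ndimage.center_of_mass(added)
        assert abs(cy - 45) < 2 and abs(cx - 45) < 2

    def test_far_neighbor_structures_not_added(self):
        shape, persistent = self._masks()
        a = persistent | _disc(shape, 45, 10, 4)
        c = persistent | _disc(shape, 45, 50, 4)  # 40 px apart: no match
        out = temporal_consistency([a, persistent, c])
        np.testing.assert_array_equal(out, persistent)

    def test_symmetric_under_window_reversal(self, rng):
        shape = (64, 64)
        masks = [
            ndimage.binary_dilation(rng.random(shape) < 0.01, iterations=2)
            for _ in range(3)
        ]
        fwd = temporal_consistency(masks)
        rev = temporal_consistency(masks[::-1])
        np.testing.assert_array_equal(fwd, rev)

    def test_wrong_window_length_rejected(self):
        with pytest.raises(ValueError, match="consistency_span"):
            temporal_consistency([np.zeros((4, 4), bool)] * 2)


class TestFuse:
    def test_empty_neutral(self, rng):
        m = rng.random((16, 16)) < 0.4
        empty = np.zeros_like(m)
        np.testing.assert_array_equal(fuse(m, empty), m)
        np.testing.assert_array_equal(fuse(empty, m), m)

    def test_elementwise_or_oracle(self, rng):
        a = rng.random((16, 16)) < 0.4
        b = rng.random((16, 16)) < 0.4
        np.testing.assert_array_equal(fuse(a, b), a | b)


class TestCloseAndFill:
    def test_closed_ring_center_filled(self):
        ring = _ring((64, 64), 32, 32, 12, 3)
        final, rejected = close_and_fill(ring, a_max=1000.0)
        assert final[32, 32]
        assert not rejected.any()

    def test_gapped_ring_closed_and_filled(self):
        ring = _ring((64, 64), 32, 32, 12, 3)
        ring[29:35, 42:] = False  # 6 px gap in the ring
        final, _ = close_and_fill(ring, a_max=1000.0, cfg=SegmentationConfig(gap_disc_px=5))
        assert final[32, 32]

    def test_oversized_fill_rejected(self):
        # C-shaped contour whose fill would far exceed the largest vessel
        ring = _ring((128, 128), 64, 64, 50, 3)
        ring[61:66, 110:] = False
        a_max = 400.0  # "biggest vessel" much smaller than the C's interior
        final, rejected = close_and_fill(ring, a_max=a_max)
        assert not final[64, 64]
        assert rejected.any()
        np.testing.assert_array_equal(final & ring, ring)

    def test_separate_blobs_not_bridged(self):
        blobs = _disc((64, 64), 32, 20, 8) | _disc((64, 64), 32, 44, 8)
        final, _ = close_and_fill(blobs, a_max=500.0)
        assert ndimage.label(final, np.ones((3, 3)))[1] == 2

    def test_empty_input(self):
        final, rejected = close_and_fill(np.zeros((8, 8), bool), a_max=10.0)
        assert not final.any() and not rejected.any()


class TestSegmentStack:
    def test_clean_phantom_dice_per_slice(self, small_phantom):
        _, _, slices, truth = small_phantom
        segs = segment_stack(slices, SegmentationConfig())
        for seg, tm in zip(segs, truth.vessel_masks):
            dice = 2 * (seg.final & tm).sum() / (seg.final.sum() + tm.sum())
            assert dice >= 0.8

    def test_worker_count_does_not_change_masks(self, small_phantom):
        _, _, slices, _ = small_phantom
        segs1 = segment_stack(slices[:3], SegmentationConfig(), workers=1)
        segs4 = segment_stack(slices[:3], SegmentationConfig(), workers=4)
        for a, b in zip(segs1, segs4):
            np.testing.assert_array_equal(a.final, b.final)
            np.testing.assert_array_equal(a.interiors, b.interiors)

    def test_single_slice_fissures_removed(self):
        from histovasc.phantom import PhantomConfig, generate_phantom

        cfg = PhantomConfig(
            volume_vox=(6, 256, 256),
            n_vessels=3,
            radius_range_vox=(8, 16),
            branching_prob=0.0,
            misalign_max_rotation_deg=0.0,
            misalign_max_translation_px=0.0,
            misalign_max_scale_dev=0.0,
            artifact_rate=1.5,
            seed=21,
        )
        slices, truth = generate_phantom(cfg)
        segs = segment_stack(slices, SegmentationConfig())
        # artifact pixels (single-slice damage) should largely disappear
        art_total = sum(a.sum() for a in truth.artifact_masks)
        art_kept = sum(
            (seg.final & art).sum() for seg, art in zip(segs, truth.artifact_masks)
        )
        assert art_total > 0
        assert art_kept / art_total < 0.35

    def test_masks_binary_and_shapes_preserved(self, small_phantom):
        _, _, slices, _ = small_phantom
        segs = segment_stack(slices[:3], SegmentationConfig())
        for seg in segs:
            for m in (seg.interiors, seg.contours, seg.fused, seg.final, seg.discarded):
                assert m.dtype == bool
                assert m.shape == slices[0].shape
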