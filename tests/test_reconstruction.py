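import numpy as np
import pytest
from scipy import ndimage

from histovasc.image_io import VoxelVolume
from histovasc.reconstruction import (
    ReconstructionConfig,
    interpolate_gaps,
    network_stats,
    prune_inconsistent,
    reconstruct,
    smooth_binarize,
)


def _brute_counts(vol, zlo, zhi, ylo, yhi, xlo, xhi):
    """Per-voxel neighbor count by explicit loops: exhaustive, clipped at the
    boundary, excluding the examined voxel."""
    Z, Y, X = vol.shape
    out = np.zeros(vol.shape, dtype=int)
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                c = 0
                for dz in range(zlo, zhi + 1):
                    for dy in range(ylo, yhi + 1):
                        for dx in range(xlo, xhi + 1):
                            if dz == 0 and dy == 0 and dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if 0 <= zz < Z and 0 <= yy < Y and 0 <= xx < X and vol[zz, yy, xx]:
                                c += 1
                out[z, y, x] = c
    return out


def _brute_interpolate(vol, min_set=15):
    counts = _brute_counts(vol, -5, 4, -1, 1, -1, 1)
    return vol | (~vol & (counts >= min_set))


def _brute_prune(vol, original, min_set=10):
    counts = _brute_counts(original, -1, 1, -1, 1, -1, 1)
    return vol & (counts >= min_set)


class TestInterpolateGaps:
    def test_empty_and_full_are_fixed_points(self):
        for fill in (False, True):
            v = VoxelVolume(np.full((12, 6, 6), fill))
            np.testing.assert_array_equal(interpolate_gaps(v).occupancy, v.occupancy)

    def test_exact_threshold_15_vs_14(self, rng):
        """A voxel with exactly 15 set neighbors in its 3x3x10 neighborhood
        is set; with 14 it stays unset."""
        for n_set, expect in ((15, True), (14, False)):
            vol = np.zeros((14, 5, 5), dtype=bool)
            # neighborhood of voxel (7,2,2): z offsets -5..+4 -> z 2..11
            coords = [
                (z, y, x)
                for z in range(2, 12)
                for y in (1, 2, 3)
                for x in (1, 2, 3)
                if (z, y, x) != (7, 2, 2)
            ]
            for z, y, x in coords[:n_set]:
                vol[z, y, x] = True
            vol[7, 2, 2] = False
            # neighbors of (7,2,2) may themselves gain voxels; only the
            # examined voxel's outcome is asserted
            out = interpolate_gaps(VoxelVolume(vol)).occupancy
            assert out[7, 2, 2] == expect

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.random((12, 12, 16)) < 0.35
        got = interpolate_gaps(VoxelVolume(vol)).occupancy
        np.testing.assert_array_equal(got, _brute_interpolate(vol))

    def test_monotone_non_decreasing(self, rng):
        vol = rng.random((12, 10, 10)) < 0.3
        out = interpolate_gaps(VoxelVolume(vol)).occupancy
        assert np.all(out[vol])


class TestPruneInconsistent:
    def test_solid_block_interior_kept(self):
        vol = np.zeros((7, 7, 7), dtype=bool)
        vol[1:6, 1:6, 1:6] = True
        v = VoxelVolume(vol)
        out = prune_inconsistent(v, v).occupancy
        assert out[3, 3, 3]

    def test_isolated_voxel_discarded(self):
        vol = np.zeros((5, 5, 5), dtype=bool)
        vol[2, 2, 2] = True
        v = VoxelVolume(vol)
        assert not prune_inconsistent(v, v).occupancy.any()

    def test_exact_threshold_10_vs_9(self):
        for n_set, expect in ((10, True), (9, False)):
            vol = np.zeros((5, 5, 5), dtype=bool)
            coords = [
                (z, y, x)
                for z in (1, 2, 3)
                for y in (1, 2, 3)
                for x in (1, 2, 3)
                if (z, y, x) != (2, 2, 2)
            ]
            for z, y, x in coords[:n_set]:
                vol[z, y, x] = True
            vol[2, 2, 2] = True
            v = VoxelVolume(vol)
            assert prune_inconsistent(v, v).occupancy[2, 2, 2] == expect

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        original = rng.random((12, 12, 16)) < 0.4
        vol = original | (rng.random((12, 12, 16)) < 0.1)
        got = prune_inconsistent(VoxelVolume(vol), VoxelVolume(original)).occupancy
        np.testing.assert_array_equal(got, _brute_prune(vol, original))

    def test_never_adds_voxels(self, rng):
        original = rng.random((10, 8, 8)) < 0.4
        vol = rng.random((10, 8, 8)) < 0.4
        out = prune_inconsistent(VoxelVolume(vol), VoxelVolume(original)).occupancy
        assert not np.any(out & ~vol)

    def test_shape_mismatch_rejected(self):
        a = VoxelVolume(np.ones((3, 4, 4), bool))
        b = VoxelVolume(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="shape"):
            prune_inconsistent(a, b)


class TestSmoothBinarize:
    def test_empty_and_full_preserved(self):
        for fill in (False, True):
            v = VoxelVolume(np.full((8, 8, 8), fill))
            np.testing.assert_array_equal(smooth_binarize(v).occupancy, v.occupancy)

    def test_half_space_interface_stable(self):
        vol = np.zeros((16, 16, 16), dtype=bool)
        vol[:8] = True
        cfg = ReconstructionConfig(gaussian_sigma_vox=(1.0, 1.0, 1.0), binarize_threshold=0.5)
        out = smooth_binarize(VoxelVolume(vol), cfg).occupancy
        # symmetric Gaussian about the interface: boundary moves < 1 voxel
        assert out[:7, 8, 8].all() and not out[9:, 8, 8].any()

    def test_ball_volume_change_small(self):
        zz, yy, xx = np.mgrid[:24, :24, :24]
        ball = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 64
        out = smooth_binarize(VoxelVolume(ball)).occupancy
        assert abs(out.sum() - ball.sum()) / ball.sum() < 0.10


def _disc2d(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


class TestReconstruct:
    def test_identical_discs_give_one_cylinder(self):
        disc = _disc2d((40, 40), 20, 20, 8)
        vol = reconstruct([disc] * 12)
        labels, n = ndimage.label(vol.occupancy, np.ones((3, 3, 3)))
        assert n == 1

    def test_two_slice_gap_bridged(self):
        """A vessel absent on 2 consecutive slices reconstructs as one
        connected component thanks to the z-reach-10 interpolation rule."""
        disc = _disc2d((40, 40), 20, 20, 8)
        empty = np.zeros((40, 40), dtype=bool)
        masks = [disc] * 5 + [empty] * 2 + [disc] * 5
        vol = reconstruct(masks)
        labels, n = ndimage.label(vol.occupancy, np.ones((3, 3, 3)))
        assert n == 1

    def test_single_slice_debris_removed(self):
        """A structure on exactly one slice (e.g. a damage artifact that
        survived 2D cleanup) is erased by the consistency pruning."""
        disc = _disc2d((40, 40), 20, 20, 8)
        debris = _disc2d((40, 40), 8, 32, 4)
        empty = np.zeros((40, 40), dtype=bool)
        masks = [empty] * 4 + [debris] + [empty] * 4
        vol = reconstruct(masks)
        assert not vol.occupancy.any()

        # sanity: the same pipeline keeps a persistent vessel
        vol2 = reconstruct([disc] * 9)
        assert vol2.occupancy.any()

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            reconstruct([])


class TestNetworkStats:
    def test_empty_volume(self):
        stats = network_stats(VoxelVolume(np.zeros((4, 8, 8), bool)))
        assert stats.vessel_count == 0

    def test_two_disjoint_tubes(self):
        masks = np.zeros((10, 40, 40), dtype=bool)
        masks[:, :, :] |= _disc2d((40, 40), 10, 10, 5)[None]
        masks |= _disc2d((40, 40), 30, 30, 5)[None]
        stats = network_stats(VoxelVolume(masks))
        assert stats.vessel_count == 2

    def test_cylinder_diameter_analytic(self):
        """A straight tube of radius 25 voxels at 0.5 um/voxel has a true
        diameter of 25 um; the medial-axis EDT estimate lands within 10%."""
        disc = _disc2d((64, 64), 32, 32, 25)
        vol = VoxelVolume(np.stack([disc] * 12), spacing_um=(2.5, 0.5, 0.5))
        stats = network_stats(vol)
        assert stats.vessel_count == 1
        assert stats.diameters_um[0][1] == pytest.approx(25.0, rel=0.10)

    def test_axial_extent_169_slices(self):
        vol = VoxelVolume(np.zeros((169, 4, 4), dtype=bool), spacing_um=(2.5, 0.5, 0.5))
        assert vol.z_extent_um == pytest.approx(422.5)
        assert network_stats(vol).z_extent_um == pytest.approx(422.5)
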