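import numpy as np
import pytest
from scipy import ndimage as ndi

from rootvoi import (
    Seed,
    SeedSet,
    Volume,
    median_filter_3d,
    segment_quadrant,
    sobel_gradient_magnitude,
    watershed_from_seeds,
)
from rootvoi.segmentation import GradientVolume

from .oracles import flood_reference, median_filter_reference, sobel_magnitude_reference


def vol(data, vs=10.4):
    return Volume(np.asarray(data, dtype=float), vs)


class TestMedianFilter:
    def test_constant_volume_is_fixed_point(self):
        v = vol(np.full((6, 6, 6), 3.5))
        for iters in (1, 3):
            out = median_filter_3d(v, iters)
            np.testing.assert_array_equal(out.data, v.data)

    def test_single_impulse_removed_in_one_iteration(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 100.0
        out = median_filter_3d(vol(data), 1)
        assert out.data.max() == 0.0

    def test_matches_brute_force_oracle_on_random_volume(self, rng):
        data = rng.integers(0, 50, (5, 5, 5)).astype(float)
        out = median_filter_3d(vol(data), 1)
        np.testing.assert_array_equal(out.data, median_filter_reference(data))

    def test_iterations_compose(self, rng):
        data = rng.integers(0, 50, (5, 5, 5)).astype(float)
        two = median_filter_3d(vol(data), 2).data
        once_twice = median_filter_3d(median_filter_3d(vol(data), 1), 1).data
        np.testing.assert_array_equal(two, once_twice)

    def test_invalid_iterations(self):
        with pytest.raises(ValueError):
            median_filter_3d(vol(np.zeros((3, 3, 3))), 0)


class TestSobel:
    def test_constant_volume_has_zero_gradient(self):
        g = sobel_gradient_magnitude(vol(np.full((6, 6, 6), 7.0)))
        assert np.all(g.data == 0.0)

    def test_axis_ramp_constant_interior_magnitude(self):
        data = np.arange(8)[:, None, None] * 2.0 * np.ones((8, 8, 8))
        g = sobel_gradient_magnitude(vol(data))
        ref = sobel_magnitude_reference(data)
        np.testing.assert_allclose(g.data, ref)
        interior = g.data[2:-2, 2:-2, 2:-2]
        # separable Sobel on slope s: derivative 2s, smoothing x16 -> 32 s
        np.testing.assert_allclose(interior, 32 * 2.0)

    def test_step_response_peaks_on_interface(self, rng):
        data = np.zeros((10, 6, 6))
        data[5:] = 50.0
        g = sobel_gradient_magnitude(vol(data))
        ref = sobel_magnitude_reference(data)
        np.testing.assert_allclose(g.data, ref)
        profile = g.data[:, 3, 3]
        assert set(np.flatnonzero(profile == profile.max())) == {4, 5}

    def test_non_negative(self, rng):
        g = sobel_gradient_magnitude(vol(rng.random((6, 6, 6))))
        assert np.all(g.data >= 0)


def grad_vol(data, vs=10.4):
    return GradientVolume(np.asarray(data, dtype=float), vs)


class TestWatershed:
    def test_seeds_covering_every_voxel_reproduce_labeling(self, rng):
        shape = (4, 4, 4)
        target = rng.integers(0, 2, shape)
        seeds = [
            Seed("air" if target[i, j, k] == 0 else "bone", (i, j, k))
            for i in range(4)
            for j in range(4)
            for k in range(4)
        ]
        lab = watershed_from_seeds(grad_vol(rng.random(shape)), SeedSet(seeds))
        expect = np.where(target == 0, lab.id_of("air"), lab.id_of("bone"))
        np.testing.assert_array_equal(lab.labels, expect)

    def test_split_exactly_at_gradient_ridge(self):
        g = np.zeros((20, 5, 5))
        g[10] = 100.0  # ridge plane at i = 10
        seeds = SeedSet([Seed("air", (2, 2, 2)), Seed("bone", (17, 2, 2))])
        lab = watershed_from_seeds(grad_vol(g), seeds)
        ref = flood_reference(g, _markers(lab, seeds, g.shape))
        np.testing.assert_array_equal(lab.labels, ref)
        assert np.all(lab.labels[:10] == lab.id_of("air"))
        assert np.all(lab.labels[11:] == lab.id_of("bone"))

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_priority_flood_oracle(self, trial):
        rng = np.random.default_rng(trial)
        shape = (9, 8, 7)
        # integer-valued gradients exercise the plateau tie-break
        g = rng.integers(0, 4, shape).astype(float) if trial % 2 else rng.random(shape)
        names = ["air", "bone", "tooth"][: int(rng.integers(2, 4))]
        seeds = []
        placed = set()
        for name in names:
            while True:
                p = tuple(int(rng.integers(0, s)) for s in shape)
                if p not in placed:
                    placed.add(p)
                    seeds.append(Seed(name, p))
                    break
        seeds = SeedSet(seeds)
        lab = watershed_from_seeds(grad_vol(g), seeds)
        ref = flood_reference(g, _markers(lab, seeds, shape))
        np.testing.assert_array_equal(lab.labels, ref)

    def test_partition_and_seed_retention(self, rng):
        shape = (10, 10, 10)
        g = rng.random(shape)
        seeds = SeedSet([Seed("air", (0, 0, 0)), Seed("bone", (9, 9, 9)), Seed("bone", (5, 5, 5))])
        lab = watershed_from_seeds(grad_vol(g), seeds)
        assert np.all(lab.labels > 0)  # full partition
        counts = np.bincount(lab.labels.ravel())
        assert counts.sum() == np.prod(shape)
        assert lab.labels[0, 0, 0] == lab.id_of("air")
        assert lab.labels[9, 9, 9] == lab.id_of("bone")
        assert lab.labels[5, 5, 5] == lab.id_of("bone")

    def test_deterministic(self, rng):
        g = rng.random((8, 8, 8))
        seeds = SeedSet([Seed("air", (0, 0, 0)), Seed("bone", (7, 7, 7))])
        a = watershed_from_seeds(grad_vol(g), seeds)
        b = watershed_from_seeds(grad_vol(g), seeds)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_conflicting_seeds_rejected(self):
        g = grad_vol(np.zeros((4, 4, 4)))
        seeds = SeedSet([Seed("air", (1, 1, 1)), Seed("bone", (1, 1, 1))])
        with pytest.raises(ValueError, match="conflicting"):
            watershed_from_seeds(g, seeds)

    def test_single_label_rejected(self):
        g = grad_vol(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match=">= 2"):
            watershed_from_seeds(g, SeedSet([Seed("air", (0, 0, 0))]))


def _markers(lab, seeds, shape):
    markers = np.zeros(shape, dtype=np.int32)
    for s in seeds.seeds:
        markers[s.ijk] = lab.id_of(s.label)
    return markers


class TestSegmentQuadrant:
    def test_phantom_tissue_dice(self, small_phantom):
        volume, truth, seeds, _ = small_phantom
        lab = segment_quadrant(volume, seeds)
        t = truth.label_map.labels
        for name in ("tooth", "bone"):
            lid = truth.label_map.id_of(name)
            a, b = lab.labels == lid, t == lid
            dice = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
            assert dice >= 0.90, f"{name} dice {dice:.3f}"

    def test_composition_is_deterministic(self, small_phantom):
        volume, _, seeds, _ = small_phantom
        a = segment_quadrant(volume, seeds)
        b = segment_quadrant(volume, seeds)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_air_only_volume_floods_to_full_partition(self, rng):
        volume = Volume(rng.normal(20, 1, (12, 12, 12)), 10.4)
        seeds = SeedSet([Seed("air", (1, 1, 1)), Seed("bone", (6, 6, 6)), Seed("tooth", (10, 10, 10))])
        lab = segment_quadrant(volume, seeds, 1)
        assert np.all(lab.labels > 0)
        assert np.bincount(lab.labels.ravel()).sum() == 12**3

    def test_extra_seed_in_correct_region_is_stable_noise_free(self, noise_free_phantom):
        volume, truth, seeds, _ = noise_free_phantom
        lab = segment_quadrant(volume, seeds)
        # add one more bone seed deep inside bone
        bone = truth.label_map.labels == truth.label_map.id_of("bone")
        edt = ndi.distance_transform_edt(bone)
        extra = tuple(int(c) for c in np.unravel_index(np.argmax(edt), edt.shape))
        seeds2 = SeedSet(seeds.seeds + [Seed("bone", extra)])
        lab2 = segment_quadrant(volume, seeds2)
        t = truth.label_map.labels
        band = np.zeros(t.shape, dtype=bool)
        for lid in np.unique(t):
            m = t == lid
            band |= m ^ ndi.binary_erosion(m)
        band = ndi.binary_dilation(band)
        np.testing.assert_array_equal(lab.labels[~band], lab2.labels[~band])
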