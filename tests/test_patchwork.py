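import itertools

import numpy as np
import pytest
from scipy import stats

from c2fseg import (ImageVolume, LabelVolume, ProbabilityVolume, SubVolumeSpec,
                    crop, fuse_patches, sample_training_subvolume, tile_volume)


def brute_force_cover(shape, patch, overlap):
    """Independent enumerator of the clamped-stride window set."""
    per_axis = []
    for s, p, o in zip(shape, patch, overlap):
        stride = p - o
        starts = sorted({min(st, s - p) for st in range(0, s, stride) if min(st, s - p) >= 0})
        starts = [st for st in starts if st % stride == 0 or st == s - p]
        per_axis.append(starts)
    return {tuple(c) for c in itertools.product(*per_axis)}


class TestCrop:
    def test_whole_volume_identity(self, random_volume):
        spec = SubVolumeSpec(start=(0, 0, 0), size=random_volume.shape)
        out = crop(random_volume, spec)
        assert np.array_equal(out.data, random_volume.data)
        assert out.spacing == random_volume.spacing

    def test_single_voxel(self, random_volume):
        out = crop(random_volume, SubVolumeSpec(start=(2, 3, 4), size=(1, 1, 1)))
        assert out.data[0, 0, 0] == random_volume.data[2, 3, 4]

    def test_matches_direct_slice(self, random_volume, rng):
        for _ in range(20):
            start = tuple(int(rng.integers(0, s - 2)) for s in random_volume.shape)
            size = tuple(int(rng.integers(1, s - st + 1))
                         for s, st in zip(random_volume.shape, start))
            spec = SubVolumeSpec(start=start, size=size)
            expected = random_volume.data[spec.slices]
            assert np.array_equal(crop(random_volume, spec).data, expected)

    def test_out_of_bounds(self, random_volume):
        with pytest.raises(ValueError):
            crop(random_volume, SubVolumeSpec(start=(5, 0, 0), size=(5, 1, 1)))


class TestSampling:
    def _pair(self, rng, shape=(8, 16, 16)):
        img = ImageVolume(data=rng.normal(size=shape))
        lbl_data = np.zeros(shape, dtype=np.uint8)
        lbl_data[4:6, 6:9, 6:9] = 1
        return img, LabelVolume(data=lbl_data)

    def test_positive_fraction_one_always_hits_foreground(self, rng):
        img, lbl = self._pair(rng)
        for _ in range(100):
            _, lp = sample_training_subvolume(img, lbl, (4, 8, 8), 1.0, rng)
            assert lp.data.sum() >= 1

    def test_uniform_starts_chi_square(self, rng):
        img, lbl = self._pair(rng)
        size = (4, 8, 8)
        rng2 = np.random.default_rng(7)
        counts = {ax: np.zeros(img.shape[ax] - size[ax] + 1) for ax in range(3)}
        for _ in range(1000):
            ipatch, _ = sample_training_subvolume(img, lbl, size, 0.0, rng2)
            # locate the patch by its first voxel value (intensities are unique floats)
            pos = np.argwhere(img.data == ipatch.data[0, 0, 0])[0]
            for ax in range(3):
                counts[ax][pos[ax]] += 1
        for ax in range(3):
            p = stats.chisquare(counts[ax]).pvalue
            assert p > 1e-3

    def test_same_seed_same_patch(self):
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        img, lbl = self._pair(np.random.default_rng(0))
        pa, la = sample_training_subvolume(img, lbl, (4, 8, 8), 0.5, rng_a)
        pb, lb = sample_training_subvolume(img, lbl, (4, 8, 8), 0.5, rng_b)
        assert np.array_equal(pa.data, pb.data)
        assert np.array_equal(la.data, lb.data)

    def test_empty_label_falls_back_with_warning(self, rng):
        img = ImageVolume(data=rng.normal(size=(8, 8, 8)))
        lbl = LabelVolume(data=np.zeros((8, 8, 8), dtype=np.uint8))
        with pytest.warns(UserWarning, match="empty"):
            sample_training_subvolume(img, lbl, (4, 4, 4), 1.0, rng)

    def test_volume_smaller_than_patch(self, rng):
        img, lbl = self._pair(rng)
        with pytest.raises(ValueError):
            sample_training_subvolume(img, lbl, (16, 8, 8), 0.5, rng)


class TestTiling:
    def test_exact_fit_single_window(self):
        specs = tile_volume((64, 128, 128), (64, 128, 128), 0)
        assert specs == [SubVolumeSpec(start=(0, 0, 0), size=(64, 128, 128))]

    def test_two_windows(self):
        specs = tile_volume((64, 256, 128), (64, 128, 128), 0)
        assert len(specs) == 2

    def test_matches_brute_force_cover(self):
        shape, patch, overlap = (70, 140, 150), (64, 128, 128), (8, 16, 16)
        specs = tile_volume(shape, patch, overlap)
        assert {s.start for s in specs} == brute_force_cover(shape, patch, overlap)
        covered = np.zeros(shape, dtype=int)
        for s in specs:
            covered[s.slices] += 1
        assert (covered >= 1).all()

    def test_overlap_must_be_smaller_than_patch(self):
        with pytest.raises(ValueError):
            tile_volume((64, 128, 128), (64, 128, 128), (64, 0, 0))


class TestFusion:
    def test_single_patch_identity(self, rng):
        vol = rng.random((6, 8, 8))
        spec = SubVolumeSpec(start=(0, 0, 0), size=(6, 8, 8))
        out = fuse_patches([spec], [vol], (6, 8, 8))
        assert np.array_equal(out.data, vol)

    def test_mean_of_two_overlapping(self):
        s1 = SubVolumeSpec(start=(0, 0, 0), size=(2, 4, 4))
        s2 = SubVolumeSpec(start=(0, 2, 0), size=(2, 4, 4))
        out = fuse_patches([s1, s2], [np.zeros((2, 4, 4)), np.ones((2, 4, 4))], (2, 6, 4))
        assert (out.data[:, :2] == 0).all()
        assert (out.data[:, 2:4] == 0.5).all()
        assert (out.data[:, 4:] == 1).all()

    def test_matches_accumulation_oracle(self, rng):
        shape = (10, 20, 18)
        specs = tile_volume(shape, (6, 8, 8), (2, 2, 2))
        patches = [rng.random(s.size) for s in specs]
        fused = fuse_patches(specs, patches, shape)
        acc = np.zeros(shape)
        cnt = np.zeros(shape)
        for s, p in zip(specs, patches):
            acc[s.slices] += p
            cnt[s.slices] += 1
        assert np.allclose(fused.data, acc / cnt, atol=0, rtol=0)

    @pytest.mark.parametrize("overlap", [(0, 0, 0), (2, 3, 3)])
    def test_round_trip_reconstruction(self, rng, overlap):
        shape = (12, 18, 16)
        vol = ProbabilityVolume(data=rng.random(shape))
        specs = tile_volume(shape, (4, 6, 8), overlap)
        patches = [crop(vol, s).data for s in specs]
        out = fuse_patches(specs, patches, shape)
        assert np.allclose(out.data, vol.data, atol=1e-15)

    def test_bounded_by_patch_extremes(self, rng):
        shape = (8, 8, 8)
        specs = tile_volume(shape, (4, 4, 4), (2, 2, 2))
        patches = [rng.random(s.size) for s in specs]
        fused = fuse_patches(specs, patches, shape)
        lo = np.full(shape, np.inf)
        hi = np.full(shape, -np.inf)
        for s, p in zip(specs, patches):
            lo[s.slices] = np.minimum(lo[s.slices], p)
            hi[s.slices] = np.maximum(hi[s.slices], p)
        assert (fused.data >= lo - 1e-12).all() and (fused.data <= hi + 1e-12).all()

    def test_uncovered_voxel_is_error(self):
        spec = SubVolumeSpec(start=(0, 0, 0), size=(2, 2, 2))
        with pytest.raises(ValueError, match="uncovered"):
            fuse_patches([spec], [np.zeros((2, 2, 2))], (4, 2, 2))
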