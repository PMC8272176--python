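"""I/O, normalization, splits/folds and augmentation properties."""

import numpy as np
import pytest

from casenet.data_io import (
    AugmentationSpec,
    SliceSample,
    augment,
    load_volume,
    make_folds,
    normalize_intensity,
    save_volume,
    split_patients,
)


def _sample(image, mask, pid="p0", idx=0):
    return SliceSample(image=image, mask=mask, patient_id=pid, slice_index=idx)


class TestSliceSample:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            _sample(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            _sample(np.zeros((4, 4)), np.full((4, 4), 2))


class TestVolumeIO:
    def test_nifti_round_trip_exact(self, tmp_path, rng):
        img = rng.random((4, 8, 8)).astype(np.float32)
        msk = (rng.random((4, 8, 8)) > 0.5).astype(np.uint8)
        save_volume(img, tmp_path / "img.nii.gz")
        save_volume(msk, tmp_path / "msk.nii.gz")
        samples = load_volume(tmp_path / "img.nii.gz", tmp_path / "msk.nii.gz")
        assert len(samples) == 4
        for i, s in enumerate(samples):
            np.testing.assert_array_equal(s.image, img[i])
            np.testing.assert_array_equal(s.mask, msk[i])

    def test_mask_binarized_at_positive(self, tmp_path):
        img = np.zeros((2, 4, 4), dtype=np.float32)
        msk = np.zeros((2, 4, 4), dtype=np.uint8)
        msk[0, :2] = 255
        save_volume(img, tmp_path / "i.nii")
        save_volume(msk, tmp_path / "m.nii")
        samples = load_volume(tmp_path / "i.nii", tmp_path / "m.nii")
        assert set(np.unique(samples[0].mask)) == {0, 1}

    def test_shape_mismatch_names_both_files(self, tmp_path):
        save_volume(np.zeros((2, 4, 4)), tmp_path / "i.nii")
        save_volume(np.zeros((2, 5, 5)), tmp_path / "m.nii")
        with pytest.raises(ValueError, match="i.nii.*m.nii"):
            load_volume(tmp_path / "i.nii", tmp_path / "m.nii")

    def test_unsupported_format_lists_supported(self, tmp_path):
        bad = tmp_path / "vol.mha"
        bad.write_text("")
        with pytest.raises(ValueError, match="NIfTI"):
            load_volume(bad, bad)

    def test_png_directory_dialect(self, tmp_path, rng):
        import imageio.v3 as iio

        (tmp_path / "img").mkdir()
        (tmp_path / "msk").mkdir()
        imgs = (rng.random((3, 6, 6)) * 255).astype(np.uint8)
        msks = (rng.random((3, 6, 6)) > 0.5).astype(np.uint8) * 255
        for i in range(3):
            iio.imwrite(tmp_path / "img" / f"s{i}.png", imgs[i])
            iio.imwrite(tmp_path / "msk" / f"s{i}.png", msks[i])
        samples = load_volume(tmp_path / "img", tmp_path / "msk")
        assert len(samples) == 3
        np.testing.assert_array_equal(samples[1].image, imgs[1].astype(np.float32))
        np.testing.assert_array_equal(samples[1].mask, (msks[1] > 0).astype(np.uint8))


class TestNormalize:
    def test_minmax_affine(self):
        img = np.array([[10.0, 30.0], [20.0, 10.0]])
        out = normalize_intensity(img)
        np.testing.assert_allclose(out, (img - 10) / 20)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_maps_to_zeros(self):
        np.testing.assert_array_equal(
            normalize_intensity(np.full((3, 3), 7.0)), np.zeros((3, 3))
        )

    def test_idempotent_on_unit_range(self, rng):
        img = rng.random((5, 5))
        img[0, 0], img[1, 1] = 0.0, 1.0
        np.testing.assert_allclose(normalize_intensity(img), img, atol=1e-12)


class TestSplits:
    def test_34_patients_split_20_7_7(self):
        ids = [f"p{i}" for i in range(34)]
        s = split_patients(ids, seed=1)
        assert (len(s.train), len(s.val), len(s.test)) == (20, 7, 7)

    def test_same_seed_same_split(self):
        ids = [f"p{i}" for i in range(12)]
        a, b = split_patients(ids, seed=5), split_patients(ids, seed=5)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)

    def test_disjoint_cover_over_100_seeds(self):
        ids = [f"p{i}" for i in range(17)]
        for seed in range(100):
            s = split_patients(ids, seed=seed)
            parts = [set(s.train), set(s.val), set(s.test)]
            assert parts[0] | parts[1] | parts[2] == set(ids)
            assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_stratified_split_spans_age_range(self):
        ids = [f"p{i}" for i in range(30)]
        ages = {p: 20 + i / 2 for i, p in enumerate(ids)}
        s = split_patients(ids, seed=3, gestational_ages=ages)
        for part in (s.train, s.val, s.test):
            got = sorted(ages[p] for p in part)
            assert got[0] < 25 and got[-1] > 30  # both tails represented

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_patients([f"p{i}" for i in range(10)], fractions=(0.5, 0.2, 0.2))

    def test_json_round_trip(self):
        s = split_patients([f"p{i}" for i in range(10)], seed=2)
        from casenet.data_io import DatasetSplit

        r = DatasetSplit.from_json(s.to_json())
        assert (r.train, r.val, r.test, r.seed) == (s.train, s.val, s.test, 2)


class TestFolds:
    def test_each_patient_in_exactly_one_holdout(self):
        ids = [f"p{i}" for i in range(10)]
        folds = make_folds(ids, k=5, seed=0)
        assert len(folds) == 5
        holdouts = [p for _, h in folds for p in h]
        assert sorted(holdouts) == sorted(ids)
        for fit, hold in folds:
            assert len(hold) == 2 and not set(fit) & set(hold)

    def test_reproducible_and_order_insensitive(self):
        ids = [f"p{i}" for i in range(7)]
        a = make_folds(ids, k=3, seed=9)
        b = make_folds(ids, k=3, seed=9)
        assert a == b

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(["a", "b"], k=5)


class TestAugment:
    def _square_sample(self, size=32, half=6):
        img = np.zeros((size, size), dtype=np.float32)
        msk = np.zeros((size, size), dtype=np.uint8)
        c = size // 2
        msk[c - half : c + half, c - half : c + half] = 1
        img[msk == 1] = 1.0
        return _sample(img, msk)

    def test_identity_spec_is_noop(self, rng):
        s = self._square_sample()
        out = augment(s, AugmentationSpec.identity(), rng)
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_flip_is_involution(self, rng):
        spec = AugmentationSpec((1, 1), (1, 1), (0, 0), (1, 1), horizontal_flip=1.0)
        s = self._square_sample()
        s.image[:] = rng.random(s.image.shape)
        once = augment(s, spec, np.random.default_rng(0))
        np.testing.assert_array_equal(once.image, s.image[:, ::-1])
        twice = augment(once, spec, np.random.default_rng(0))
        np.testing.assert_array_equal(twice.image, s.image)
        np.testing.assert_array_equal(twice.mask, s.mask)

    def test_image_and_mask_stay_synchronized(self):
        # warping the mask through the image path with nearest interpolation
        # must equal the mask path: the same sampled transform hits both
        spec = AugmentationSpec()
        s = self._square_sample()
        s2 = _sample(s.mask.astype(np.float32), s.mask.copy())
        out = augment(s2, spec, np.random.default_rng(42), image_order=0)
        np.testing.assert_array_equal(out.image.astype(np.uint8), out.mask)

    def test_mask_stays_binary(self):
        spec = AugmentationSpec((0.8, 1.2), (0.8, 1.2), (-15, 15), (0.8, 1.2), 0.5)
        r = np.random.default_rng(1)
        s = self._square_sample()
        for _ in range(10):
            out = augment(s, spec, r)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.mask.shape == s.mask.shape

    def test_foreground_area_follows_sampled_zoom(self, monkeypatch):
        # freeze the sampled transform; the foreground area of a centred
        # square must scale as sx*sy*zoom^2 (shear preserves area)
        import casenet.data_io as dio

        sx, sy, zoom = 1.15, 0.9, 1.1
        monkeypatch.setattr(
            dio, "_sample_transform", lambda spec, rng: (sx, sy, 5.0, zoom, False)
        )
        s = self._square_sample(size=64, half=12)
        out = dio.augment(s, AugmentationSpec(), np.random.default_rng(0))
        expected = s.mask.sum() * sx * sy * zoom**2
        assert out.mask.sum() == pytest.approx(expected, rel=0.06)
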