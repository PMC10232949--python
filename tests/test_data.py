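"""Data pipeline: phantoms, NIfTI round-trips, preprocessing, augmentation, split."""

import numpy as np
import pytest

from masunet import (AugmentationConfig, PhantomConfig, VolumeRecord,
                     augment_offline, generate_phantom_dataset,
                     load_msd_volume, load_phantom_dataset, prepare_split,
                     preprocess_volume, split_dataset)


class TestPhantomGenerator:
    def test_deterministic_given_seed(self):
        cfg = PhantomConfig(num_volumes=2, slices_per_volume=3, slice_size=32,
                            seed=4)
        a = generate_phantom_dataset(cfg)
        b = generate_phantom_dataset(cfg)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.image, vb.image)
            np.testing.assert_array_equal(va.label, vb.label)

    def test_region_nesting_and_disjointness(self, tiny_volumes):
        for vol in tiny_volumes:
            assert set(np.unique(vol.label)) <= {0, 1, 2}
            for s in range(vol.label.shape[0]):
                lab = vol.label[s]
                tz = lab == 2
                pz = lab == 1
                assert not np.any(tz & pz)
                if tz.any():
                    # every TZ pixel is 4-adjacent only to TZ or PZ pixels
                    padded = np.pad(lab, 1)
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        neigh = padded[1 + dr:1 + dr + lab.shape[0],
                                       1 + dc:1 + dc + lab.shape[1]]
                        assert np.all(neigh[tz] > 0)

    def test_intensity_ordering(self, tiny_volumes):
        for vol in tiny_volumes:
            img = vol.image[0]
            tz_mean = img[vol.label == 2].mean()
            pz_mean = img[vol.label == 1].mean()
            bg_mean = img[vol.label == 0].mean()
            assert tz_mean > pz_mean > bg_mean

    def test_unlabeled_fraction(self):
        cfg = PhantomConfig(num_volumes=4, slices_per_volume=2, slice_size=32,
                            labeled_fraction=0.5, seed=0)
        vols = generate_phantom_dataset(cfg)
        assert sum(v.labeled for v in vols) == 2


class TestNiftiRoundTrip:
    def test_write_then_load_identical(self, tmp_path):
        cfg = PhantomConfig(num_volumes=2, slices_per_volume=3, slice_size=32,
                            seed=9)
        written = generate_phantom_dataset(cfg, out_dir=tmp_path)
        loaded = load_phantom_dataset(tmp_path)
        assert (tmp_path / "dataset.json").exists()
        for w, l in zip(written, loaded):
            np.testing.assert_allclose(l.image, w.image, atol=1e-6)
            np.testing.assert_array_equal(l.label, w.label)
            assert l.spacing == pytest.approx(w.spacing)

    def test_label_spatial_mismatch_raises(self):
        with pytest.raises(ValueError, match="label shape"):
            VolumeRecord(volume_id="x",
                         image=np.zeros((1, 3, 8, 8), np.float32),
                         label=np.zeros((3, 8, 4), np.int16))

    def test_unknown_label_code_named_in_error(self):
        label = np.zeros((2, 8, 8), np.int16)
        label[0, 0, 0] = 3
        with pytest.raises(ValueError, match="3"):
            VolumeRecord(volume_id="x",
                         image=np.zeros((1, 2, 8, 8), np.float32),
                         label=label)

    def test_loader_code_map_remaps(self, tmp_path):
        import nibabel as nib
        img = np.random.default_rng(0).random((8, 8, 2)).astype(np.float32)
        lab = np.zeros((8, 8, 2), np.int16)
        lab[2:5, 2:5] = 7
        nib.save(nib.Nifti1Image(img, np.eye(4)), str(tmp_path / "i.nii.gz"))
        nib.save(nib.Nifti1Image(lab, np.eye(4)), str(tmp_path / "l.nii.gz"))
        rec = load_msd_volume(tmp_path / "i.nii.gz", tmp_path / "l.nii.gz",
                              code_map={7: 2})
        assert set(np.unique(rec.label)) == {0, 2}


class TestPreprocess:
    def test_slice_count_and_shapes(self, tiny_volumes):
        samples = preprocess_volume(tiny_volumes[0], (32, 32))
        assert len(samples) == 3
        for s in samples:
            assert s.image.shape == (1, 32, 32)
            assert s.target.shape == (2, 32, 32)
            assert not np.any(s.target[0] & s.target[1])

    def test_normalization_contract(self, tiny_volumes):
        samples = preprocess_volume(tiny_volumes[0], (32, 32))
        stack = np.stack([s.image for s in samples])
        assert abs(stack.mean()) < 0.1
        assert 0.5 < stack.std() < 1.5

    def test_resize_keeps_label_codes(self, tiny_volumes):
        vol = tiny_volumes[0]
        samples = preprocess_volume(vol, (48, 48))
        merged = np.stack([s.target for s in samples])
        # nearest-neighbour label resize introduces no new classes
        assert set(np.unique(merged)) <= {0, 1}
        assert samples[1].target.sum() > 0

    def test_indivisible_target_raises(self, tiny_volumes):
        with pytest.raises(ValueError, match="divisible by 16"):
            preprocess_volume(tiny_volumes[0], (30, 30))


class TestAugmentation:
    def test_triples_the_set(self, tiny_volumes):
        samples = preprocess_volume(tiny_volumes[0], (32, 32))
        cfg = AugmentationConfig(copies_per_image=2, seed=1)
        out = augment_offline(samples, cfg)
        assert len(out) == 3 * len(samples)
        originals = [s for s in out if s.augmentation == "original"]
        assert len(originals) == len(samples)

    def test_deterministic_given_seed(self, tiny_volumes):
        samples = preprocess_volume(tiny_volumes[0], (32, 32))
        cfg = AugmentationConfig(seed=7)
        a = augment_offline(samples, cfg)
        b = augment_offline(samples, cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.target, sb.target)

    def test_double_flip_involution(self, tiny_volumes):
        s = preprocess_volume(tiny_volumes[0], (32, 32))[1]
        flipped_twice = s.image[..., ::-1][..., ::-1]
        np.testing.assert_array_equal(flipped_twice, s.image)

    def test_flips_preserve_mask_count_rotation_nearly(self, tiny_volumes):
        samples = preprocess_volume(tiny_volumes[0], (32, 32))
        flip_only = AugmentationConfig(
            copies_per_image=3, rotation_degrees=0.0,
            noise_sigma_range=(0.0, 0.0), brightness_range=(1.0, 1.0),
            contrast_range=(1.0, 1.0), seed=3)
        for out in augment_offline(samples, flip_only):
            src = next(s for s in samples
                       if (s.volume_id, s.slice_index) ==
                       (out.volume_id, out.slice_index))
            assert int(out.target.sum()) == int(src.target.sum())
        rot_only = AugmentationConfig(
            copies_per_image=3, horizontal_flip=False, vertical_flip=False,
            rotation_degrees=15.0, noise_sigma_range=(0.0, 0.0),
            brightness_range=(1.0, 1.0), contrast_range=(1.0, 1.0), seed=3)
        for out in augment_offline(samples, rot_only):
            src = next(s for s in samples
                       if (s.volume_id, s.slice_index) ==
                       (out.volume_id, out.slice_index))
            if out.augmentation != "original" and "rotate" in out.augmentation:
                assert int(out.target.sum()) == pytest.approx(
                    int(src.target.sum()), rel=0.15)

    def test_geometric_transform_hits_masks_identically(self, tiny_volumes):
        """An hflip-tagged copy has image and masks flipped together."""
        samples = preprocess_volume(tiny_volumes[0], (32, 32))
        cfg = AugmentationConfig(
            copies_per_image=5, vertical_flip=False, rotation_degrees=0.0,
            noise_sigma_range=(0.0, 0.0), brightness_range=(1.0, 1.0),
            contrast_range=(1.0, 1.0), seed=2)
        out = augment_offline(samples[:1], cfg)
        src = samples[0]
        hflipped = [s for s in out if s.augmentation.endswith(":hflip")]
        assert hflipped, "no horizontal flip drawn in 5 copies"
        for s in hflipped:
            np.testing.assert_array_equal(s.image, src.image[..., ::-1])
            np.testing.assert_array_equal(s.target, src.target[..., ::-1])

    def test_empty_input_gives_empty_output(self):
        assert augment_offline([], AugmentationConfig()) == []


class TestSplit:
    def test_eight_two_partition(self, phantom_volumes):
        split = split_dataset(phantom_volumes, fraction=0.8, seed=0)
        assert len(split.train_volumes) == 8
        assert len(split.val_volumes) == 2
        assert split.train_ids & split.val_ids == set()

    def test_too_few_labeled_raises(self, phantom_volumes):
        with pytest.raises(ValueError, match="labeled"):
            split_dataset(phantom_volumes[:1])

    def test_bad_fraction_raises(self, phantom_volumes):
        with pytest.raises(ValueError, match="fraction"):
            split_dataset(phantom_volumes, fraction=1.0)

    def test_augmented_only_in_training(self, tiny_volumes):
        split = prepare_split(tiny_volumes, fraction=0.75, split_seed=0,
                              target_size=(32, 32),
                              augmentation=AugmentationConfig(seed=1))
        assert len(split.train_volumes) == 3
        assert all(s.augmentation == "original" for s in split.val_samples)
        assert any(s.augmentation != "original" for s in split.train_samples)
        train_ids = {s.volume_id for s in split.train_samples}
        val_ids = {s.volume_id for s in split.val_samples}
        assert train_ids & val_ids == set()

    def test_pipeline_reproducible_from_seeds(self, tiny_volumes):
        kw = dict(fraction=0.75, split_seed=5, target_size=(32, 32),
                  augmentation=AugmentationConfig(seed=2))
        a = prepare_split(tiny_volumes, **kw)
        b = prepare_split(tiny_volumes, **kw)
        assert [s.augmentation for s in a.train_samples] == \
               [s.augmentation for s in b.train_samples]
        for sa, sb in zip(a.train_samples, b.train_samples):
            np.testing.assert_array_equal(sa.image, sb.image)
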