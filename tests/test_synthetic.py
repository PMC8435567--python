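"""Synthetic dataset protocol: rendering, counts, splits, preprocessing."""

import numpy as np
import pytest
from PIL import Image

from skaresnet.synthetic import (DatasetIndex, DatasetManifest, Pose,
                                 PreprocessConfig, SID19_CLASS_NAMES,
                                 compute_channel_stats, default_class_specs,
                                 generate_dataset, load_arrays, preprocess,
                                 render_arrays, render_instrument,
                                 sample_pose, split_train_test)

SPECS = default_class_specs()


class TestManifest:
    def test_default_protocol_counts(self):
        man = DatasetManifest()
        assert len(man.classes) == 19
        assert man.per_class == 200
        assert man.classes == SID19_CLASS_NAMES

    def test_json_roundtrip(self):
        man = DatasetManifest(per_class=7, seed=3, image_size=64)
        assert DatasetManifest.from_json(man.to_json()) == man

    def test_invalid_angle_range_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            DatasetManifest(side_view_angle_range=(30.0, 95.0))

    def test_fine_grained_partners_are_symmetric(self):
        for name, spec in SPECS.items():
            if spec.fine_grained_partner:
                partner = SPECS[spec.fine_grained_partner]
                assert partner.fine_grained_partner == name


class TestRenderer:
    POSE = Pose(state="open", angle=45.0, rotation=30.0, lighting="day")

    def test_seeded_determinism_byte_identical(self):
        a = render_instrument(SPECS["Alice forceps"], self.POSE,
                              np.random.default_rng(4), 64)
        b = render_instrument(SPECS["Alice forceps"], self.POSE,
                              np.random.default_rng(4), 64)
        assert a.tobytes() == b.tobytes()

    @pytest.mark.parametrize("lighting", ["day", "night-with-lamp"])
    def test_background_is_near_black(self, lighting):
        pose = Pose(state="closed", angle=40.0, rotation=10.0, lighting=lighting)
        img = np.asarray(render_instrument(SPECS["Tissue hook"], pose,
                                           np.random.default_rng(0), 128))
        # background dominates the frame; overall mean intensity stays
        # below 10% of full scale
        assert img.mean() < 25.5

    def test_fine_pair_differs_only_at_tip(self):
        pose = self.POSE
        a, box = render_instrument(SPECS["Alice forceps"], pose,
                                   np.random.default_rng(5), 256,
                                   return_tip_box=True)
        b, _ = render_instrument(SPECS["Appendix forceps"], pose,
                                 np.random.default_rng(5), 256,
                                 return_tip_box=True)
        diff = (np.asarray(a) != np.asarray(b)).any(axis=2)
        x1, y1, x2, y2 = (int(v) for v in box)
        outside = diff.copy()
        outside[y1:y2, x1:x2] = False
        assert diff.sum() > 0                       # the pair is not identical
        assert 1.0 - outside.sum() / diff.size >= 0.99

    def test_invalid_pose_rejected(self):
        man = DatasetManifest()
        with pytest.raises(ValueError, match="angle"):
            render_instrument(SPECS["Alice forceps"],
                              Pose(angle=10.0), np.random.default_rng(0),
                              64, manifest=man)
        with pytest.raises(ValueError, match="state"):
            render_instrument(SPECS["Alice forceps"],
                              Pose(state="ajar"), np.random.default_rng(0), 64)

    def test_difficulty_structure_fine_pair_harder_than_coarse(self):
        """Pixel-space nearest-centroid separates the coarse pair better
        than the matched fine-grained pair (50 seeded renders each)."""
        man = DatasetManifest(per_class=50, image_size=64, seed=3)

        def renders(name, seed):
            spec = SPECS[name]
            rng = np.random.default_rng([9, seed])
            out = []
            for _ in range(50):
                pose = sample_pose(spec, man, rng)
                img = render_instrument(spec, pose, rng, 64, man)
                out.append(np.asarray(img, dtype=float).mean(axis=2).ravel() / 255.0)
            return np.asarray(out)

        def nc_accuracy(a, b):
            ca, cb = a[:25].mean(0), b[:25].mean(0)
            hits = 0
            for t, cme, coth in ((a[25:], ca, cb), (b[25:], cb, ca)):
                hits += int((np.linalg.norm(t - cme, axis=1)
                             < np.linalg.norm(t - coth, axis=1)).sum())
            return hits / 50.0

        alice = renders("Alice forceps", 1)
        appendix = renders("Appendix forceps", 2)
        tweezers = renders("Tissue tweezers", 3)
        coarse = nc_accuracy(alice, tweezers)
        fine = nc_accuracy(alice, appendix)
        assert coarse > fine


class TestGeneration:
    def test_counts_match_manifest(self, tmp_path):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:3], per_class=4,
                              image_size=48, seed=2)
        index = generate_dataset(man, tmp_path / "ds")
        assert len(index.records) == 12
        pngs = sorted((tmp_path / "ds").rglob("*.png"))
        assert len(pngs) == 12
        img = Image.open(pngs[0])
        assert img.mode == "RGB" and img.size == (48, 48)

    def test_reduced_per_class_arithmetic(self):
        man = DatasetManifest(per_class=10, image_size=32, seed=0)
        X, y, index = render_arrays(man, size=32)
        assert len(index.records) == 190
        assert X.shape == (190, 3, 32, 32)

    def test_identical_seed_identical_index(self, tmp_path):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:2], per_class=3,
                              image_size=32, seed=5)
        generate_dataset(man, tmp_path / "a")
        generate_dataset(man, tmp_path / "b")
        assert (tmp_path / "a/index.csv").read_bytes() == \
               (tmp_path / "b/index.csv").read_bytes()

    def test_refuses_overwrite_without_flag(self, tmp_path):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:1], per_class=2,
                              image_size=32)
        generate_dataset(man, tmp_path / "ds")
        with pytest.raises(FileExistsError):
            generate_dataset(man, tmp_path / "ds")
        generate_dataset(man, tmp_path / "ds", overwrite=True)

    def test_index_csv_roundtrip_and_loader(self, tmp_path):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:2], per_class=4,
                              image_size=40, seed=1)
        index = generate_dataset(man, tmp_path / "ds")
        index = split_train_test(index, 0.5, seed=0)
        index.to_csv(tmp_path / "ds/index.csv")
        back = DatasetIndex.from_csv(tmp_path / "ds/index.csv")
        assert len(back.records) == 8
        X, y = load_arrays(tmp_path / "ds", back, "train",
                           PreprocessConfig(crop_size=32, resize_size=36))
        assert X.shape == (4, 3, 32, 32)


class TestSplit:
    @pytest.mark.parametrize("per_class,want_train", [
        (200, 120), (10, 6), (5, 3), (2, 2), (3, 2),
    ])
    def test_three_to_two_rounds_toward_train(self, per_class, want_train):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:2],
                              per_class=per_class, image_size=32, seed=1)
        _, _, index = render_arrays(man, size=32)
        index = split_train_test(index, 0.6, seed=4)
        for label in (0, 1):
            n_train = sum(r.split == "train" and r.label == label
                          for r in index.records)
            assert n_train == want_train

    def test_partition_disjoint_and_exhaustive(self):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:3], per_class=9,
                              image_size=32, seed=1)
        _, _, index = render_arrays(man, size=32)
        index = split_train_test(index, 0.6, seed=7)
        assert all(r.split in ("train", "test") for r in index.records)

    def test_deterministic_under_seed(self):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:2], per_class=6,
                              image_size=32, seed=1)
        _, _, index = render_arrays(man, size=32)
        a = [r.split for r in split_train_test(index, 0.6, seed=9).records]
        b = [r.split for r in split_train_test(index, 0.6, seed=9).records]
        assert a == b

    def test_tiny_class_rejected(self):
        man = DatasetManifest(classes=SID19_CLASS_NAMES[:1], per_class=1,
                              image_size=32)
        _, _, index = render_arrays(man, size=32)
        with pytest.raises(ValueError, match="fewer"):
            split_train_test(index, 0.6)


class TestPreprocess:
    def make_image(self, value=128, size=300):
        return Image.fromarray(np.full((size, size, 3), value, np.uint8), "RGB")

    @pytest.mark.parametrize("mode", ["train", "eval"])
    def test_output_shape(self, mode):
        out = preprocess(self.make_image(), mode, PreprocessConfig())
        assert out.shape == (3, 224, 224)

    @pytest.mark.parametrize("crop", [112, 224, 336, 448])
    def test_scale_ablation_sizes(self, crop):
        out = preprocess(self.make_image(), "eval", PreprocessConfig(crop_size=crop))
        assert out.shape == (3, crop, crop)

    def test_eval_deterministic(self):
        img = Image.fromarray(
            np.random.default_rng(0).integers(0, 255, (300, 300, 3), dtype=np.uint8)
            .astype(np.uint8), "RGB")
        a = preprocess(img, "eval", PreprocessConfig())
        b = preprocess(img, "eval", PreprocessConfig())
        assert np.array_equal(a, b)

    def test_constant_image_normalizes_to_zero(self):
        val = 100 / 255.0
        cfg = PreprocessConfig(mean=(val, val, val), std=(1.0, 1.0, 1.0))
        out = preprocess(self.make_image(100), "eval", cfg)
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_non_rgb_rejected(self):
        gray = Image.fromarray(np.zeros((64, 64), np.uint8), "L")
        with pytest.raises(ValueError, match="RGB"):
            preprocess(gray, "eval")

    def test_channel_stats(self):
        x = np.zeros((4, 3, 8, 8))
        x[:, 1] = 0.5
        mean, std = compute_channel_stats(x)
        assert mean == (0.0, 0.5, 0.0)
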