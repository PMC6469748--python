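"""Patch pipeline: Euler filtering, lightness normalization, augmentation,
network shapes and the training/prediction contracts."""

import numpy as np
import pytest
from skimage import color as skcolor

from conftest import random_blob_binary
from oracles import euler_brute_force
from osteotile.cnn import (CnnConfig, PatchCNN, PatchPrediction, dihedral_augment,
                           euler_value, layer_shapes, lightness_normalize,
                           patches_to_array, pca_color_augment, predict_patches,
                           significance_filter, tile_vote, train_cnn)
from osteotile.synth import PatchRecord


def binary_to_gray(binary):
    """Dark foreground on white background, as the Euler stage expects."""
    return np.where(binary, 0.0, 255.0)


class TestEuler:
    def test_solid_square(self):
        b = np.zeros((32, 32), dtype=bool)
        b[8:24, 8:24] = True
        assert euler_value(binary_to_gray(b)) == 1

    def test_square_with_hole(self):
        b = np.zeros((32, 32), dtype=bool)
        b[4:28, 4:28] = True
        b[12:20, 12:20] = False
        assert euler_value(binary_to_gray(b)) == 0

    def test_matches_brute_force_on_random_blobs(self, rng):
        """Euler number equals explicit BFS object/hole counting on 100
        random blob binaries."""
        for _ in range(100):
            b = random_blob_binary(rng, size=48, n_blobs=10)
            if not b.any() or b.all():
                continue
            assert euler_value(binary_to_gray(b)) == euler_brute_force(b)

    def test_constant_patch_is_zero(self):
        assert euler_value(np.full((16, 16), 255.0)) == 0


def make_patch(image, tin="T000000", label="NT"):
    return PatchRecord(parent_tin=tin, image=image, offset=(0, 0), label=label)


def blobby_patch(rng, n_blobs, holes=0):
    b = random_blob_binary(rng, size=128, n_blobs=n_blobs)
    if holes:
        b[:] = False
        b[8:120, 8:120] = True
        for k in range(holes):
            r, c = 16 + 24 * (k % 4), 16 + 24 * (k // 4)
            b[r:r + 8, c:c + 8] = False
    img = np.where(b[..., None], 40, 230).astype(np.uint8) * np.ones(3, np.uint8)
    return img


class TestSignificanceFilter:
    def test_keep_and_drop_by_euler(self, rng):
        kept_patch = make_patch(blobby_patch(rng, 3))          # e > 0
        dropped = make_patch(blobby_patch(rng, 0, holes=6))    # e = 1 - 6 = -5
        assert euler_value(dropped.image) == -5
        kept = significance_filter([kept_patch, dropped])
        assert kept == [kept_patch]
        assert kept_patch.keep and not dropped.keep

    def test_thousand_patch_recount(self, rng):
        """A 1000-patch set with 300 pure-background members: the kept-set
        size equals a direct recount at the same threshold."""
        patches = [make_patch(np.full((128, 128, 3), 245, dtype=np.uint8))
                   for _ in range(300)]
        patches += [make_patch(blobby_patch(rng, int(rng.integers(1, 14))))
                    for _ in range(700)]
        kept = significance_filter(patches)
        recount = sum(euler_value(p.image) >= -3 for p in patches)
        assert len(kept) == recount

    def test_monotone_in_threshold(self, rng):
        patches = [make_patch(blobby_patch(rng, int(rng.integers(0, 12))))
                   for _ in range(50)]
        sizes = [len(significance_filter(list(patches), threshold=t))
                 for t in (-10, -3, 0, 3)]
        assert sizes == sorted(sizes, reverse=True)


class TestLightnessNormalize:
    def patch(self, rng):
        base = rng.uniform(80, 200, size=(32, 32, 3))
        return np.clip(base, 0, 255).astype(np.uint8)

    def test_idempotent(self, rng):
        p = self.patch(rng)
        once = lightness_normalize(p)
        twice = lightness_normalize(once)
        assert np.abs(once - twice).max() < 0.5

    def test_chroma_channels_preserved(self, rng):
        p = self.patch(rng)
        out = lightness_normalize(p)
        lab_in = skcolor.rgb2lab(p.astype(float) / 255)
        lab_out = skcolor.rgb2lab(out / 255)
        assert np.abs(lab_in[..., 1:] - lab_out[..., 1:]).max() < 1e-6

    def test_brightness_pair_converges(self, rng):
        """Two renditions of one patch at +-20% lightness normalize to the
        same image within 2/255 per channel."""
        p = self.patch(rng).astype(float) / 255
        lab = skcolor.rgb2lab(p)
        pair = []
        for gain in (0.8, 1.2):
            lab_g = lab.copy()
            lab_g[..., 0] = np.clip(lab[..., 0] * gain, 0, 100)
            rgb = np.clip(skcolor.lab2rgb(lab_g), 0, 1) * 255
            pair.append(lightness_normalize(rgb))
        assert np.abs(pair[0] - pair[1]).max() <= 2.0


class TestDihedral:
    def test_eight_transforms(self, rng):
        p = rng.integers(0, 255, size=(16, 16, 3)).astype(np.uint8)
        outs = dihedral_augment(p)
        assert len(outs) == 8
        assert all(o.shape == p.shape for o in outs)

    def test_uniform_patch_all_identical(self):
        p = np.full((8, 8, 3), 7, dtype=np.uint8)
        outs = dihedral_augment(p)
        assert all(np.array_equal(o, p) for o in outs)

    def test_corner_marker_all_distinct(self):
        p = np.zeros((8, 8, 3), dtype=np.uint8)
        p[0, 0] = 255
        p[0, 1] = 128
        outs = dihedral_augment(p)
        for i in range(8):
            for j in range(i + 1, 8):
                assert not np.array_equal(outs[i], outs[j])

    def test_group_closure_involutions(self, rng):
        p = rng.integers(0, 255, size=(12, 12, 3)).astype(np.uint8)
        outs = dihedral_augment(p)
        # rot180, both flips and both flipped-rotations are involutions;
        # rot90 applied four times returns the identity
        assert np.array_equal(np.rot90(outs[1], -1), p)
        assert np.array_equal(np.rot90(outs[2], 2), p)
        assert np.array_equal(np.flip(outs[4], axis=1), p)
        assert np.array_equal(np.flip(outs[5], axis=0), p)
        q = p
        for _ in range(4):
            q = np.rot90(q)
        assert np.array_equal(q, p)


class TestPcaColorAugment:
    def test_zero_alpha_identity(self, rng):
        X = rng.integers(0, 255, size=(4, 8, 8, 3)).astype(np.uint8)
        out, lam, Q = pca_color_augment(X, seed=0, alpha_mean=0.0, alpha_sd=0.0)
        assert np.array_equal(out, X)

    def test_same_seed_same_perturbation(self, rng):
        X = rng.integers(0, 255, size=(5, 8, 8, 3)).astype(np.uint8)
        a, *_ = pca_color_augment(X, seed=9)
        b, *_ = pca_color_augment(X, seed=9)
        assert np.array_equal(a, b)

    def test_grayscale_dataset_shifts_along_intensity_axis(self, rng):
        g = rng.integers(0, 255, size=(6, 16, 16, 1)).astype(np.uint8)
        X = np.repeat(g, 3, axis=-1)
        with pytest.warns(UserWarning):
            _, lam, Q = pca_color_augment(X, seed=1)
        top = Q[:, 0]
        assert np.abs(np.abs(top @ (np.ones(3) / np.sqrt(3))) - 1) < 1e-8
        assert lam[1] == pytest.approx(0.0, abs=1e-10)


class TestAugmentTrainingSet:
    def test_eightfold_expansion_keeps_labels(self, rng):
        from osteotile.cnn import AugmentationSpec, augment_training_set
        X = rng.integers(0, 255, size=(6, 16, 16, 3)).astype(np.uint8)
        y = np.array(["NT", "NEC", "VT"] * 2)
        Xa, ya = augment_training_set(X, y, AugmentationSpec(pca=False))
        assert Xa.shape[0] == 48 and len(ya) == 48
        assert list(ya[:8]) == ["NT"] * 8  # transforms inherit the label
        assert np.array_equal(Xa[0], X[0])  # identity member present

    def test_pca_only_preserves_count(self, rng):
        from osteotile.cnn import AugmentationSpec, augment_training_set
        X = rng.integers(0, 255, size=(5, 16, 16, 3)).astype(np.uint8)
        y = np.array(["NT", "NEC", "VT", "NT", "VT"])
        Xa, ya = augment_training_set(X, y, AugmentationSpec(dihedral=False,
                                                             seed=3))
        assert Xa.shape == X.shape and np.array_equal(ya, y)
        assert not np.array_equal(Xa, X)  # alpha ~ N(1, .1) shifts colors


class TestLayerShapes:
    def test_reference_feature_map_progression(self):
        shapes = layer_shapes(CnnConfig())
        assert shapes[0] == (128, 124, 62)   # 5x5 conv then pool 2
        assert shapes[1] == (62, 58, 29)
        assert shapes[2] == (29, 27, 13)     # floor division

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            layer_shapes(CnnConfig(input_size=8, kernels=(5, 5, 3)))


@pytest.fixture(scope="module")
def tiny_trained():
    rng = np.random.default_rng(0)
    # two trivially different patch populations, small net for speed
    X = np.concatenate([
        rng.integers(0, 60, size=(30, 36, 36, 3)),
        rng.integers(180, 255, size=(30, 36, 36, 3)),
    ]).astype(np.uint8)
    y = np.array(["VT"] * 30 + ["NT"] * 30)
    cfg = CnnConfig(input_size=36, kernels=(3, 3, 3), filters=(2, 3, 4),
                    hidden=8, epochs=5, batch_size=20, seed=1)
    model = PatchCNN(cfg).fit(X, y)
    return model, X, y, cfg


class TestNetwork:
    def test_training_deterministic(self, tiny_trained):
        model, X, y, cfg = tiny_trained
        again = PatchCNN(cfg).fit(X, y)
        assert all(np.array_equal(model.params[k], again.params[k])
                   for k in model.params)

    def test_probabilities_sum_to_one(self, tiny_trained):
        model, X, _, _ = tiny_trained
        probs = model.predict_proba(X[:10])
        assert probs.shape == (10, 3)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6

    def test_loss_decreases(self, tiny_trained):
        model, *_ = tiny_trained
        losses = [h["loss"] for h in model.history]
        assert losses[-1] < losses[0]

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            PatchCNN(CnnConfig(input_size=36, kernels=(3, 3, 3))).fit(
                np.empty((0, 36, 36, 3), dtype=np.uint8), np.array([]))


class TestVoting:
    def pred(self, probs, tin="T1"):
        probs = np.asarray(probs, dtype=float)
        from osteotile.synth import CLASS_LABELS
        return PatchPrediction(tin, probs, CLASS_LABELS[int(probs.argmax())])

    def test_unanimous(self):
        preds = [self.pred([0.1, 0.2, 0.7]) for _ in range(5)]
        assert tile_vote(preds) == "VT"

    def test_majority(self):
        preds = [self.pred([0.1, 0.8, 0.1])] * 6 + [self.pred([0.1, 0.1, 0.8])] * 4
        assert tile_vote(preds) == "NEC"

    def test_tie_breaks_by_mean_probability(self):
        preds = [self.pred([0.05, 0.9, 0.05]), self.pred([0.05, 0.05, 0.9]),
                 self.pred([0.1, 0.3, 0.6]), self.pred([0.2, 0.5, 0.3])]
        # two votes each; VT mean prob higher
        assert tile_vote(preds) == "VT"

    def test_empty_defaults_to_nt_with_warning(self):
        with pytest.warns(UserWarning):
            assert tile_vote([]) == "NT"

    def test_matches_brute_force_recount(self, rng):
        from osteotile.synth import CLASS_LABELS
        for _ in range(20):
            probs = rng.dirichlet(np.ones(3), size=11)
            preds = [self.pred(p) for p in probs]
            votes = [p.label for p in preds]
            counts = {c: votes.count(c) for c in CLASS_LABELS}
            best = max(counts.values())
            tied = [c for c in CLASS_LABELS if counts[c] == best]
            got = tile_vote(preds)
            assert got in tied

    def test_predict_patches_round_trip(self, tiny_trained):
        model, X, y, _ = tiny_trained
        patches = [PatchRecord("T7", img, (0, 0), lab)
                   for img, lab in zip(X[:8], y[:8])]
        preds = predict_patches(model, patches)
        assert len(preds) == 8
        assert all(p.parent_tin == "T7" for p in preds)
        assert all(abs(p.probabilities.sum() - 1) < 1e-6 for p in preds)
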