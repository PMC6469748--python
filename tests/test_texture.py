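"""Texture bank: stain unmixing, Haralick statistics, Gabor response,
object detection and neighbor counting, each against an independent oracle."""

import numpy as np
import pytest

from oracles import glcm_pair_count, haralick_textbook, min_pixel_distance
from osteotile.texture import (HARALICK_NAMES, TEXTURE_FEATURE_NAMES,
                               GlcmSpec, TextureConfig, gabor_score, glcm,
                               haralick13, haralick_from_glcm, neighbor_counts,
                               primary_objects, quantize, secondary_objects,
                               stains_to_rgb, texture_vector, unmix_he)
from osteotile.expert import EXPERT_FEATURE_NAMES


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestUnmix:
    def test_white_pixel_zero_od(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        pair = unmix_he(img)
        assert np.allclose(pair.hematoxylin, 0)
        assert np.allclose(pair.eosin, 0)

    def test_pure_hematoxylin_has_no_eosin(self):
        conc = np.zeros((8, 8, 2))
        conc[..., 0] = 0.6
        img = stains_to_rgb(conc)
        pair = unmix_he(img)
        assert pair.eosin.max() < 0.02
        assert pair.hematoxylin.mean() == pytest.approx(0.6, abs=0.02)

    def test_two_stain_mixture_recovered(self, rng):
        """Forward-simulate Beer-Lambert mixing with known concentrations and
        invert; recovery within 1% RMS (relative to the concentration scale)."""
        conc = rng.uniform(0.05, 0.7, size=(32, 32, 2))
        img = stains_to_rgb(conc)
        pair = unmix_he(img)
        est = np.stack([pair.hematoxylin, pair.eosin], axis=-1)
        rms = np.sqrt(((est - conc) ** 2).mean())
        assert rms / conc.mean() < 0.01

    def test_singular_basis_rejected(self):
        v = np.array([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
        with pytest.raises(ValueError):
            unmix_he(np.zeros((4, 4, 3), dtype=np.uint8), v)


class TestHaralick:
    def test_constant_image_degenerate_glcm(self):
        q = np.zeros((16, 16), dtype=int)
        with pytest.warns(UserWarning):
            feats = haralick13(q, GlcmSpec())
        assert feats["asm"] == 1.0
        assert feats["entropy"] == 0.0
        assert feats["contrast"] == 0.0

    def test_checkerboard_hand_computed(self):
        """Strict 2-level checkerboard, offset (0,1): the GLCM is 0.5 on each
        off-diagonal entry, so contrast = 1 and ASM = 0.5."""
        q = np.indices((16, 16)).sum(axis=0) % 2
        P = glcm(q, (0, 1), levels=2)
        assert np.allclose(P, [[0, 0.5], [0.5, 0]])
        feats = haralick_from_glcm(P)
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["asm"] == pytest.approx(0.5)

    def test_glcm_normalized_and_symmetric(self, rng):
        q = rng.integers(0, 8, size=(32, 32))
        for off in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
            P = glcm(q, off, 8)
            assert P.sum() == pytest.approx(1.0)
            assert np.allclose(P, P.T)

    def test_matches_textbook_formulas(self, rng):
        """All 13 statistics agree with an independent textbook-formula
        implementation on 20 random 16x16, 8-level images to 1e-8."""
        for _ in range(20):
            q = rng.integers(0, 8, size=(16, 16))
            for off in ((0, 1), (-1, 0)):
                ours = haralick_from_glcm(glcm(q, off, 8))
                P_oracle = glcm_pair_count(q, off, 8)
                theirs = haralick_textbook(P_oracle)
                for name in HARALICK_NAMES:
                    assert ours[name] == pytest.approx(theirs[name], abs=1e-8), name


class TestGabor:
    def test_constant_image_zero(self):
        assert gabor_score(np.full((64, 64), 3.7)) == pytest.approx(0.0, abs=1e-10)

    def test_matched_grating_strongest(self):
        x = np.arange(96)
        grating = np.tile(np.sin(2 * np.pi * 0.08 * x), (96, 1))
        matched = gabor_score(grating, frequency=0.08, orientations=4)
        half = gabor_score(np.tile(np.sin(2 * np.pi * 0.04 * x), (96, 1)),
                           frequency=0.08, orientations=4)
        assert matched > gabor_score(np.zeros((96, 96)))
        assert matched > half

    def test_bad_frequency(self):
        with pytest.raises(ValueError):
            gabor_score(np.zeros((8, 8)), frequency=0)


class TestObjects:
    def test_three_disks_of_diameter_40(self):
        b = np.zeros((200, 200), dtype=bool)
        for c in ((40, 40), (40, 150), (150, 90)):
            b |= disk_mask(b.shape, c, 20)
        objs = primary_objects(b)
        assert objs.count == 3

    def test_small_disk_filtered_out(self):
        b = disk_mask((64, 64), (32, 32), 5)  # diameter 10 < 30
        assert primary_objects(b).count == 0

    def test_diameter_filter_matches_brute_force(self, rng):
        b = np.zeros((400, 400), dtype=bool)
        radii = rng.uniform(3, 70, size=12)
        centers = rng.uniform(30, 370, size=(12, 2))
        for c, r in zip(centers, radii):
            b |= disk_mask(b.shape, c, r)
        objs = primary_objects(b, 30, 120)
        # oracle: label by BFS-equivalent scipy call is avoided; recount by
        # direct component area filter on the unfiltered label image
        from oracles import bfs_label
        lab = bfs_label(b, 8)
        kept = 0
        for k in range(1, lab.max() + 1):
            area = (lab == k).sum()
            if 30 <= 2 * np.sqrt(area / np.pi) <= 120:
                kept += 1
        assert objs.count == kept

    def test_widening_band_is_monotone(self, rng):
        b = np.zeros((300, 300), dtype=bool)
        for _ in range(10):
            b |= disk_mask(b.shape, rng.uniform(20, 280, 2), rng.uniform(4, 40))
        counts = [primary_objects(b, d_min, d_max).count
                  for d_min, d_max in ((40, 80), (30, 120), (10, 200))]
        assert counts == sorted(counts)


class TestSecondaryObjects:
    def test_one_seed_uniform_permissive_mask(self):
        b = disk_mask((64, 64), (32, 32), 18)
        prim = primary_objects(b, 30, 120)
        assert prim.count == 1
        sec = secondary_objects(prim, mask=np.ones((64, 64), dtype=bool))
        assert sec.count == 1
        assert (sec.labels[prim.labels == 1] == 1).all()

    def test_two_seeds_nearest_assignment(self):
        b = disk_mask((80, 160), (40, 40), 16) | disk_mask((80, 160), (40, 120), 16)
        prim = primary_objects(b, 30, 120)
        assert prim.count == 2
        mask = np.ones((80, 160), dtype=bool)
        sec = secondary_objects(prim, mask=mask)
        assert sec.count == prim.count
        # brute-force nearest-seed assignment on a sample of pixels
        seeds = [np.argwhere(prim.labels == k) for k in (1, 2)]
        rng = np.random.default_rng(0)
        for r, c in rng.integers(0, (80, 160), size=(50, 2)):
            d = [np.sqrt(((s - (r, c)) ** 2).sum(1)).min() for s in seeds]
            assert sec.labels[r, c] == int(np.argmin(d)) + 1
        # regions partition the mask
        assert ((sec.labels > 0) == mask).all()


class TestNeighbors:
    def test_two_disks_five_apart(self):
        # centers 25 apart, radius 10 -> boundary gap 5 <= distance 10
        b = disk_mask((60, 120), (30, 30), 10) | disk_mask((60, 120), (30, 55), 10)
        prim = primary_objects(b, 10, 120)
        counts, summary = neighbor_counts(prim, distance=10)
        assert list(counts) == [1, 1]
        assert summary["neighbor_max"] == 1

    def test_single_object_no_neighbors(self):
        b = disk_mask((64, 64), (32, 32), 16)
        counts, summary = neighbor_counts(primary_objects(b, 10, 120), 10)
        assert list(counts) == [0]
        assert summary["n_clumps"] == 1

    def test_random_layout_matches_pairwise_distances(self, rng):
        b = np.zeros((200, 200), dtype=bool)
        for _ in range(8):
            b |= disk_mask(b.shape, rng.uniform(20, 180, 2), rng.uniform(5, 12))
        prim = primary_objects(b, 5, 200)
        d = 15.0
        counts, _ = neighbor_counts(prim, distance=d)
        n = prim.count
        oracle = np.zeros(n)
        for a in range(1, n + 1):
            for bb in range(1, n + 1):
                if a != bb and min_pixel_distance(prim.labels, a, bb) <= d:
                    oracle[a - 1] += 1
        assert list(counts) == list(oracle)


class TestTextureVector:
    def test_fifty_three_named_features(self, one_tile_per_class):
        vec = texture_vector(one_tile_per_class["VT"])
        assert tuple(vec) == TEXTURE_FEATURE_NAMES
        assert len(vec) == 53
        assert np.isfinite(list(vec.values())).all()

    def test_deterministic(self, one_tile_per_class):
        t = one_tile_per_class["NEC"]
        assert texture_vector(t) == texture_vector(t)

    def test_vt_has_more_primary_objects_than_nt(self, archetypes):
        """Viable tumor's clustered stain-dense nuclei yield more primary
        objects than sparse non-tumor tissue, by generator construction."""
        from osteotile.synth import synth_tile
        vt = np.mean([texture_vector(synth_tile(archetypes["VT"], s))["primary_count"]
                      for s in range(3)])
        nt = np.mean([texture_vector(synth_tile(archetypes["NT"], s))["primary_count"]
                      for s in range(3)])
        assert vt > nt

    def test_catalog_disjoint_from_expert_features(self):
        assert not set(TEXTURE_FEATURE_NAMES) & set(EXPERT_FEATURE_NAMES)


def test_quantize_range():
    g = np.linspace(0, 1, 100).reshape(10, 10)
    q = quantize(g, 8)
    assert q.min() == 0 and q.max() == 7
    assert np.all(np.diff(q.ravel()) >= 0)
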