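"""Feature bank: exact values, exhaustive oracles and invariances."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from gbp_radiomics import features as F
from gbp_radiomics.preprocess import build_lesion_mask, high_intensity_region
from gbp_radiomics.features import (
    BINARY_TEXTURE_NAMES,
    FIRST_ORDER_NAMES,
    GLCM_FEATURE_NAMES,
    MORPHOLOGY_NAMES,
    SPATIAL_NAMES,
    binary_texture,
    build_tables,
    extract_case,
    first_order,
    glcm_features,
    glcm_matrix,
    glcm_stats,
    morphology,
    quantize,
)

# ---------------------------------------------------------------------------
# independent oracles


def oracle_glcm(q: np.ndarray, mask: np.ndarray, offset: int, directions) -> np.ndarray:
    """Pair-enumeration GLCM oracle: walk every pixel, list its partner."""
    levels = int(q[mask].max()) + 1 if mask.any() else 1
    h, w = q.shape
    mats = []
    for dr, dc in directions:
        mat = np.zeros((32, 32))
        count = 0
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr * offset, c + dc * offset
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    mat[q[r, c], q[r2, c2]] += 1
                    mat[q[r2, c2], q[r, c]] += 1
                    count += 1
        if count:
            mats.append(mat / mat.sum())
    if not mats:
        return np.zeros((32, 32))
    return np.mean(mats, axis=0)


def oracle_binary_texture(image, lesion, high):
    n_lesion = lesion.sum()
    eq_r = np.sqrt(n_lesion / np.pi)
    lr, lc = np.nonzero(lesion)
    hr, hc = np.nonzero(high)
    if len(hr) == 0:
        return {"AR": 0.0, "CDD": 0.0, "DD": 0.0}
    lcy, lcx = lr.mean(), lc.mean()
    hcy, hcx = hr.mean(), hc.mean()
    cdd = np.mean([np.sqrt((r - lcy) ** 2 + (c - lcx) ** 2) for r, c in zip(hr, hc)])
    dd = np.mean([np.sqrt((r - hcy) ** 2 + (c - hcx) ** 2) for r, c in zip(hr, hc)])
    return {"AR": len(hr) / n_lesion, "CDD": cdd / eq_r, "DD": dd / eq_r}


# ---------------------------------------------------------------------------


def small_lesion(values):
    """1-row lesion with the given pixel values, plus a constant reference."""
    img = np.zeros((16, 16), dtype=float)
    lesion = np.zeros((16, 16), dtype=bool)
    vals = np.asarray(values, dtype=float)
    img[8, 2 : 2 + len(vals)] = vals
    lesion[8, 2 : 2 + len(vals)] = True
    ref = np.zeros_like(lesion)
    ref[4, :] = True
    img[4, :] = 10.0
    return img, lesion, ref


class TestFirstOrder:
    def test_constant_lesion_and_reference(self):
        img = np.full((32, 32), 100.0)
        lesion = np.zeros((32, 32), dtype=bool)
        lesion[8:24, 8:24] = True
        ref = np.zeros_like(lesion)
        ref[2:6, :] = True
        v = first_order(img, lesion, ref)
        assert v["IMean"] == 100 and v["IMedian"] == 100
        assert v["Std_I"] == 0 and v["CoV"] == 0 and v["Entropy"] == 0
        assert v["RImean"] == 1 and v["RImedian"] == 1
        assert v["Skewness"] == 0 and v["Kurtosis"] == 0

    def test_five_pixel_lesion_hand_computed(self):
        img, lesion, ref = small_lesion([1, 2, 3, 4, 5])
        v = first_order(img, lesion, ref)
        assert v["IMean"] == 3 and v["IMedian"] == 3
        assert v["Std_I"] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert v["Variance"] == pytest.approx(2.0, abs=1e-12)
        assert v["IMin"] == 1 and v["IMax"] == 5 and v["IRange"] == 4
        assert v["RMS"] == pytest.approx(np.sqrt(11), abs=1e-12)
        assert v["Energy"] == pytest.approx(55.0)
        assert v["MAD"] == pytest.approx(1.2)

    def test_symmetric_histogram_has_zero_skewness(self):
        img, lesion, ref = small_lesion([10, 20, 30, 40, 50, 60, 70])
        v = first_order(img, lesion, ref)
        assert abs(v["Skewness"]) < 1e-9

    def test_exactly_28_features_with_frozen_names(self):
        img, lesion, ref = small_lesion([1, 2, 3, 4, 5])
        v = first_order(img, lesion, ref)
        assert tuple(v) == FIRST_ORDER_NAMES
        assert len(v) == 28

    def test_zero_mean_lesion_rejected(self):
        img, lesion, ref = small_lesion([0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="CoV"):
            first_order(img, lesion, ref)

    def test_rimean_is_one_when_lesion_matches_reference_mean(self):
        rng = np.random.default_rng(0)
        img = np.zeros((16, 16))
        lesion = np.zeros((16, 16), dtype=bool)
        lesion[8:12, 2:10] = True
        vals = rng.normal(50, 5, lesion.sum())
        img[lesion] = vals
        ref = np.zeros_like(lesion)
        ref[0:4, :] = True
        img[ref] = vals.mean()
        v = first_order(img, lesion, ref)
        assert v["RImean"] == pytest.approx(1.0, abs=1e-12)


class TestGlcm:
    def test_constant_lesion_degenerate_values_at_every_offset(self):
        img = np.full((32, 32), 7.0)
        lesion = np.zeros((32, 32), dtype=bool)
        lesion[8:24, 8:24] = True
        v = glcm_features(img, lesion)
        for d in range(1, 16):
            assert v[f"Ener{d}"] == 1.0 and v[f"Cont{d}"] == 0.0
            assert v[f"Entr{d}"] == 0.0 and v[f"Homo{d}"] == 1.0

    def test_checkerboard_contrast_matches_pair_enumeration(self):
        """4x4 two-level checkerboard, d=1, horizontal only: every horizontal
        pair alternates levels, so contrast equals (0-31)^2 exactly."""
        img = np.indices((4, 4)).sum(axis=0) % 2 * 255.0
        lesion = np.ones((4, 4), dtype=bool)
        p = glcm_matrix(img, lesion, 1, directions=[(0, 1)])
        stats = glcm_stats(p)
        q = quantize(img, lesion)
        oracle_p = oracle_glcm(np.where(lesion, q, -1), lesion, 1, [(0, 1)])
        assert np.allclose(p, oracle_p, atol=1e-12)
        assert stats["Cont"] == pytest.approx(31.0**2, abs=1e-9)
        assert stats["Ener"] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("offset", [1, 2, 5])
    def test_matrix_matches_exhaustive_oracle_on_8x8(self, seed, offset):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (8, 8)).astype(float)
        lesion = rng.random((8, 8)) < 0.7
        lesion[3:5, 3:5] = True  # guarantee some valid pairs
        p = glcm_matrix(img, lesion, offset)
        q = quantize(img, lesion)
        oracle_p = oracle_glcm(np.where(lesion, q, -1), lesion, offset,
                               [(0, 1), (-1, 1), (-1, 0), (-1, -1)])
        assert np.allclose(p, oracle_p, atol=1e-9)

    def test_sixty_features_with_canonical_names(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, (20, 20)).astype(float)
        lesion = np.zeros((20, 20), dtype=bool)
        lesion[2:18, 2:18] = True
        v = glcm_features(img, lesion)
        assert tuple(v) == GLCM_FEATURE_NAMES
        assert len(v) == 60

    def test_matrix_normalized_and_stats_in_range(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, (16, 16)).astype(float)
        lesion = np.zeros((16, 16), dtype=bool)
        lesion[2:14, 2:14] = True
        for d in (1, 4, 9):
            p = glcm_matrix(img, lesion, d)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            s = glcm_stats(p)
            assert 0 < s["Ener"] <= 1 and 0 < s["Homo"] <= 1
            assert s["Cont"] >= 0 and s["Entr"] >= 0

    def test_translation_and_intensity_rescale_invariance(self):
        rng = np.random.default_rng(6)
        patch = rng.integers(20, 200, (10, 10)).astype(float)
        img1 = np.zeros((32, 32))
        img1[4:14, 6:16] = patch
        lesion1 = np.zeros((32, 32), dtype=bool)
        lesion1[4:14, 6:16] = True
        img2 = np.zeros((32, 32))
        img2[15:25, 10:20] = 2.0 * patch + 30.0  # moved and affinely rescaled
        lesion2 = np.zeros((32, 32), dtype=bool)
        lesion2[15:25, 10:20] = True
        v1 = glcm_features(img1, lesion1)
        v2 = glcm_features(img2, lesion2)
        for name in v1:
            assert v1[name] == pytest.approx(v2[name], abs=1e-9)

    def test_offset_larger_than_lesion_warns_and_degenerates(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        lesion = np.zeros((5, 5), dtype=bool)
        lesion[1:4, 1:4] = True
        with pytest.warns(UserWarning, match="offset"):
            v = glcm_features(img, lesion, offsets=[4])
        assert v["Ener4"] == 1.0 and v["Homo4"] == 1.0


class TestBinaryTexture:
    def test_high_equals_lesion_gives_unit_area_ratio(self):
        lesion = np.zeros((16, 16), dtype=bool)
        lesion[4:12, 4:12] = True
        v = binary_texture(np.ones((16, 16)), lesion, lesion.copy())
        assert v["AR"] == 1.0

    def test_single_bright_pixel_at_centroid(self):
        lesion = np.zeros((17, 17), dtype=bool)
        lesion[4:13, 4:13] = True  # 9x9, centroid exactly at (8, 8)
        high = np.zeros_like(lesion)
        high[8, 8] = True
        v = binary_texture(np.ones((17, 17)), lesion, high)
        assert v["CDD"] == 0.0 and v["DD"] == 0.0
        assert v["AR"] == pytest.approx(1 / 81)

    def test_disc_with_bright_annulus_matches_distance_oracle(self, disc_mask):
        yy, xx = np.mgrid[0:64, 0:64]
        r2 = (xx - 32) ** 2 + (yy - 32) ** 2
        high = disc_mask & (r2 >= 6**2)
        img = np.where(high, 200.0, 50.0)
        v = binary_texture(img, disc_mask, high)
        o = oracle_binary_texture(img, disc_mask, high)
        for k in ("AR", "CDD", "DD"):
            assert v[k] == pytest.approx(o[k], abs=1e-9)

    def test_translation_invariance(self):
        lesion = np.zeros((32, 32), dtype=bool)
        lesion[4:12, 4:12] = True
        high = np.zeros_like(lesion)
        high[5:8, 5:8] = True
        v1 = binary_texture(np.ones((32, 32)), lesion, high)
        v2 = binary_texture(
            np.ones((32, 32)), np.roll(lesion, (10, 7), (0, 1)),
            np.roll(high, (10, 7), (0, 1)),
        )
        for k in BINARY_TEXTURE_NAMES:
            assert v1[k] == pytest.approx(v2[k], abs=1e-12)

    def test_empty_high_region_returns_zeros(self):
        lesion = np.zeros((8, 8), dtype=bool)
        lesion[2:6, 2:6] = True
        v = binary_texture(np.ones((8, 8)), lesion, np.zeros_like(lesion))
        assert v == {"AR": 0.0, "CDD": 0.0, "DD": 0.0}


class TestMorphology:
    def test_disc_area_and_solidity(self, disc_mask):
        v = morphology(disc_mask, pixel_spacing=1.0)
        assert v["Area"] == pytest.approx(np.pi * 100, rel=0.03)
        assert v["Solidity"] >= 0.98
        assert v["Area"] <= v["C.area"]

    def test_convex_lesion_hull_area_close_to_area(self, disc_mask):
        v = morphology(disc_mask, pixel_spacing=1.0)
        assert v["C.area"] == pytest.approx(v["Area"], rel=0.02)

    def test_rectangle_axis_ratio(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:20, 5:25] = True  # 10 rows x 20 cols
        v = morphology(mask, pixel_spacing=1.0)
        assert v["Maj.Len"] / v["Min.Len"] == pytest.approx(2.0, rel=0.05)
        assert v["BBoxW"] == 20 and v["BBoxH"] == 10
        assert v["Extent"] == pytest.approx(1.0)

    def test_pixel_spacing_scales_lengths_and_areas(self, disc_mask):
        v1 = morphology(disc_mask, pixel_spacing=1.0)
        v2 = morphology(disc_mask, pixel_spacing=0.2)
        assert v2["Area"] == pytest.approx(v1["Area"] * 0.04)
        assert v2["Maj.Len"] == pytest.approx(v1["Maj.Len"] * 0.2)
        assert v2["Solidity"] == pytest.approx(v1["Solidity"])  # dimensionless

    def test_fifteen_features_with_frozen_names(self, disc_mask):
        v = morphology(disc_mask)
        assert tuple(v) == MORPHOLOGY_NAMES

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[2:8, 2:8] = True
        mask[20:26, 20:26] = True
        with pytest.raises(ValueError, match="connected"):
            morphology(mask)


class TestExtractAndTables:
    def test_feature_counts_per_modality(self, small_cohort):
        b, smi = extract_case(small_cohort[0])
        assert len(b.values) == 106
        assert len(smi.values) == 91

    def test_extraction_deterministic(self, small_cohort):
        b1, s1 = extract_case(small_cohort[2])
        b2, s2 = extract_case(small_cohort[2])
        assert b1.values == b2.values and s1.values == s2.values

    def test_tables_shapes_and_suffixed_columns(self, small_cohort):
        tabs = build_tables(small_cohort)
        n = len(small_cohort)
        assert tabs.b.shape == (n, 106)
        assert tabs.smi.shape == (n, 91)
        assert tabs.dual.shape == (n, 197)
        assert {"IMean_B", "IMean_SMI", "Cont8_SMI", "Area_B"} <= set(tabs.dual.columns)
        assert list(tabs.b.index) == list(tabs.dual.index)
        assert not tabs.dual.isna().any().any()

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_tables([])

    def test_spatial_name_inventory_is_91(self):
        assert len(SPATIAL_NAMES) == 91
        assert len(set(SPATIAL_NAMES)) == 91
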