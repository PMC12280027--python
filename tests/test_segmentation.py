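"""Segmentation operators: preprocessing, thresholding, islet assembly,
compartmentalisation, and their partition/monotonicity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage as ndi
from skimage.morphology import disk

from isletmorph import (
    MultiChannelSection,
    assemble_islets,
    compartmentalize,
    derive_exocrine,
    preprocess_channel,
    segment_section,
    segment_tissue,
    threshold_channel,
)


def brute_force_otsu(raster: np.ndarray) -> float:
    """Exhaustive 256-level search maximising between-class variance."""
    levels = np.linspace(raster.min(), raster.max(), 256)
    best_t, best_var = levels[0], -1.0
    flat = raster.ravel().astype(float)
    for t in levels[:-1]:
        lo, hi = flat[flat <= t], flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / flat.size, hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestPreprocess:
    def test_filters_preserve_constants(self):
        raster = np.full((32, 32), 17.0)
        out = preprocess_channel(raster, closing_radius=2, mean_radius=2)
        assert np.allclose(out, 17.0)

    def test_zero_radii_is_identity(self):
        rng = np.random.default_rng(0)
        raster = rng.random((20, 20)).astype(np.float32)
        out = preprocess_channel(raster, closing_radius=0, mean_radius=0)
        assert np.array_equal(out, raster)

    def test_closing_fills_one_pixel_hole(self):
        # bright 7x7 square with a single dark pixel inside
        raster = np.zeros((15, 15), dtype=np.float32)
        raster[4:11, 4:11] = 100.0
        raster[7, 7] = 0.0
        out = preprocess_channel(raster, closing_radius=1, mean_radius=0)
        # oracle: explicit dilation then erosion with the same disc element
        element = disk(1)
        oracle = ndi.grey_erosion(
            ndi.grey_dilation(raster, footprint=element), footprint=element
        )
        assert out[7, 7] == 100.0
        assert np.array_equal(out, oracle)

    def test_radius_exceeding_image_errors(self):
        with pytest.raises(ValueError, match="exceeds image size"):
            preprocess_channel(np.zeros((8, 8)), closing_radius=10)
        with pytest.raises(ValueError, match=">= 0"):
            preprocess_channel(np.zeros((8, 8)), closing_radius=-1)


class TestThreshold:
    def test_two_valued_raster_separates_modes(self):
        raster = np.zeros((10, 10))
        raster[:3] = 100.0
        mask, t = threshold_channel(raster, "otsu")
        assert 0 < t < 100
        assert np.array_equal(mask, raster == 100.0)

    def test_otsu_matches_brute_force_search(self):
        rng = np.random.default_rng(3)
        raster = np.concatenate(
            [rng.normal(50, 10, 600), rng.normal(180, 15, 400)]
        ).clip(0, 255).astype(np.uint8).reshape(40, 25)
        _, t = threshold_channel(raster, "otsu")
        oracle = brute_force_otsu(raster.astype(float))
        # both land in the same inter-mode valley
        mask_impl = raster > t
        mask_oracle = raster > oracle
        assert np.mean(mask_impl ^ mask_oracle) < 0.01

    def test_fixed_matches_otsu_on_bimodal(self):
        raster = np.zeros((10, 10))
        raster[5:] = 100.0
        mask_fixed, t = threshold_channel(raster, "fixed", 50.0)
        mask_otsu, _ = threshold_channel(raster, "otsu")
        assert t == 50.0
        assert np.array_equal(mask_fixed, mask_otsu)

    def test_constant_raster_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant raster"):
            mask, _ = threshold_channel(np.full((5, 5), 3.0), "otsu")
        assert not mask.any()

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError):
            threshold_channel(np.zeros((4, 4)), "magic")


class TestTissue:
    def test_blank_section_gives_empty_tissue(self):
        section = MultiChannelSection(
            {"glucagon": np.zeros((16, 16)), "insulin": np.zeros((16, 16))},
            pixel_size=1.0,
        )
        assert not segment_tissue(section).any()

    def test_tissue_contains_all_hormone_pixels(self, clean_section):
        section, _ = clean_section
        comps = segment_section(section)
        hormone = comps.alpha_only | comps.beta_only | comps.bihormonal
        assert np.all(comps.tissue[hormone])

    def test_tissue_footprint_recovered_noise_free(self, clean_section):
        section, truth = clean_section
        comps = segment_section(section)
        rel = abs(comps.tissue.sum() - truth.masks["tissue"].sum())
        assert rel / truth.masks["tissue"].sum() < 0.05


class TestAssembleIslets:
    def test_empty_masks_give_zero_islets(self):
        z = np.zeros((20, 20), dtype=bool)
        assert assemble_islets(z, z, pixel_size=1.0).max() == 0

    def test_size_filter_retains_only_large_blob(self):
        # 900 um^2 and 1100 um^2 blobs at 1 um/px, min_area 1000
        alpha = np.zeros((100, 100), dtype=bool)
        alpha[5:35, 5:35] = True  # 900 px
        beta = np.zeros_like(alpha)
        beta[50:94, 50:75] = True  # 1100 px
        labels = assemble_islets(alpha, beta, min_area=1000.0, pixel_size=1.0)
        assert labels.max() == 1
        # oracle: connected-component area enumeration on the raw union
        union_labels, n = ndi.label(alpha | beta)
        areas = np.bincount(union_labels.ravel())[1:]
        assert sorted(areas) == [900, 1100]
        assert np.count_nonzero(labels) == 1100

    def test_touching_blobs_share_one_label(self):
        alpha = np.zeros((40, 40), dtype=bool)
        beta = np.zeros_like(alpha)
        alpha[10:30, 5:20] = True
        beta[10:30, 20:36] = True  # touches alpha at column 20
        labels = assemble_islets(alpha, beta, min_area=0.0, pixel_size=1.0)
        assert labels.max() == 1

    def test_closing_joins_nearby_blobs(self):
        alpha = np.zeros((40, 40), dtype=bool)
        beta = np.zeros_like(alpha)
        alpha[10:30, 5:18] = True
        beta[10:30, 20:36] = True  # 2 px gap, closed by the disc element
        labels = assemble_islets(
            alpha, beta, min_area=0.0, pixel_size=1.0, closing_radius=2
        )
        assert labels.max() == 1
        # labels exist only on hormone-positive pixels
        assert not labels[:, 18:20].any()

    def test_lowering_min_area_never_decreases_count(self):
        rng = np.random.default_rng(5)
        alpha = rng.random((80, 80)) > 0.7
        beta = rng.random((80, 80)) > 0.7
        counts = [
            assemble_islets(alpha, beta, min_area=a, pixel_size=1.0).max()
            for a in (400.0, 100.0, 10.0, 0.0)
        ]
        assert counts == sorted(counts)


class TestCompartmentalize:
    def test_alpha_only_mask(self):
        alpha = np.zeros((20, 20), dtype=bool)
        alpha[2:12, 2:12] = True
        beta = np.zeros_like(alpha)
        labels = assemble_islets(alpha, beta, min_area=0.0, pixel_size=1.0)
        a, b, h = compartmentalize(labels, alpha, beta)
        assert not h.any() and not b.any()
        assert np.array_equal(a, alpha)

    def test_overlapping_squares_pixel_oracle(self):
        # 10x10 squares offset by 5 px -> bihormonal 50 px
        alpha = np.zeros((30, 30), dtype=bool)
        beta = np.zeros_like(alpha)
        alpha[5:15, 5:15] = True
        beta[5:15, 10:20] = True
        labels = assemble_islets(alpha, beta, min_area=0.0, pixel_size=1.0)
        a, b, h = compartmentalize(labels, alpha, beta)
        assert h.sum() == 50
        assert a.sum() + b.sum() + h.sum() == (alpha | beta).sum()

    def test_disjoint_masks_have_no_bihormonal(self):
        alpha = np.zeros((20, 20), dtype=bool)
        beta = np.zeros_like(alpha)
        alpha[2:8, 2:8] = True
        beta[2:8, 9:15] = True
        labels = assemble_islets(labels_src := alpha, beta, min_area=0.0, pixel_size=1.0)
        _, _, h = compartmentalize(labels, labels_src, beta)
        assert not h.any()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        alpha=hnp.arrays(bool, (24, 24), elements=st.booleans()),
        beta=hnp.arrays(bool, (24, 24), elements=st.booleans()),
    )
    def test_partition_property(self, alpha, beta):
        """alpha-only + beta-only + bihormonal tile the islet footprint exactly."""
        labels = assemble_islets(alpha, beta, min_area=0.0, pixel_size=1.0)
        a, b, h = compartmentalize(labels, alpha, beta)
        footprint = labels > 0
        assert a.sum() + b.sum() + h.sum() == footprint.sum()
        assert np.array_equal(a | b | h, footprint)
        assert not (a & b).any() and not (a & h).any() and not (b & h).any()

    def test_idempotence(self, analyzed_clean):
        """Re-running compartmentalize on its own outputs is a fixed point."""
        _, comps = analyzed_clean
        alpha2 = comps.alpha_only | comps.bihormonal
        beta2 = comps.beta_only | comps.bihormonal
        a, b, h = compartmentalize(comps.whole_islet, alpha2, beta2)
        assert np.array_equal(a, comps.alpha_only)
        assert np.array_equal(b, comps.beta_only)
        assert np.array_equal(h, comps.bihormonal)


class TestExocrine:
    def test_set_difference_oracle(self):
        tissue = np.zeros((120, 120), dtype=bool)
        tissue[10:110, 10:110] = True  # 10,000 px
        labels = np.zeros((120, 120), dtype=np.int32)
        labels[20:60, 20:45] = 1  # 1,000 px inside
        exo = derive_exocrine(tissue, labels)
        assert exo.sum() == 9000

    def test_tissue_equals_islet_gives_empty(self):
        tissue = np.zeros((10, 10), dtype=bool)
        tissue[2:6, 2:6] = True
        labels = tissue.astype(np.int32)
        assert not derive_exocrine(tissue, labels).any()

    def test_no_islets_gives_whole_tissue(self):
        tissue = np.ones((8, 8), dtype=bool)
        exo = derive_exocrine(tissue, np.zeros((8, 8), dtype=np.int32))
        assert np.array_equal(exo, tissue)


def test_noise_free_recovery_within_five_percent(clean_section, analyzed_clean):
    """Noise-free synthetic sections: every compartment area within 5% of truth."""
    _, truth = clean_section
    metrics, comps = analyzed_clean
    assert comps.check_partition()
    for name in ("islet", "alpha", "beta", "bihormonal", "tissue", "exocrine"):
        est = metrics[f"{name}_area_um2"]
        assert est == pytest.approx(truth.areas[name], rel=0.05), name
    assert metrics["islet_count"] == truth.islet_count
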