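"""Otsu thresholding and vacuole-candidate detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import steatoquant as sq
from steatoquant.detect import collagen_annulus, otsu_threshold


def brute_force_otsu(hist):
    """Independent oracle: exhaustive argmax of between-class variance."""
    hist = list(hist)
    total = sum(hist)
    best_level, best_var = None, -1.0
    for t in range(len(hist) - 1):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * h for i, h in enumerate(hist[: t + 1])) / w0
        mu1 = sum(i * h for i, h in enumerate(hist[t + 1 :], start=t + 1)) / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_level = var, t
    return best_level


def _slide(tpef, shg=None, px=1.0):
    if shg is None:
        shg = np.zeros_like(np.asarray(tpef, dtype=float))
    return sq.SlideImage(shg, tpef, pixel_size_um=px)


def _disk_image(radius_px, size=128, value=0.0, background=200.0):
    yy, xx = np.mgrid[-size // 2 : size // 2, -size // 2 : size // 2]
    tpef = np.full((size, size), background)
    tpef[yy**2 + xx**2 <= radius_px**2] = value
    return tpef


class TestOtsu:
    def test_two_point_histogram_separates_modes(self):
        hist = np.zeros(256)
        hist[50] = 1000
        hist[200] = 1000
        t = otsu_threshold(hist)
        assert 50 <= t < 200  # all 50s in the low class, all 200s in the high

    def test_degenerate_single_level(self):
        hist = np.zeros(256)
        hist[77] = 10
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(hist)

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            hist = rng.poisson(rng.uniform(0, 50), size=256)
            if np.count_nonzero(hist) < 2:
                continue
            assert otsu_threshold(hist) == brute_force_otsu(hist)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=100), min_size=4, max_size=32)
    )
    def test_matches_brute_force_property(self, counts):
        hist = np.array(counts)
        if np.count_nonzero(hist) < 2:
            with pytest.raises(ValueError):
                otsu_threshold(hist)
        else:
            assert otsu_threshold(hist) == brute_force_otsu(hist)


class TestDetectCandidates:
    def test_single_dark_disk(self):
        tpef = _disk_image(radius_px=10)
        img = _slide(tpef)
        tissue = sq.TissueMask(np.ones_like(tpef, dtype=bool), 1.0)
        cands = sq.detect_candidates(img, tissue)
        assert len(cands) == 1
        assert cands[0].equivalent_diameter_um == pytest.approx(20.0, rel=0.05)
        assert cands[0].circularity == pytest.approx(1.0, abs=0.1)
        assert cands[0].mean_tpef_intensity == pytest.approx(0.0, abs=1e-9)

    def test_square_circularity_approaches_pi_over_4(self):
        tpef = np.full((256, 256), 200.0)
        tpef[64:192, 64:192] = 0.0
        img = _slide(tpef)
        tissue = sq.TissueMask(np.ones((256, 256), dtype=bool), 1.0)
        (cand,) = sq.detect_candidates(img, tissue, max_diameter_um=300)
        assert cand.circularity == pytest.approx(math.pi / 4, abs=0.05)

    def test_two_to_one_ellipse_axis_ratio(self):
        yy, xx = np.mgrid[-64:64, -64:64]
        tpef = np.where((xx / 40.0) ** 2 + (yy / 20.0) ** 2 <= 1, 0.0, 200.0)
        img = _slide(tpef)
        tissue = sq.TissueMask(np.ones((128, 128), dtype=bool), 1.0)
        (cand,) = sq.detect_candidates(img, tissue)
        assert cand.length_width_ratio == pytest.approx(2.0, rel=0.05)

    def test_border_touching_component_excluded(self):
        tpef = np.full((64, 64), 200.0)
        tpef[0:10, 20:30] = 0.0  # touches row 0
        img = _slide(tpef)
        tissue = sq.TissueMask(np.ones((64, 64), dtype=bool), 1.0)
        assert sq.detect_candidates(img, tissue) == []

    def test_intensity_scale_invariance(self, default_phantom, default_tissue):
        img, _ = default_phantom
        cands = sq.detect_candidates(img, default_tissue)
        scaled = sq.SlideImage(
            img.shg * 4.0, img.tpef * 4.0, img.pixel_size_um
        )
        cands_scaled = sq.detect_candidates(scaled, default_tissue)
        assert len(cands) == len(cands_scaled)
        for a, b in zip(cands, cands_scaled):
            assert a.bbox == b.bbox
            assert np.array_equal(a.mask, b.mask)

    def test_candidates_disjoint_and_inside_tissue(
        self, default_candidates, default_tissue
    ):
        seen = np.zeros(default_tissue.mask.shape, dtype=bool)
        for c in default_candidates:
            patch = seen[c.bbox]
            assert not (patch & c.mask).any()
            patch |= c.mask
            assert default_tissue.mask[c.bbox][c.mask].all()

    def test_diameter_consistent_with_area(self, default_candidates):
        for c in default_candidates:
            assert c.equivalent_diameter_um == pytest.approx(
                2 * math.sqrt(c.area_um2 / math.pi), rel=1e-6
            )

    def test_feature_invariants(self, default_candidates):
        for c in default_candidates:
            assert c.area_um2 > 0
            assert 0 < c.circularity <= 1
            assert c.length_width_ratio >= 1
            assert 0 < c.solidity <= 1
            assert 0 <= c.collagen_annulus_fraction <= 1

    def test_phantom_fat_recall(self, default_phantom, default_candidates):
        _, truth = default_phantom
        centroids = np.array([c.centroid_um for c in default_candidates])
        found = 0
        for o in truth.fat_objects:
            d = np.hypot(
                centroids[:, 0] - o.centroid_um[0],
                centroids[:, 1] - o.centroid_um[1],
            )
            found += (d <= 2.0).any()
        assert found / len(truth.fat_objects) >= 0.95

    def test_textured_background_without_holes_yields_nothing(self):
        rng = np.random.default_rng(4)
        tpef = 150.0 + rng.normal(0, 10, size=(256, 256))
        tpef = np.maximum(tpef, 0)
        img = _slide(tpef)
        tissue = sq.TissueMask(np.ones((256, 256), dtype=bool), 1.0)
        assert sq.detect_candidates(img, tissue) == []


class TestCollagenAnnulus:
    def test_portal_ring_high_fraction(self, default_phantom, default_candidates):
        img, truth = default_phantom
        portal_ids = {o.id for o in truth.objects if o.vessel_type == "portal_tract"}
        hits = 0
        for c in default_candidates:
            ids = truth.label_raster[c.bbox][c.mask]
            ids = ids[ids > 0]
            if ids.size and int(np.bincount(ids).argmax()) in portal_ids:
                area, frac = collagen_annulus(c, img.shg, img.pixel_size_um, 5.0)
                assert frac >= 0.5
                assert area > 0
                hits += 1
        assert hits >= 1

    def test_zero_shg_gives_zero(self, default_candidates):
        c = default_candidates[0]
        shape = (1024, 1024)
        area, frac = collagen_annulus(c, np.zeros(shape), 0.390625, 5.0)
        assert (area, frac) == (0.0, 0.0)

    def test_invalid_width(self, default_candidates):
        with pytest.raises(ValueError):
            collagen_annulus(default_candidates[0], np.zeros((8, 8)), 1.0, 0.0)
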