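"""Hotspot detection, artifact triage and margin status rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from farkit.imaging import FarImage
from farkit.margins import (
    MARGIN_NAMES,
    Hotspot,
    classify_artifacts,
    detect_hotspots,
    far_margin_status,
    histo_margin_status,
)
from farkit.phantom import InjectionRecord
from farkit.pipeline import assess_specimen
from farkit.quant import Roi, roi_stats


def _image(arr, pitch=938.0):
    return FarImage(radiance=np.asarray(arr, float), pixel_pitch=pitch)


def _tbg(image, mask=None):
    mask = np.ones(image.radiance.shape, bool) if mask is None else mask
    return roi_stats(image, Roi("TBG", mask), 1.0)


class TestDetectHotspots:
    def test_uniform_image_has_no_hotspots(self):
        img = _image(np.full((20, 20), 50.0))
        assert detect_hotspots(img, _tbg(img), np.ones((20, 20), bool)) == []

    def test_three_by_three_component_diameter(self):
        """9 pixels of 938 um pitch: d = 2*sqrt(9*0.938^2/pi) ~ 3.18 mm."""
        arr = np.full((20, 20), 10.0)
        bg_mask = np.ones((20, 20), bool)
        bg_mask[8:11, 8:11] = False
        arr[8:11, 8:11] = 1000.0
        img = _image(arr)
        hs = detect_hotspots(img, _tbg(img, bg_mask), np.ones((20, 20), bool))
        assert len(hs) == 1
        expected = 2.0 * math.sqrt(9 * 0.938**2 / math.pi)
        assert hs[0].equivalent_diameter_mm == pytest.approx(expected, rel=1e-12)
        assert hs[0].equivalent_diameter_mm == pytest.approx(3.18, abs=0.01)

    def test_sub_threshold_bump_ignored(self):
        # checkerboard background: mean 50, sd 5 exactly
        arr = np.full((20, 20), 45.0)
        arr[::2, ::2] = 55.0
        arr[1::2, 1::2] = 55.0
        stats = _tbg(_image(arr))
        assert (stats.mean, stats.sd) == (50.0, 5.0)
        arr2 = arr.copy()
        arr2[5:8, 5:8] = stats.mean + 1.5 * stats.sd  # below mean + 2 sd
        assert detect_hotspots(_image(arr2), stats, np.ones((20, 20), bool)) == []

    def test_raising_k_shrinks_the_detected_region(self, rng):
        """Monotone filtering: the union of hotspot pixels at a higher k is
        contained in the union at any lower k (components may merge or split,
        so pixel-set inclusion is the invariant, not the component count)."""
        arr = np.clip(rng.normal(50.0, 20.0, (30, 30)), 0, None)
        img = _image(arr)
        stats = _tbg(img)
        mask = np.ones((30, 30), bool)

        def union(k):
            hs = detect_hotspots(img, stats, mask, k=k)
            out = np.zeros((30, 30), bool)
            for h in hs:
                out |= h.mask
            return out

        unions = [union(k) for k in (0.5, 1.0, 2.0, 3.0)]
        for bigger, smaller in zip(unions, unions[1:]):
            assert np.all(bigger[smaller]), "higher-k pixels must persist at lower k"

    def test_min_pixel_guard_drops_single_pixel_components(self):
        arr = np.full((10, 10), 10.0)
        arr[5, 5] = 1000.0
        bg = np.ones((10, 10), bool)
        bg[5, 5] = False
        img = _image(arr)
        # a lone 938 um pixel has equivalent diameter 1.06 mm: kept by default
        assert len(detect_hotspots(img, _tbg(img, bg), np.ones((10, 10), bool))) == 1
        assert (
            detect_hotspots(img, _tbg(img, bg), np.ones((10, 10), bool), min_pixels=2)
            == []
        )

    def test_missing_background_stats_rejected(self):
        img = _image(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            detect_hotspots(img, None, np.ones((4, 4), bool))


def _hotspot_from_mask(image, mask):
    vals = image.radiance[mask]
    r, c = np.argwhere(mask).mean(axis=0)
    area = mask.sum() * (image.pixel_pitch / 1000.0) ** 2
    return Hotspot(
        mask=mask,
        centroid=(float(r), float(c)),
        area_mm2=area,
        peak_normalized=float(vals.max()),
        mean_normalized=float(vals.mean()),
    )


class TestClassifyArtifacts:
    def test_comet_tail_strike_classified_as_gamma_strike(self):
        arr = np.full((20, 20), 10.0)
        arr[10, 5] = 65535.0
        arr[10, 6:10] = [30000.0, 14000.0, 6000.0, 2000.0]
        img = _image(arr)
        mask = arr > 1000.0
        hs = _hotspot_from_mask(img, mask)
        assert classify_artifacts(hs, img) == "gamma_strike"
        assert hs.classification == "gamma_strike"

    def test_full_field_saturation_is_white_square(self):
        img = _image(np.full((20, 20), 65535.0))
        hs = _hotspot_from_mask(img, np.ones((20, 20), bool))
        assert classify_artifacts(hs, img) == "white_square"

    def test_annular_component_is_ring(self):
        arr = np.full((30, 30), 10.0)
        yy, xx = np.mgrid[0:30, 0:30]
        r2 = (yy - 15) ** 2 + (xx - 15) ** 2
        mask = (r2 <= 144) & (r2 >= 100)
        arr[mask] = 500.0
        img = _image(arr)
        hs = _hotspot_from_mask(img, mask)
        assert classify_artifacts(hs, img) == "ring"

    def test_simulated_surface_focus_is_tumour(self, superior_specimen, quiet_settings, record):
        res = assess_specimen(
            superior_specimen, record, quiet_settings, noise=False
        )
        assert [h.classification for h in res["hotspots"]] == ["tumour"]

    def test_classification_set_exactly_once(self):
        img = _image(np.full((4, 4), 10.0))
        hs = _hotspot_from_mask(img, np.ones((4, 4), bool))
        hs.classify("tumour")
        with pytest.raises(ValueError):
            hs.classify("ring")


class TestFarMarginStatus:
    def _sectors(self, shape=(30, 30)):
        sectors = {}
        h, w = shape
        cols = np.array_split(np.arange(w), 6)
        for name, cc in zip(MARGIN_NAMES, cols):
            m = np.zeros(shape, bool)
            m[:, cc] = True
            sectors[name] = m
        return sectors

    def _tumour_hotspot(self, shape, rc):
        mask = np.zeros(shape, bool)
        mask[rc] = True
        hs = Hotspot(
            mask=mask, centroid=(float(rc[0]), float(rc[1])), area_mm2=1.0,
            peak_normalized=1.0, mean_normalized=1.0,
        )
        hs.classify("tumour")
        return hs

    def test_no_hotspots_all_margins_negative(self):
        status = far_margin_status([], self._sectors())
        assert set(status.values()) == {"negative"}

    def test_hotspot_in_superior_sector_flags_only_superior(self):
        sectors = self._sectors()
        col = int(np.argwhere(sectors["superior"][0]).mean())
        hs = self._tumour_hotspot((30, 30), (15, col))
        status = far_margin_status([hs], sectors)
        assert status["superior"] == "positive"
        assert sum(v == "positive" for v in status.values()) == 1
        assert hs.assigned_margin == "superior"

    def test_artifact_hotspots_never_flag_margins(self):
        sectors = self._sectors()
        mask = np.zeros((30, 30), bool)
        mask[15, 2] = True
        hs = Hotspot(mask=mask, centroid=(15.0, 2.0), area_mm2=1.0,
                     peak_normalized=1.0, mean_normalized=1.0)
        hs.classify("gamma_strike")
        status = far_margin_status([hs], sectors)
        assert set(status.values()) == {"negative"}

    def test_missing_sector_rejected(self):
        sectors = self._sectors()
        del sectors["medial"]
        with pytest.raises(ValueError, match="medial"):
            far_margin_status([], sectors)

    def test_statuses_invariant_under_scene_translation(self):
        shape = (40, 40)
        sectors = {}
        for i, name in enumerate(MARGIN_NAMES):
            m = np.zeros(shape, bool)
            m[2 + i, 2:8] = True
            sectors[name] = m
        hs = self._tumour_hotspot(shape, (4, 5))
        base = far_margin_status([hs], sectors)

        shifted_sectors = {k: np.roll(v, (7, 9), axis=(0, 1)) for k, v in sectors.items()}
        hs2 = self._tumour_hotspot(shape, (4 + 7, 5 + 9))
        shifted = far_margin_status([hs2], shifted_sectors)
        assert base == shifted


class TestHistoMarginStatus:
    @pytest.mark.parametrize(
        "inv, dcis, rule, expected",
        [
            (0.0, None, "site12", "positive"),
            (0.5, None, "site3", "positive"),
            (0.5, 1.5, "site12", "negative"),
            (0.5, 1.5, "site3", "positive"),  # DCIS < 2 mm
            (None, 0.0, "site12", "positive"),
            (None, 1.9, "site3", "positive"),
            (None, 2.0, "site3", "negative"),
            (1.0, None, "site3", "negative"),
            (5.0, 5.0, "site12", "negative"),
            (None, None, "site3", "negative"),  # both components absent
            (float("nan"), None, "site12", "negative"),
        ],
    )
    def test_site_rules(self, inv, dcis, rule, expected):
        assert histo_margin_status(inv, dcis, rule) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            histo_margin_status(-0.1, None, "site12")
        with pytest.raises(ValueError):
            histo_margin_status(0.0, None, "site4")

    @settings(derandomize=True, max_examples=200)
    @given(
        inv=st.floats(0.0, 5.0, allow_nan=False),
        dcis=st.floats(0.0, 5.0, allow_nan=False),
        shrink=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_site3_monotone_in_distances(self, inv, dcis, shrink):
        """Decreasing either distance never flips positive -> negative."""
        before = histo_margin_status(inv, dcis, "site3")
        after = histo_margin_status(inv * shrink, dcis * shrink, "site3")
        if before == "positive":
            assert after == "positive"
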