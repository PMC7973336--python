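"""Forward model, acquisition noise and cohort generator."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from farkit.imaging import median_combine
from farkit.phantom import (
    AcquisitionSettings,
    CohortParams,
    DetectionModel,
    FluxParams,
    InjectionRecord,
    TumourFocus,
    inject_gamma_strikes,
    make_cohort,
    make_specimen,
    simulate_frames,
    surface_flux_map,
)


class TestSurfaceFlux:
    def test_depth_zero_focus_reaches_reference_tumour_radiance(self):
        """Calibration identity: a surface focus peaks at 126.7 per MBq."""
        ph = make_specimen(foci=[TumourFocus((0, 0), 10.0)])
        flux = surface_flux_map(ph, 97.0)
        assert flux.max() / 97.0 == pytest.approx(126.7, abs=1e-9)

    def test_background_radiance_inside_contour(self):
        ph = make_specimen()
        flux = surface_flux_map(ph, 10.0)
        inside = flux[ph.contour_mask]
        assert np.allclose(inside, 10.0 * 56.5)
        assert np.all(flux[~ph.contour_mask] == 0.0)

    def test_focus_deeper_than_positron_range_adds_nothing(self):
        ph = make_specimen(foci=[TumourFocus((0, 0), 5.0, depth_below_surface=1.5)])
        flux = surface_flux_map(ph, 50.0)
        assert np.allclose(flux[ph.contour_mask], 50.0 * 56.5)

    def test_half_value_depth_halves_the_focal_excess(self):
        """At depth lambda*ln2 the exponential excess is exactly halved."""
        p = FluxParams()
        shallow = make_specimen(foci=[TumourFocus((0, 0), 5.0, 0.0)])
        deep = make_specimen(foci=[TumourFocus((0, 0), 5.0, p.lam * math.log(2))])
        e0 = surface_flux_map(shallow, 1.0, p).max() - p.k_bg
        e1 = surface_flux_map(deep, 1.0, p).max() - p.k_bg
        assert e1 == pytest.approx(e0 / 2, rel=1e-12)

    def test_flux_scales_linearly_with_activity(self):
        ph = make_specimen(foci=[TumourFocus((0, 5.0), 4.0)])
        f1 = surface_flux_map(ph, 50.0)
        f2 = surface_flux_map(ph, 100.0)
        assert np.allclose(f2, 2.0 * f1)

    def test_deeper_focus_never_exceeds_shallower(self):
        depths = [0.0, 0.2, 0.5, 0.9]
        peaks = []
        for d in depths:
            ph = make_specimen(foci=[TumourFocus((0, 0), 5.0, d)])
            peaks.append(surface_flux_map(ph, 1.0).max())
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_invalid_inputs_rejected(self):
        ph = make_specimen()
        with pytest.raises(ValueError):
            surface_flux_map(ph, 0.0)
        with pytest.raises(ValueError):
            surface_flux_map(
                make_specimen(foci=[TumourFocus((100.0, 0), 2.0)]), 10.0
            )
        with pytest.raises(ValueError):
            TumourFocus((0, 0), radius=-1.0)
        with pytest.raises(ValueError):
            TumourFocus((0, 0), radius=1.0, uptake_factor=0.5)


class TestSimulateFrames:
    def test_zero_flux_zero_dark_gives_zero_counts(self, quiet_settings, rng):
        stack = simulate_frames(np.zeros((16, 16)), quiet_settings, rng)
        assert np.all(stack.frames == 0)

    def test_poisson_sample_mean_matches_expectation(self, quiet_settings, rng):
        """Mean of 10_000 pixels at expected 50 counts is within 3*sqrt(50/1e4)."""
        s = AcquisitionSettings(gamma_strike_rate=0.0, gain=1e-4)
        flux = np.full((100, 100), 50.0 / (s.gain * s.frame_exposure))
        stack = simulate_frames(flux, s, rng)
        assert abs(stack.frames[0].mean() - 50.0) < 3.0 * math.sqrt(50.0 / 10_000)

    def test_noiseless_frames_equal_expected_counts(self, quiet_settings):
        flux = np.linspace(0, 100, 64).reshape(8, 8)
        stack = simulate_frames(flux, quiet_settings, 0, noise=False)
        expected = flux * quiet_settings.gain * quiet_settings.frame_exposure
        assert np.allclose(stack.frames, expected[None])

    def test_seeded_runs_bit_reproducible(self, quiet_settings):
        flux = np.full((32, 32), 1000.0)
        a = simulate_frames(flux, quiet_settings, 7).frames
        b = simulate_frames(flux, quiet_settings, 7).frames
        c = simulate_frames(flux, quiet_settings, 8).frames
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_negative_flux_rejected(self, quiet_settings):
        with pytest.raises(ValueError):
            simulate_frames(np.full((4, 4), -1.0), quiet_settings, 0)


class TestGammaStrikes:
    def test_rate_zero_leaves_frame_unchanged(self, rng):
        frame = rng.poisson(10.0, (32, 32)).astype(float)
        out = inject_gamma_strikes(frame, 0.0, rng)
        assert np.array_equal(out, frame)

    def test_single_strike_is_saturated_peak_with_decaying_tail(self):
        # find a seed producing exactly one event
        for seed in range(100):
            frame = np.zeros((32, 32))
            out = inject_gamma_strikes(frame, 1.0, seed, saturation=65535)
            if (out == 65535).sum() == 1:
                break
        else:
            pytest.fail("no seed with exactly one strike")
        r, c = np.argwhere(out == 65535)[0]
        tail = out[r, c:]
        nz = tail[tail > 0]
        assert nz[0] == 65535
        assert np.all(np.diff(nz) < 0), "tail must decay monotonically"
        # tail is one-sided: nothing added left of the peak
        assert np.all(out[r, :c] == 0)

    def test_mean_strike_count_matches_rate(self, rng):
        """Over 500 frames at rate 2 the strike mean is within 3*sqrt(2/500)."""
        rate, n = 2.0, 500
        counts = []
        for _ in range(n):
            out = inject_gamma_strikes(np.zeros((64, 64)), rate, rng)
            counts.append(int((out == 65535).sum()))
        assert abs(np.mean(counts) - rate) < 3.0 * math.sqrt(rate / n)

    def test_median_combination_removes_single_frame_strikes(self, rng):
        """A strike lives in one frame only, so no strike amplitude survives
        the 27-sample median: the output stays within the clean stack's
        neighbourhood extremes everywhere."""
        from scipy import ndimage

        from farkit.imaging import FrameStack

        base = rng.poisson(100.0, (3, 32, 32)).astype(float)
        struck = base.copy()
        struck[1] = inject_gamma_strikes(base[1], 5.0, rng)
        assert struck[1].max() == 65535.0, "at least one strike injected"
        combined = median_combine(
            FrameStack(frames=struck, frame_exposure=100.0, pixel_pitch=938.0)
        )
        hi = ndimage.maximum_filter(base, size=(3, 3, 3), mode="nearest")[1]
        lo = ndimage.minimum_filter(base, size=(3, 3, 3), mode="nearest")[1]
        assert np.all(combined <= hi) and np.all(combined >= lo)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_gamma_strikes(np.zeros((8, 8)), -1.0, 0)


class TestMakeCohort:
    def test_single_patient_structure(self):
        c = make_cohort(1, seed=0)
        assert len(c.margins) == 6
        assert len(c.patients) == 1
        a = c.patients["injected_mbq"].iloc[0]
        assert 185.0 <= a <= 334.0
        rec = c.injection_record(c.patients["patient_id"].iloc[0])
        assert 60.0 <= rec.minutes_post_injection <= 180.0

    def test_prevalence_converges_to_configured_value(self):
        """Empirical positive-margin rate within 3 binomial SEs at n=10_000."""
        p = 13 / 385
        c = make_cohort(10_000, seed=1)
        n = len(c.margins)
        emp = (c.margins["histo_status"] == "positive").mean()
        assert abs(emp - p) < 3.0 * math.sqrt(p * (1 - p) / n)

    def test_activity_moments_match_truncated_normal(self):
        params = CohortParams()
        a, b = (
            (params.activity_bounds[0] - params.activity_mean) / params.activity_sd,
            (params.activity_bounds[1] - params.activity_mean) / params.activity_sd,
        )
        mu, var = sps.truncnorm.stats(
            a, b, loc=params.activity_mean, scale=params.activity_sd, moments="mv"
        )
        c = make_cohort(5000, params, seed=2)
        emp = c.margins["patient_id"].map(
            c.patients.set_index("patient_id")["injected_mbq"]
        )
        se = math.sqrt(float(var) / 5000)
        assert abs(c.patients["injected_mbq"].mean() - float(mu)) < 3 * se
        assert emp.notna().all()

    def test_histo_status_consistent_with_distance_rules(self):
        c = make_cohort(50, seed=3)
        pos = c.margins["histo_status"] == "positive"
        assert (c.margins.loc[pos, "invasive_mm"] == 0.0).all()
        assert (c.margins.loc[~pos, "invasive_mm"] > 0.0).all()

    def test_detection_step_changes_rates_across_threshold(self):
        params = CohortParams(detection=DetectionModel(threshold=97.0, width=0.0))
        c = make_cohort(3000, params, seed=4)
        dec = c.patients.set_index("patient_id")["decayed_mbq"]
        act = c.margins["patient_id"].map(dec)
        neg = c.margins["histo_status"] == "negative"
        far = c.margins["far_status"] == "positive"
        fpr_hi = (far & neg & (act >= 97)).sum() / (neg & (act >= 97)).sum()
        fpr_lo = (far & neg & (act < 97)).sum() / (neg & (act < 97)).sum()
        assert fpr_hi > fpr_lo

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(0)
        with pytest.raises(ValueError):
            CohortParams(activity_bounds=(300.0, 200.0))

    def test_seeded_cohorts_reproducible(self):
        a = make_cohort(20, seed=5)
        b = make_cohort(20, seed=5)
        assert a.margins.equals(b.margins)
        assert a.patients.equals(b.patients)
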