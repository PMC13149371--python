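import numpy as np
import pytest

from deptrack.chip import field_proxy, make_chip_layout
from deptrack.fco import (
    MobilitySample,
    RingRegion,
    fit_zero_crossing,
    intensity_fco,
    intensity_trace,
    population_summary,
    probe_intensity,
    recm_from_velocity,
    ring_velocity,
    select_ring,
    trapped_site,
)
from deptrack.physics import EPS0
from deptrack.schedule import FrequencySchedule, Segment


class TestTrappedSite:
    def test_center_recovered_from_jittered_stationary_track(self, rng):
        true = np.array([120.0, 80.0])
        pts = true + rng.normal(0, 1.5, size=(400, 2))
        site = trapped_site(pts)
        assert site.valid
        # mean error scales as sigma / sqrt(n); allow 4x margin
        assert np.linalg.norm(site.center - true) < 4 * 1.5 / np.sqrt(400)

    def test_gross_outliers_excluded(self, rng):
        true = np.array([50.0, 50.0])
        inliers = true + rng.normal(0, 1.0, size=(180, 2))
        outliers = true + rng.uniform(30, 60, size=(20, 2))
        site_clean = trapped_site(inliers)
        site_dirty = trapped_site(np.vstack([inliers, outliers]))
        assert site_dirty.valid
        assert site_dirty.n_used <= 185  # the injected outliers were gated out
        assert np.linalg.norm(site_dirty.center - site_clean.center) < 0.5

    def test_too_few_states_rejected(self):
        with pytest.raises(ValueError):
            trapped_site(np.zeros((9, 2)))

    def test_perfectly_still_track_is_degenerate(self):
        site = trapped_site(np.tile([5.0, 5.0], (50, 1)))
        assert not site.valid

    def test_static_window_selects_frames(self, rng):
        pts = np.vstack([
            np.tile([0.0, 0.0], (100, 1)) + rng.normal(0, 1, (100, 2)),
            np.tile([90.0, 90.0], (100, 1)) + rng.normal(0, 1, (100, 2)),
        ])
        site = trapped_site(pts, static_window=(100, 200))
        assert np.linalg.norm(site.center - [90, 90]) < 1.0


class TestProbeIntensity:
    def test_uniform_frame(self):
        frame = np.full((50, 50), 100.0)
        assert probe_intensity(frame, (25, 25), 6) == pytest.approx(100.0)
        trace = intensity_trace([frame] * 4, type("S", (), {"center": (25, 25)})(), 6)
        np.testing.assert_allclose(trace, 100.0)

    def test_step_change_when_cell_leaves(self):
        bright = np.full((50, 50), 100.0)
        dark = np.full((50, 50), 60.0)
        trace = intensity_trace(
            [bright, bright, dark, dark], type("S", (), {"center": (25, 25)})(), 6
        )
        np.testing.assert_allclose(trace, [100, 100, 60, 60])

    def test_off_grid_pixels_excluded(self):
        frame = np.full((20, 20), 7.0)
        # probe centred on the corner still averages only in-grid pixels
        assert probe_intensity(frame, (0, 0), 5) == pytest.approx(7.0)
        assert np.isnan(probe_intensity(frame, (-100, -100), 5))


@pytest.fixture(scope="module")
def schedule():
    return FrequencySchedule(
        [Segment(0, 10, "static", 1e3, 1e3), Segment(10, 60, "sweep", 1e3, 41e3)],
        fps=10,
    )


class TestIntensityFco:
    def test_trigger_frequency_reported(self, schedule):
        sweep = schedule.segments[1]
        trace = np.zeros(600)
        trace[:100] = 100.0 + 2.0 * np.tile([-1, 1], 50)  # baseline sd = 2
        trace[100:] = 100.0
        t_21khz = 100 + 250  # 25 s into the sweep: f = 21 kHz
        trace[t_21khz:] = 110.0  # deviation 10 > 3 sigma = 6
        est = intensity_fco(trace, schedule, sweep,
                            baseline_frames=np.arange(50, 100))
        assert est.valid
        assert est.fco == pytest.approx(21_000.0)
        assert est.diagnostics["trigger_frame"] == t_21khz

    def test_quiet_trace_reports_no_crossover(self, schedule):
        trace = np.full(600, 100.0)
        trace[:100] = 100.0 + 2.0 * np.tile([-1, 1], 50)
        trace[100:] += 1.0  # always within 3 sigma
        est = intensity_fco(trace, schedule, schedule.segments[1],
                            baseline_frames=np.arange(50, 100))
        assert not est.valid

    def test_flat_baseline_invalid(self, schedule):
        trace = np.full(600, 100.0)
        est = intensity_fco(trace, schedule, schedule.segments[1],
                            baseline_frames=np.arange(50, 100))
        assert not est.valid
        assert "degenerate" in est.diagnostics["reason"]

    def test_single_frame_noise_spike_ignored(self, schedule):
        trace = np.zeros(600)
        trace[:100] = 100.0 + 2.0 * np.tile([-1, 1], 50)
        trace[100:] = 100.0
        trace[150] = 120.0  # isolated spike, persistence not met
        trace[400:] = 115.0  # genuine sustained escape
        est = intensity_fco(trace, schedule, schedule.segments[1],
                            baseline_frames=np.arange(50, 100))
        assert est.diagnostics["trigger_frame"] == 400


class TestRingVelocity:
    ring = RingRegion(r_in=10.0, r_out=40.0, grad_e2_ref=1.0)

    def test_uniform_outward_transit(self):
        # 30 px radially outward over 2 s -> +15 px/s
        d = np.concatenate([[5.0], np.linspace(10, 40, 21), [45.0]])
        for est in ("endpoints", "slope"):
            assert ring_velocity(d, self.ring, fps=10, estimator=est) == pytest.approx(15.0)

    def test_inward_transit_is_negative(self):
        d = np.concatenate([[45.0], np.linspace(40, 10, 21), [5.0]])
        assert ring_velocity(d, self.ring, fps=10) == pytest.approx(-15.0)

    def test_track_grazing_the_ring_not_crossing(self):
        d = np.full(50, 45.0)
        assert ring_velocity(d, self.ring, fps=10) is None
        shallow = np.concatenate([np.full(10, 45.0), [39.0, 38.0, 39.5], np.full(10, 45.0)])
        assert ring_velocity(shallow, self.ring, fps=10) is None

    def test_ring_validation(self):
        with pytest.raises(ValueError):
            RingRegion(r_in=10, r_out=10, grad_e2_ref=1.0)

    def test_select_ring_has_low_gradient_variation(self):
        lay = make_chip_layout(1, 1, 200, 20, (256, 256))
        field = field_proxy(lay, sigma_bump=20.0)
        ring = select_ring(field, cv_max=0.10)
        assert 0 < ring.r_in < ring.r_out <= lay.hole_radius - 4
        radii = np.linspace(ring.r_in, ring.r_out, 30)
        cx, cy = lay.hole_centers[0]
        g = field.grad_at(np.column_stack([cx + radii, np.full_like(radii, cy)]))
        # small slack over the nominal bound for the resampled grid
        assert g.std() / g.mean() <= 0.105


class TestRecmFromVelocity:
    def test_zero_velocity_gives_zero(self):
        assert recm_from_velocity(0.0, 9.5e-6, 1e-3, 78 * EPS0, 1e13) == 0.0

    def test_dimensional_reference_value(self):
        # 3 * 1e-3 * 1e-5 / ((9.5e-6)^2 * 78 eps0 * 1e13) ~ 0.0481
        val = recm_from_velocity(1e-5, 9.5e-6, 1e-3, 78 * EPS0, 1e13)
        assert val == pytest.approx(0.0481, rel=2e-3)

    def test_quadratic_radius_scaling(self):
        v1 = recm_from_velocity(1e-5, 9.5e-6, 1e-3, 78 * EPS0, 1e13)
        v2 = recm_from_velocity(1e-5, 19e-6, 1e-3, 78 * EPS0, 1e13)
        assert v1 / v2 == pytest.approx(4.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            recm_from_velocity(1.0, 9.5e-6, 1e-3, 78 * EPS0, 0.0)

    def test_force_balance_proportionality_constant(self):
        # mobility-vs-Re[CM] linearity: the fitted slope k over synthetic
        # evaluations matches 3 eta / (eps grad) to machine precision
        eta, eps, grad = 1e-3, 78 * EPS0, 1e13
        r = 9.5e-6
        v = np.linspace(-2e-5, 2e-5, 11)
        recm = np.array([recm_from_velocity(x, r, eta, eps, grad) for x in v])
        k_fit = np.polyfit(v / r**2, recm, 1)[0]
        assert k_fit == pytest.approx(3 * eta / (eps * grad), rel=1e-6)


def logistic_samples(l1, l2, k, f0, freqs, r_cell=1.0):
    vals = l1 + (l2 - l1) / (1 + np.exp(-k * (np.asarray(freqs) - f0)))
    return [MobilitySample(f, v * r_cell**2, r_cell) for f, v in zip(freqs, vals)]


class TestFitZeroCrossing:
    def test_symmetric_logistic_centered_root(self):
        freqs = np.linspace(5e3, 55e3, 12)
        samples = logistic_samples(-1.0, 1.0, 2e-4, 30e3, freqs)
        est = fit_zero_crossing(samples, x_scale="linear")
        assert est.valid
        assert est.fco == pytest.approx(30e3, rel=1e-6)

    def test_asymmetric_logistic_closed_form_root(self):
        # root = f0 - ln((l2 - l1)/(-l1) - 1)/k = 20 kHz - ln(2)/0.2e-3
        freqs = np.linspace(2e3, 60e3, 15)
        samples = logistic_samples(-0.5, 1.0, 2e-4, 20e3, freqs)
        est = fit_zero_crossing(samples, x_scale="linear")
        assert est.valid
        assert est.fco == pytest.approx(20e3 - np.log(2) / 2e-4, rel=1e-4)

    def test_log_axis_family_recovered(self):
        fco = 24e3
        freqs = np.array([1, 1.5, 2, 3.5, 20, 30, 40, 50, 60, 70]) * 1e3
        vals = np.tanh(np.log(freqs / fco) / 0.8)
        samples = [MobilitySample(f, v, 1.0) for f, v in zip(freqs, vals)]
        est = fit_zero_crossing(samples)
        assert est.valid
        assert est.fco == pytest.approx(fco, rel=1e-3)

    def test_single_sign_data_invalid(self):
        freqs = np.linspace(30e3, 60e3, 6)
        samples = [MobilitySample(f, 0.5, 1.0) for f in freqs]
        est = fit_zero_crossing(samples)
        assert not est.valid
        assert "no crossover" in est.diagnostics["reason"]

    def test_too_few_samples_invalid(self):
        samples = [MobilitySample(1e3, -1, 1), MobilitySample(50e3, 1, 1)]
        assert not fit_zero_crossing(samples).valid


class TestPopulationSummary:
    def test_single_estimate(self):
        from deptrack.fco import FcoEstimate

        summary = population_summary([FcoEstimate(0, 20e3, "velocity")])
        assert summary["velocity"]["mean"] == 20e3
        assert summary["velocity"]["sd"] == 0.0

    def test_three_estimates(self):
        from deptrack.fco import FcoEstimate

        ests = [FcoEstimate(i, f, "velocity") for i, f in enumerate([10e3, 20e3, 30e3])]
        summary = population_summary(ests)
        assert summary["velocity"]["mean"] == 20e3
        assert summary["velocity"]["median"] == 20e3

    def test_invalid_counted_not_pooled(self):
        from deptrack.fco import FcoEstimate

        ests = [
            FcoEstimate(0, 20e3, "intensity"),
            FcoEstimate(1, float("nan"), "intensity", valid=False),
        ]
        summary = population_summary(ests)
        assert summary["intensity"]["n_valid"] == 1
        assert summary["intensity"]["n_invalid"] == 1
        assert summary["n_total"] == 2
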