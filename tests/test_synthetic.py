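"""Synthetic-data generators: mixtures, walks, dwells, rendered stacks."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from curtainkit.presets import (
    GENOME_KB,
    ExperimentPreset,
    SiteComponent,
    get_preset,
    site_weight_for_fold,
)
from curtainkit.simulate import (
    Trajectory,
    make_behavior_fixtures,
    render_frames,
    simulate_binding_positions,
    simulate_dwell_times,
    simulate_trajectory,
)


def _site_preset(center, sd, weight, jitter=0.0, name="toy"):
    return ExperimentPreset(
        name=name,
        kind="binding",
        sites=(SiteComponent(center, sd, weight, jitter),),
        background_weight=1.0 - weight,
    )


class TestBindingPositions:
    def test_pure_background_is_uniform(self):
        p = get_preset("yPCNA_homoduplex")
        pos = simulate_binding_positions(p, 10_000, seed=1)
        assert pos.min() >= 0 and pos.max() <= GENOME_KB
        _, pval = stats.kstest(pos / GENOME_KB, "uniform")
        assert pval > 0.01

    def test_degenerate_site_component_is_constant(self):
        p = _site_preset(21.3, 0.0, 1.0)
        pos = simulate_binding_positions(p, 50, seed=2)
        assert np.all(pos == 21.3)

    def test_all_zero_weights_rejected(self):
        p = ExperimentPreset(name="zero", kind="diffusion")
        with pytest.raises(ValueError, match="zero"):
            simulate_binding_positions(p, 10, seed=0)

    def test_determinism_bit_identical(self):
        p = get_preset("yPCNA_flap")
        a = simulate_binding_positions(p, 1000, seed=42)
        b = simulate_binding_positions(p, 1000, seed=42)
        assert np.array_equal(a, b)

    def test_site_fraction_matches_weight(self):
        # empirical window count at n = 1e5 within 3 binomial SDs
        w = 0.3
        p = _site_preset(10.0, 0.5, w)
        n = 100_000
        pos = simulate_binding_positions(p, n, seed=3)
        window = (8.0, 12.0)
        p_expected = w * (stats.norm.cdf(4.0) - stats.norm.cdf(-4.0)) + (1 - w) * (
            (window[1] - window[0]) / GENOME_KB
        )
        count = np.sum((pos >= window[0]) & (pos < window[1]))
        sd = np.sqrt(n * p_expected * (1 - p_expected))
        assert abs(count - n * p_expected) < 3 * sd

    def test_anchor_jitter_broadens_component(self):
        narrow = simulate_binding_positions(_site_preset(21.3, 0.3, 1.0), 20_000, 5)
        jittered = simulate_binding_positions(
            _site_preset(21.3, 0.3, 1.0, jitter=4.0), 20_000, 5
        )
        expected_var = 0.3**2 + 4.0**2 / 12.0
        assert np.var(jittered) == pytest.approx(expected_var, rel=0.05)
        assert np.var(jittered) > np.var(narrow)

    def test_flap_preset_peaks_near_site_a(self):
        p = get_preset("yPCNA_flap")
        pos = simulate_binding_positions(p, 10_000, seed=1)
        hist, edges = np.histogram(pos, bins=np.arange(0, 49, 1.0))
        peak_kb = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert abs(peak_kb - 21.2) < 1.5


class TestTrajectories:
    def test_zero_diffusion_is_constant(self, diffusion_preset):
        t = simulate_trajectory(
            diffusion_preset, 0.0, 100, 5.0, seed=1, localization_noise=False
        )
        assert np.all(t.y_um == 5.0)

    def test_negative_diffusion_rejected(self, diffusion_preset):
        with pytest.raises(ValueError):
            simulate_trajectory(diffusion_preset, -0.1, 100, 5.0, seed=1)

    def test_reflecting_tether_ends_bound_every_sample(self, diffusion_preset):
        t = simulate_trajectory(diffusion_preset, 5.0, 5000, 1.0, seed=9)
        L = diffusion_preset.geometry.tether_um
        assert t.y_um.min() >= 0.0 and t.y_um.max() <= L

    def test_mean_step_variance_matches_2ddt(self, diffusion_preset):
        d, dt = 0.2, diffusion_preset.optics.frame_interval_s
        t = simulate_trajectory(
            diffusion_preset, d, 50_000, 6.5, seed=4, localization_noise=False
        )
        steps = np.diff(t.y_um)
        assert np.var(steps) == pytest.approx(2 * d * dt, rel=0.05)

    def test_reflecting_site_never_crossed(self):
        p = dataclasses.replace(
            get_preset("yPCNA_homoduplex_diffusion"),
            site_interaction="reflecting",
            interaction_site_kb=21.3,
        )
        site_um = 21.3 * p.geometry.um_per_kb
        t = simulate_trajectory(p, 1.0, 3000, site_um - 2.0, seed=6,
                                localization_noise=False)
        assert np.all(t.y_um <= site_um)

    def test_trapping_site_pins_particle(self):
        p = dataclasses.replace(
            get_preset("yPCNA_homoduplex_diffusion"),
            site_interaction="trapping",
            interaction_site_kb=21.3,
        )
        site_um = 21.3 * p.geometry.um_per_kb
        t = simulate_trajectory(p, 1.0, 3000, site_um - 1.0, seed=7,
                                localization_noise=False)
        crossed = np.flatnonzero(t.y_um == site_um)
        assert crossed.size > 0
        assert np.all(t.y_um[crossed[0]:] == site_um)

    def test_start_outside_tether_rejected(self, diffusion_preset):
        with pytest.raises(ValueError):
            simulate_trajectory(diffusion_preset, 0.1, 10, 99.0, seed=1)


class TestDwellTimes:
    def test_all_censored_when_half_life_huge(self):
        s = simulate_dwell_times(1e9, 50, 10.0, seed=1)
        assert np.all(s.censored)
        assert np.all(s.times_s == 10.0)

    def test_uncensored_mean_matches_closed_form(self):
        t_half = 10.0
        s = simulate_dwell_times(t_half, 100_000, np.inf, seed=1)
        assert s.n_events == 100_000
        assert s.times_s.mean() == pytest.approx(t_half / np.log(2), rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_dwell_times(0.0, 10, 10.0, seed=1)
        with pytest.raises(ValueError):
            simulate_dwell_times(1.0, 0, 10.0, seed=1)


class TestRenderFrames:
    def test_particle_free_region_mean_equals_background(self, diffusion_preset):
        opt = diffusion_preset.optics
        t = Trajectory(0, 0.05, np.full(50, 48 * opt.pixel_um))
        stack = render_frames([t], diffusion_preset, seed=1, shape=(16, 64),
                              rows_px=[8.0])
        bg = opt.background
        region = stack[:, :, :10].astype(float)  # >30 sigma from the emitter
        sem = np.sqrt(bg / region.size)
        assert abs(region.mean() - bg) < 5 * sem

    def test_noiseless_centroid_matches_subpixel_position(self, diffusion_preset):
        opt = diffusion_preset.optics
        t = Trajectory(0, 0.05, np.array([10.30 * opt.pixel_um]))
        stack = render_frames([t], diffusion_preset, seed=0, shape=(16, 32),
                              rows_px=[7.60], noise=False)
        f = stack[0].astype(float)
        yy, xx = np.mgrid[0:16, 0:32]
        assert (f * xx).sum() / f.sum() == pytest.approx(10.30, abs=0.01)
        assert (f * yy).sum() / f.sum() == pytest.approx(7.60, abs=0.01)

    def test_photon_conservation_in_roi(self, diffusion_preset):
        opt = diffusion_preset.optics
        t = Trajectory(0, 0.05, np.array([16 * opt.pixel_um] * 20))
        noiseless = render_frames([t], diffusion_preset, seed=0, shape=(16, 32),
                                  rows_px=[8.0], noise=False)
        assert noiseless[0].sum() == pytest.approx(opt.photons_per_frame, rel=0.01)
        noisy = render_frames([t], diffusion_preset, seed=2, shape=(16, 32),
                              rows_px=[8.0], noise=True)
        signal = noisy.sum(axis=(1, 2)).mean() - opt.background * 16 * 32
        expected = opt.photons_per_frame
        assert abs(signal - expected) < 3 * np.sqrt(
            (expected + opt.background * 16 * 32) / 20
        )

    def test_zero_photon_rate_rejected(self, diffusion_preset):
        p = dataclasses.replace(
            diffusion_preset,
            optics=dataclasses.replace(diffusion_preset.optics, photons_per_frame=0.0),
        )
        t = Trajectory(0, 0.05, np.array([6.5]))
        with pytest.raises(ValueError):
            render_frames([t], p, seed=1)

    def test_determinism(self, diffusion_preset):
        t = Trajectory(0, 0.05, np.full(5, 6.5))
        a = render_frames([t], diffusion_preset, seed=3, shape=(16, 32))
        b = render_frames([t], diffusion_preset, seed=3, shape=(16, 32))
        assert np.array_equal(a, b)


class TestBehaviorFixtures:
    def test_exact_category_counts(self):
        p = get_preset("yPCNA_flap_dynamics")
        fixtures = make_behavior_fixtures(p)
        labels = [lab for _, lab in fixtures]
        assert labels.count("blocked") == 36
        assert labels.count("captured") == 2
        assert labels.count("bypass") == 2
        assert len(fixtures) == 40

    def test_fixtures_are_deterministic(self):
        p = get_preset("yPCNA_cag13_dynamics")
        a = make_behavior_fixtures(p)
        b = make_behavior_fixtures(p)
        for (ta, _), (tb, _) in zip(a, b):
            assert np.array_equal(ta.y_um, tb.y_um)


def test_site_weight_for_fold_reproduces_expected_frequency():
    # closed-form check: with weight w the window frequency is fold * p_bg
    window = (18.8, 23.8)
    w = site_weight_for_fold(2.7, 21.2, 1.4, window)
    p_bg = 5.0 / GENOME_KB
    p_site = stats.norm.cdf((window[1] - 21.2) / 1.4) - stats.norm.cdf(
        (window[0] - 21.2) / 1.4
    )
    freq = w * p_site + (1 - w) * p_bg
    assert freq == pytest.approx(2.7 * p_bg, rel=1e-12)
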