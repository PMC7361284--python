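"""Tests of the seeded synthetic-data generators and their ground truth."""

import dataclasses
import math

import numpy as np
import pytest

from cristaquant import (
    FilterParams,
    MorphometryPreset,
    SceneModel,
    SceneParams,
    cj_frequency,
    failing_reasons,
    render_image,
    simulate_minflux_events,
    simulate_morphometry,
    simulate_scene,
)


class TestSimulateScene:
    def test_zero_clusters_gives_empty_ground_truth(self):
        truth = simulate_scene(SceneParams(n_clusters=0))
        assert truth.emitter_positions.shape == (0, 2)
        assert truth.cluster_membership.size == 0

    def test_seeded_determinism(self):
        p = SceneParams(model=SceneModel.STRIPE_PATTERN, seed=9)
        a, b = simulate_scene(p), simulate_scene(p)
        assert np.array_equal(a.emitter_positions, b.emitter_positions)
        assert np.array_equal(a.cluster_membership, b.cluster_membership)

    def test_every_emitter_has_one_cluster_and_lies_in_bounds(self):
        for model in SceneModel:
            p = SceneParams(model=model, n_clusters=10, seed=4)
            truth = simulate_scene(p)
            assert truth.cluster_membership.shape[0] == truth.emitter_positions.shape[0]
            assert set(np.unique(truth.cluster_membership)) <= set(range(10))
            ny, nx = p.image_shape
            x, y = truth.emitter_positions.T
            assert (x >= 0).all() and (x <= nx * p.pixel_size_nm).all()
            assert (y >= 0).all() and (y <= ny * p.pixel_size_nm).all()

    def test_emitters_stay_inside_tubule_footprint(self):
        p = SceneParams(model=SceneModel.OPPOSITE_BANDS, n_clusters=20, seed=1)
        truth = simulate_scene(p)
        x, y = truth.emitter_positions.T
        m, r = p.margin_nm, p.tubule_radius_nm
        assert (x >= m).all() and (x <= m + p.tubule_length_nm).all()
        assert (np.abs(y - (m + r)) <= r + 1e-9).all()

    def test_opposite_bands_centers_confined_to_strips(self):
        """With 50 nm half-width on a 150 nm radius tubule, every projected
        cluster-centre transverse offset lies in one of the two edge strips
        [100, 150] nm — checked centre by centre."""
        p = SceneParams(
            model=SceneModel.OPPOSITE_BANDS, band_halfwidth_nm=50.0,
            tubule_radius_nm=150.0, n_clusters=200, seed=12,
        )
        truth = simulate_scene(p)
        offsets = np.abs(truth.cluster_centers[:, 1] - (p.margin_nm + 150.0))
        assert ((offsets >= 100.0 - 1e-9) & (offsets <= 150.0 + 1e-9)).all()

    def test_stripe_centers_sit_on_period_rings(self):
        p = SceneParams(model=SceneModel.STRIPE_PATTERN, stripe_period_nm=250.0,
                        n_clusters=40, seed=3)
        truth = simulate_scene(p)
        axial = truth.cluster_centers[:, 0] - p.margin_nm
        assert np.allclose((axial - 125.0) % 250.0, 0.0, atol=1e-9)

    def test_model_specific_validation(self):
        bad_arc = SceneParams(model=SceneModel.EXTENDED_ASSEMBLIES, assembly_arc_deg=0.0)
        with pytest.raises(ValueError, match="assembly_arc_deg"):
            simulate_scene(bad_arc)
        bad_period = SceneParams(model=SceneModel.STRIPE_PATTERN, stripe_period_nm=-1.0)
        with pytest.raises(ValueError, match="stripe_period_nm"):
            simulate_scene(bad_period)

    def test_param_invariants(self):
        with pytest.raises(ValueError):
            SceneParams(pixel_size_nm=2.0)
        with pytest.raises(ValueError):
            SceneParams(psf_fwhm_nm=10.0, pixel_size_nm=20.0)
        with pytest.raises(ValueError):
            SceneParams(n_clusters=-1)


class TestRenderImage:
    def test_zero_emitters_zero_background_is_all_zero(self):
        p = SceneParams(n_clusters=0, background_rate=0.0)
        img = render_image(simulate_scene(p), noise=False)
        assert np.all(img.pixels == 0.0)
        assert img.pixel_size_nm == p.pixel_size_nm

    def test_single_emitter_photon_conservation(self):
        """Noise-free, background-free image of one emitter integrates to
        the emitter photon budget within the 1% PSF-truncation bound."""
        p = SceneParams(n_clusters=1, emitters_per_cluster=1,
                        photons_per_emitter=800.0, background_rate=0.0,
                        psf_fwhm_nm=80.0, seed=6)
        img = render_image(simulate_scene(p), noise=False)
        assert img.pixels.sum() == pytest.approx(800.0, rel=0.01)

    def test_peak_value_is_analytic_gaussian_amplitude_plus_background(self):
        p = SceneParams(n_clusters=1, emitters_per_cluster=1, background_rate=3.0,
                        photons_per_emitter=1000.0, psf_fwhm_nm=80.0, seed=2)
        truth = simulate_scene(p)
        # move the emitter onto an exact pixel centre
        px = p.pixel_size_nm
        pos = np.array([[40.5 * px, 12.5 * px]])
        truth = dataclasses.replace(truth, emitter_positions=pos)
        img = render_image(truth, noise=False)
        sigma_px = 80.0 / (2 * math.sqrt(2 * math.log(2))) / px
        expected = 1000.0 / (2 * math.pi * sigma_px**2) + 3.0
        assert img.pixels[12, 40] == pytest.approx(expected, rel=1e-6)

    def test_noise_free_total_intensity_accounting(self):
        p = SceneParams(n_clusters=5, background_rate=1.5, seed=8)
        truth = simulate_scene(p)
        img = render_image(truth, noise=False)
        n_emitters = len(truth.emitter_positions)
        expected = n_emitters * p.photons_per_emitter + 1.5 * img.pixels.size
        assert img.pixels.sum() == pytest.approx(expected, rel=0.01)

    def test_noisy_rendering_is_seed_deterministic(self):
        p = SceneParams(n_clusters=3, seed=5)
        a = render_image(simulate_scene(p))
        b = render_image(simulate_scene(p))
        assert np.array_equal(a.pixels, b.pixels)


class TestSimulateMinflux:
    def test_empty(self):
        sim = simulate_minflux_events(0, 0, seed=1)
        assert sim.events == [] and sim.is_valid.size == 0

    def test_label_fidelity_against_thresholds(self):
        """Ground-truth labels agree with re-application of the five
        criteria for every event."""
        sim = simulate_minflux_events(50, 50, seed=21)
        params = FilterParams()
        recomputed = np.array(
            [failing_reasons(e, params) == () for e in sim.events]
        )
        assert np.array_equal(recomputed, sim.is_valid)
        assert recomputed.sum() == 50

    def test_artifacts_cover_all_five_criteria(self):
        sim = simulate_minflux_events(0, 10, seed=3)
        assert set(sim.failure_modes) == {"P0", "R_RELATIVE", "RATE", "PHOTONS", "SBR"}

    def test_seeded_determinism(self):
        a = simulate_minflux_events(20, 20, seed=13)
        b = simulate_minflux_events(20, 20, seed=13)
        assert a.events == b.events
        assert a.failure_modes == b.failure_modes

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_minflux_events(-1, 0, seed=0)


WT_LIKE = MorphometryPreset("wt-like", cj_per_um=1.0, diameter_mean_nm=20.0,
                            diameter_sd_nm=4.0)


class TestSimulateMorphometry:
    def test_zero_rate_gives_zero_junctions(self):
        preset = MorphometryPreset("null", cj_per_um=0.0, diameter_mean_nm=20.0,
                                   diameter_sd_nm=4.0)
        sections = simulate_morphometry(preset, 50, seed=1)
        assert all(s.n_cj == 0 and s.cj_diameters_nm == () for s in sections)

    def test_seeded_determinism(self):
        a = simulate_morphometry(WT_LIKE, 30, seed=17)
        b = simulate_morphometry(WT_LIKE, 30, seed=17)
        assert a == b

    def test_diameter_mean_recovery_at_n96(self):
        """Pooling 96 simulated diameters from a mean-28 / SD-6 preset
        recovers the mean within 2 SEM = 2 * 6 / sqrt(96)."""
        preset = MorphometryPreset("mic10-like", cj_per_um=1.0,
                                   diameter_mean_nm=28.0, diameter_sd_nm=6.0)
        sections = simulate_morphometry(preset, 100, seed=96)
        pooled = [d for s in sections for d in s.cj_diameters_nm][:96]
        assert len(pooled) == 96
        assert abs(np.mean(pooled) - 28.0) < 2 * 6.0 / math.sqrt(96)

    def test_pooled_rate_converges_to_preset(self):
        """Law of large numbers: pooled CJ count over pooled OM length
        approaches the preset intensity."""
        sections = simulate_morphometry(WT_LIKE, 10_000, seed=5)
        rate = cj_frequency(sections)[WT_LIKE.condition_label].pooled_rate
        total_len = sum(s.om_length_um for s in sections)
        se = math.sqrt(WT_LIKE.cj_per_um / total_len)
        assert abs(rate - 1.0) < 3 * se

    def test_diameters_all_positive(self):
        preset = MorphometryPreset("noisy", cj_per_um=2.0, diameter_mean_nm=5.0,
                                   diameter_sd_nm=10.0)
        sections = simulate_morphometry(preset, 200, seed=3)
        assert all(d > 0 for s in sections for d in s.cj_diameters_nm)

    def test_hurdle_mode_hits_prevalence_and_septum_share(self):
        preset = MorphometryPreset("opa1-like", cj_per_um=0.5,
                                   diameter_mean_nm=28.0, diameter_sd_nm=6.0,
                                   p_section_has_junction=0.36,
                                   p_septum_given_junction=0.50)
        sections = simulate_morphometry(preset, 5000, seed=8)
        bearing = [s for s in sections if s.n_junctions_total >= 1]
        prevalence = len(bearing) / len(sections)
        septum_share = sum(1 for s in bearing if s.has_septum) / len(bearing)
        assert prevalence == pytest.approx(0.36, abs=0.03)
        assert septum_share == pytest.approx(0.50, abs=0.04)

    def test_om_lengths_lognormal_median(self):
        sections = simulate_morphometry(WT_LIKE, 4000, seed=2)
        med = np.median([s.om_length_um for s in sections])
        assert med == pytest.approx(3.0, rel=0.05)
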