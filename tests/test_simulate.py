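"""Generator contracts: determinism, closed-form moments, boundary behavior."""

import numpy as np
import pytest
from scipy import stats

from tightrope.simulate import (
    SubstrateGeometry,
    TrajectorySimConfig,
    render_kymograph,
    simulate_afm_positions,
    simulate_free_diffusion,
    simulate_titration,
    simulate_two_state,
)


def cfg(**kw):
    base = dict(D_free=0.1, frame_interval_s=0.05, n_frames=200,
                localization_sigma_um=0.0, tightrope_length_um=10.0,
                start_position_um=5.0, seed=0)
    base.update(kw)
    return TrajectorySimConfig(**base)


class TestFreeDiffusion:
    def test_zero_diffusion_zero_noise_is_constant(self):
        traj = simulate_free_diffusion(cfg(D_free=0.0))
        assert np.allclose(traj.positions_um, 5.0)

    def test_lag1_msd_matches_2D_dt(self):
        c = cfg(n_frames=10001, tightrope_length_um=200.0, start_position_um=100.0,
                seed=3)
        traj = simulate_free_diffusion(c)
        d = np.diff(traj.positions_um)
        expected = 2 * c.D_free * c.frame_interval_s
        se = np.std(d ** 2, ddof=1) / np.sqrt(d.size)
        assert abs(np.mean(d ** 2) - expected) < 3 * se

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_positions_stay_on_tightrope(self, seed):
        c = cfg(D_free=0.5, tightrope_length_um=0.8, start_position_um=0.4,
                localization_sigma_um=0.016, seed=seed)
        traj = simulate_free_diffusion(c)
        assert traj.positions_um.min() >= 0.0
        assert traj.positions_um.max() <= 0.8
        assert traj.true_positions_um.min() >= 0.0
        assert traj.true_positions_um.max() <= 0.8

    def test_seed_determinism(self):
        a = simulate_free_diffusion(cfg(seed=7, localization_sigma_um=0.016))
        b = simulate_free_diffusion(cfg(seed=7, localization_sigma_um=0.016))
        assert np.array_equal(a.positions_um, b.positions_um)

    def test_invalid_parameters_name_the_field(self):
        with pytest.raises(ValueError, match="frame_interval_s"):
            cfg(frame_interval_s=0.0)
        with pytest.raises(ValueError, match="D_free"):
            cfg(D_free=-0.1)

    def test_detachment_marks_absent_frames(self):
        c = cfg(detach_rate_per_s=2.0, n_frames=400, seed=5)
        traj = simulate_free_diffusion(c)
        present = traj.present
        assert present[0]
        assert not present[-1]
        # presence is a prefix: once detached, gone for good
        first_off = int(np.argmin(present))
        assert not present[first_off:].any()


class TestTwoState:
    def test_start_paused_no_release_is_constant_at_site(self):
        c = cfg(pause_sites_um=(3.0,), k_pause_per_s=5.0, k_release_per_s=0.0,
                start_paused=True, start_position_um=3.1)
        traj, states = simulate_two_state(c)
        assert np.all(states == 1)
        assert np.allclose(traj.true_positions_um, 3.0)

    def test_no_capture_rate_never_pauses(self):
        c = cfg(pause_sites_um=(5.0,), k_pause_per_s=0.0, k_release_per_s=1.0)
        _, states = simulate_two_state(c)
        assert np.all(states == 0)

    def test_mean_dwell_matches_geometric_closed_form(self):
        # large capture radius + high capture rate => many complete pauses
        c = cfg(pause_sites_um=(5.0,), k_pause_per_s=50.0, k_release_per_s=1.0,
                capture_radius_um=0.15, n_frames=60000, seed=11)
        _, states = simulate_two_state(c)
        s = states.astype(int)
        starts = np.where(np.diff(s) == 1)[0]
        ends = np.where(np.diff(s) == -1)[0]
        ends = ends[ends > starts[0]]
        n = min(len(starts), len(ends))
        dwells = (ends[:n] - starts[:n]) * c.frame_interval_s
        assert len(dwells) >= 500
        # discrete-frame dwell is geometric: mean = dt / (1 - exp(-k dt))
        expected = c.frame_interval_s / (1 - np.exp(-1.0 * c.frame_interval_s))
        se = dwells.std(ddof=1) / np.sqrt(len(dwells))
        assert abs(dwells.mean() - expected) < 3 * se

    def test_paused_position_is_site_coordinate(self):
        c = cfg(pause_sites_um=(2.0, 8.0), k_pause_per_s=5.0, k_release_per_s=0.2,
                capture_radius_um=0.1, n_frames=5000, seed=2)
        traj, states = simulate_two_state(c)
        paused_pos = traj.true_positions_um[states == 1]
        assert paused_pos.size > 0
        dist = np.min(np.abs(paused_pos[:, None] - np.array([2.0, 8.0])), axis=1)
        assert np.all(dist < 1e-12)

    def test_capture_radius_must_be_positive_with_capture(self):
        with pytest.raises(ValueError, match="capture_radius"):
            cfg(pause_sites_um=(5.0,), k_pause_per_s=1.0, capture_radius_um=0.0)


class TestKymographRendering:
    def test_zero_photons_is_pure_background(self):
        traj = simulate_free_diffusion(cfg(D_free=0.0, n_frames=300))
        k = render_kymograph(traj, photons_per_frame=0.0, background=4.0, seed=1)
        col_means = k.intensity.mean(axis=0)
        assert abs(k.intensity.mean() - 4.0) < 0.2
        # no spatial structure tied to the particle position
        row_means = k.intensity.mean(axis=1)
        assert row_means.std() < 1.0

    def test_peak_pixel_contains_true_position_at_high_snr(self):
        traj = simulate_free_diffusion(cfg(D_free=0.0, start_position_um=6.32,
                                           n_frames=50))
        k = render_kymograph(traj, photons_per_frame=50000, background=0.5,
                             pixel_size_um=0.05, seed=2)
        peaks = np.argmax(k.intensity, axis=0)
        lo = peaks * k.pixel_size_um
        assert np.all((lo <= 6.32 + 0.05) & (lo + 0.05 >= 6.32 - 0.05))

    def test_fixed_seed_bitwise_identical(self):
        traj = simulate_free_diffusion(cfg(seed=4))
        a = render_kymograph(traj, seed=9)
        b = render_kymograph(traj, seed=9)
        assert np.array_equal(a.intensity, b.intensity)

    def test_grid_shorter_than_tightrope_rejected(self):
        traj = simulate_free_diffusion(cfg())
        with pytest.raises(ValueError, match="shorter"):
            render_kymograph(traj, pixel_size_um=0.05, n_pixels=10)


class TestAFMPositions:
    def test_no_specificity_is_uniform(self):
        geom = SubstrateGeometry(length_bp=2000, specific_sites=(("gap", 460),))
        rec = simulate_afm_positions(geom, S=1.0, n_complexes=10000, seed=0)
        # fold-aware: uniform on the substrate => uniform over folded bins
        counts, _ = np.histogram(rec["position_pct"], bins=np.linspace(0, 50, 21))
        chi2, p = stats.chisquare(counts)
        assert p > 0.01

    def test_high_specificity_mode_at_gap(self):
        geom = SubstrateGeometry(length_bp=2030, specific_sites=(("gap", 470),))
        rec = simulate_afm_positions(geom, S=1994.0, n_complexes=251, seed=5)
        counts, edges = np.histogram(rec["position_pct"], bins=np.linspace(0, 50, 21))
        modal = int(np.argmax(counts))
        assert edges[modal] <= 100 * 470 / 2030 <= edges[modal + 1]

    def test_specificity_below_one_rejected(self):
        geom = SubstrateGeometry(length_bp=100)
        with pytest.raises(ValueError, match="S"):
            simulate_afm_positions(geom, S=0.5, n_complexes=10)

    def test_positions_are_folded(self):
        geom = SubstrateGeometry(length_bp=500)
        rec = simulate_afm_positions(geom, S=1.0, n_complexes=5000, seed=0)
        assert rec["position_pct"].between(0, 50).all()


class TestTitration:
    def test_zero_concentration_gives_p_free(self):
        t = simulate_titration(88.0, 120.0, 320.0, [0.0, 10.0, 100.0, 200.0,
                                                    500.0, 1000.0], 0.0, seed=0)
        assert t["polarization_mP"].iloc[0] == pytest.approx(120.0)

    def test_half_saturation_at_kd(self):
        t = simulate_titration(88.0, 100.0, 300.0, [88.0], 0.0, seed=0)
        assert t["polarization_mP"].iloc[0] == pytest.approx(200.0)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError, match="P_bound"):
            simulate_titration(88.0, 100.0, 100.0, [0, 10], 0.0)


class TestSubstrateGeometry:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SubstrateGeometry(length_bp=0)
        with pytest.raises(ValueError):
            SubstrateGeometry(length_bp=100, specific_sites=(("gap", 200),))
        with pytest.raises(ValueError):
            SubstrateGeometry(length_bp=100, specific_sites=(("blob", 50),))

    def test_tightrope_length_from_contour(self):
        geom = SubstrateGeometry(length_bp=2030, rise_nm_per_bp=0.32,
                                 elongation_fraction=0.9)
        assert geom.contour_length_nm == pytest.approx(649.6)
        assert geom.tightrope_length_um == pytest.approx(0.58464)
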