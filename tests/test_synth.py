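import numpy as np
import pandas as pd
import pytest

from placefields.config import TrackConfig
from placefields.synth import (
    CellTuningSpec,
    SessionPairSpec,
    derive_session2_specs,
    random_tuning_specs,
    simulate_fluorescence,
    simulate_footprints,
    simulate_olm_traces,
    simulate_place_cell_events,
    simulate_session_pair,
    simulate_trajectory,
)


class TestTrajectory:
    def test_two_laps_span_track_with_monotone_segments(self, cfg):
        traj = simulate_trajectory(cfg, n_laps=2, mean_speed=20.0, pause_s=0.0, seed=0)
        assert traj.x.min() == 0.0 and traj.x.max() == cfg.track_length_cm
        assert traj.lap.max() == 1
        for lap in (0, 1):
            seg = traj.x[traj.lap == lap]
            d = np.diff(seg)
            assert np.all(d >= 0) or np.all(d <= 0)

    def test_pause_gives_near_zero_velocity_in_reward_zone(self, cfg):
        traj = simulate_trajectory(cfg, n_laps=3, mean_speed=20.0, pause_s=5.0, seed=2)
        at_end = (traj.x >= cfg.track_length_cm - 1e-9) | (traj.x <= 1e-9)
        # 3 turn pauses of >= 5 s each, velocity ~ 0 at the dwell centre
        assert at_end.sum() >= 3 * 50
        still = np.flatnonzero(at_end)
        centre_of_dwell = still[25]
        assert traj.v[centre_of_dwell] < 1.0

    def test_seed_determinism(self, cfg):
        a = simulate_trajectory(cfg, 5, 18.0, 1.0, seed=7)
        b = simulate_trajectory(cfg, 5, 18.0, 1.0, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.t, b.t)
        c = simulate_trajectory(cfg, 5, 18.0, 1.0, seed=8)
        assert not np.array_equal(a.x, c.x)

    @pytest.mark.parametrize("kwargs", [dict(n_laps=0), dict(mean_speed=-1.0), dict(pause_s=-1.0)])
    def test_invalid_parameters(self, cfg, kwargs):
        base = dict(n_laps=2, mean_speed=20.0, pause_s=0.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            simulate_trajectory(cfg, seed=0, **base)


class TestEvents:
    def test_zero_rate_cell_is_silent(self, cfg, traj20):
        spec = CellTuningSpec(field_centre_cm=70, peak_rate_hz=0.0, baseline_rate_hz=0.0)
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=0)
        assert len(ev) == 0

    def test_empty_spec_list_rejected(self, cfg, traj20):
        with pytest.raises(ValueError):
            simulate_place_cell_events(traj20, [], cfg, seed=0)

    def test_seed_determinism(self, cfg, traj20):
        spec = CellTuningSpec(field_centre_cm=70)
        a, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=3)
        b, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_opto_gain_halves_in_zone_rate_against_poisson_oracle(self, cfg):
        """For a uniform-rate cell, in-zone events ≈ gain × rate × occupancy."""
        traj = simulate_trajectory(cfg, n_laps=60, seed=9)
        rate = 4.0
        spec = CellTuningSpec(
            field_centre_cm=70, peak_rate_hz=rate, baseline_rate_hz=rate, direction="both"
        )
        ev, _ = simulate_place_cell_events(traj, [spec], cfg, seed=10, opto_gain=0.5)
        lo, hi = cfg.zone_interval("opto", "right")
        x_at_ev = traj.x[traj.sample_of(ev["t_s"].to_numpy())]
        n_in = np.sum((x_at_ev >= lo) & (x_at_ev < hi))
        occ_in = np.sum((traj.x >= lo) & (traj.x < hi)) * traj.dt
        expect = 0.5 * rate * occ_in  # Poisson expectation oracle
        assert abs(n_in - expect) <= 3 * np.sqrt(expect)

    def test_event_totals_match_integrated_rate(self, cfg, traj20):
        """Generated counts match the analytic Poisson expectation within 3 SD."""
        spec = CellTuningSpec(
            field_centre_cm=70, field_sd_cm=10, peak_rate_hz=12.0,
            baseline_rate_hz=5.0, direction="both",
        )
        lam = spec.baseline_rate_hz + (spec.peak_rate_hz - spec.baseline_rate_hz) * np.exp(
            -((traj20.x - 70.0) ** 2) / (2 * 10.0**2)
        )
        expect = lam.sum() * traj20.dt
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=11)
        assert expect > 1000  # enough events for the 3-sigma band to be tight
        assert abs(len(ev) - expect) <= 3 * np.sqrt(expect)

    def test_direction_selective_cell_fires_at_baseline_opposite(self, cfg, traj20):
        spec = CellTuningSpec(field_centre_cm=70, peak_rate_hz=5.0, direction="right",
                              baseline_rate_hz=0.0)
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=12)
        d_at_ev = traj20.direction[traj20.sample_of(ev["t_s"].to_numpy())]
        assert np.all(d_at_ev == 1)


class TestSessionPair:
    def test_degenerate_stable_mixture_keeps_centres(self, cfg):
        rng = np.random.default_rng(0)
        specs = random_tuning_specs(cfg, 20, rng)
        pair = SessionPairSpec(p_stable=1.0, p_remap=0.0, p_lost=0.0, shift_sd_bins=0.0)
        sp = simulate_session_pair(cfg, specs, pair, n_laps=4, seed=1)
        assert np.allclose(sp.truth["centre1_cm"], sp.truth["centre2_cm"])
        assert (sp.truth["stability_class"] == "stable").all()

    def test_remapped_centres_move_more_than_two_bins(self, cfg):
        rng = np.random.default_rng(1)
        specs = random_tuning_specs(cfg, 50, rng)
        pair = SessionPairSpec(p_stable=0.0, p_remap=1.0, p_lost=0.0)
        specs2, classes = derive_session2_specs(specs, pair, cfg, np.random.default_rng(2))
        assert all(c == "remapped" for c in classes)
        for s1, s2 in zip(specs, specs2):
            assert abs(s2.field_centre_cm - s1.field_centre_cm) > 2 * cfg.bin_width_cm

    def test_lost_cells_silent_in_session2(self, cfg):
        rng = np.random.default_rng(2)
        specs = random_tuning_specs(cfg, 10, rng)
        pair = SessionPairSpec(p_stable=0.0, p_remap=0.0, p_lost=1.0)
        sp = simulate_session_pair(cfg, specs, pair, n_laps=4, seed=3)
        assert len(sp.session2.events) == 0

    def test_mixture_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SessionPairSpec(p_stable=0.5, p_remap=0.5, p_lost=0.5)


class TestFluorescence:
    def test_no_events_no_noise_constant_baseline(self):
        t = np.arange(100) * 0.1
        ev = pd.DataFrame(columns=["cell_id", "t_s", "amplitude"])
        F = simulate_fluorescence(ev, t, [0], noise_sd=0.0, baseline_f=1.3)
        assert np.allclose(F, 1.3)

    def test_single_event_peaks_then_decays_monotonically(self):
        t = np.arange(200) * 0.1
        ev = pd.DataFrame(dict(cell_id=[0], t_s=[5.0], amplitude=[1.0]))
        F = simulate_fluorescence(ev, t, [0], noise_sd=0.0)[0]
        peak = np.argmax(F)
        assert F[peak] > 1.0
        assert np.all(np.diff(F[peak:]) <= 1e-12)

    def test_seed_determinism_and_parameter_validation(self):
        t = np.arange(50) * 0.1
        ev = pd.DataFrame(dict(cell_id=[0], t_s=[1.0], amplitude=[1.0]))
        a = simulate_fluorescence(ev, t, [0], noise_sd=0.1, seed=5)
        b = simulate_fluorescence(ev, t, [0], noise_sd=0.1, seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            simulate_fluorescence(ev, t, [0], kernel_rise_s=0.5, kernel_decay_s=0.2)
        with pytest.raises(ValueError):
            simulate_fluorescence(ev, t, [0], noise_sd=-0.1)


class TestOlmTraces:
    def test_zero_velocity_zero_traces(self, cfg):
        traj = simulate_trajectory(cfg, 2, 20.0, 0.0, seed=0)
        still = traj
        still.v[:] = 0.0
        out = simulate_olm_traces(still, noise_sd=0.0, seed=1)
        assert np.allclose(out.dff, 0.0)

    def test_novelty_factor_halves_mean_activity(self, cfg, traj20):
        fam = simulate_olm_traces(traj20, novelty_factor=1.0, noise_sd=0.0, seed=2)
        nov = simulate_olm_traces(traj20, novelty_factor=0.5, noise_sd=0.0, seed=2)
        ratio = nov.dff.mean() / fam.dff.mean()
        assert ratio == pytest.approx(0.5, rel=1e-9)

    def test_regression_recovers_gain_within_10pct(self, cfg, traj20):
        out = simulate_olm_traces(traj20, gain_per_cm_s=0.01, noise_sd=1e-4, n_cells=5, seed=3)
        for i in range(5):
            slope = np.polyfit(traj20.v, out.dff[i], 1)[0]
            assert slope == pytest.approx(out.gains[i], rel=0.1)

    def test_parameter_validation(self, traj20):
        with pytest.raises(ValueError):
            simulate_olm_traces(traj20, novelty_factor=1.5)
        with pytest.raises(ValueError):
            simulate_olm_traces(traj20, n_cells=0)


class TestFootprints:
    def test_identity_transform_reproduces_stack(self):
        A, B, match = simulate_footprints(12, (96, 96), seed=0)
        assert len(B.cell_ids) == 12
        assert np.allclose(A.images, B.images)
        assert match == [(i, i) for i in range(12)]

    def test_drop_fraction_removes_exact_count(self):
        A, B, match = simulate_footprints(50, (256, 256), drop_fraction=0.2, seed=1)
        assert len(B.cell_ids) == 40
        assert len(match) == 40

    def test_shift_recovered_by_cross_correlation_oracle(self):
        from scipy.signal import fftconvolve

        A, B, _ = simulate_footprints(10, (96, 96), shift_px=(3, -2), seed=2)
        corr = fftconvolve(B.fov, A.fov[::-1, ::-1], mode="same")
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        centre = (corr.shape[0] // 2, corr.shape[1] // 2)
        assert (peak[0] - centre[0], peak[1] - centre[1]) == (3, -2)

    def test_overcrowded_fov_raises(self):
        with pytest.raises(RuntimeError):
            simulate_footprints(500, (48, 48), seed=3)
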