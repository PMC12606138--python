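import numpy as np
import pandas as pd
import pytest

from placefields.config import TrackConfig
from placefields.placecells import (
    EmptyMapError,
    NoFieldError,
    compute_rate_map,
    detect_place_field,
    even_odd_consistency,
    map_spatial_information,
    place_cell_test,
    resolve_direction,
    spatial_information,
)
from placefields.signals import RunningMask
from placefields.synth import CellTuningSpec, simulate_place_cell_events


def si_oracle(p, r):
    """Direct term-by-term evaluation of the Skaggs sum."""
    p = np.asarray(p, float)
    r = np.asarray(r, float)
    r_bar = sum(pi * ri for pi, ri in zip(p, r))
    if r_bar == 0:
        return 0.0
    total = 0.0
    for pi, ri in zip(p, r):
        if pi > 0 and ri > 0:
            total += pi * (ri / r_bar) * np.log2(ri / r_bar)
    return total


class TestSpatialInformation:
    def test_uniform_map_gives_zero(self):
        assert spatial_information(np.full(8, 0.125), np.full(8, 3.7)) == 0.0

    def test_two_bin_hand_value(self):
        # p = [.5, .5], r = [2, 0]: r_bar = 1, SI = .5*2*log2(2) = 1 bit
        assert spatial_information([0.5, 0.5], [2.0, 0.0]) == pytest.approx(1.0)

    def test_four_bin_hand_value(self):
        # p = .25 each, r = [4,0,0,0]: r_bar = 1, SI = .25*4*log2(4) = 2 bits
        assert spatial_information([0.25] * 4, [4.0, 0.0, 0.0, 0.0]) == pytest.approx(2.0)

    def test_matches_oracle_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 40)
            p = rng.dirichlet(np.ones(n))
            r = rng.gamma(1.0, 2.0, n) * (rng.random(n) > 0.2)
            assert spatial_information(p, r) == pytest.approx(si_oracle(p, r), abs=1e-12)

    def test_nonnegative_and_zero_iff_constant(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.dirichlet(np.ones(10))
            r = rng.gamma(1.0, 2.0, 10)
            assert spatial_information(p, r) >= -1e-15

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            spatial_information([0.5, 0.5], [1.0, -1.0])


class TestRateMap:
    def test_events_in_single_bin_with_uniform_occupancy(self, cfg):
        # synthetic aligned trajectory: one sample per bin centre, running
        n = cfg.n_bins
        t = np.arange(n) * 0.1
        x = cfg.bin_centres.copy()
        traj_like = _make_traj(t, x)
        mask = RunningMask(accepted=np.ones(n, bool))
        events = t[[7, 7, 7]]
        m = compute_rate_map(events, traj_like, mask, cfg, "right", sigma_bins=0.0)
        assert m.r[7] == pytest.approx(30.0)  # 3 events / 0.1 s
        assert np.sum(m.r[m.valid] > 0) == 1

    def test_smoothing_preserves_occupancy_weighted_mean(self, cfg, traj20, mask20):
        spec = CellTuningSpec(field_centre_cm=60, peak_rate_hz=6.0, direction="right",
                              baseline_rate_hz=0.2)
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=4)
        m = compute_rate_map(ev["t_s"].to_numpy(), traj20, mask20, cfg, "right")
        raw_mean = m.n_events / m.occupancy_s.sum()
        assert m.r_bar == pytest.approx(raw_mean, abs=1e-12)
        # direct kernel-sum oracle: smoothed counts over smoothed occupancy
        from placefields.placecells import smoothing_matrix

        M = smoothing_matrix(cfg.n_bins, 1.5, m.valid)
        counts = np.nan_to_num(m.r) * m.occupancy_s
        oracle = (M @ counts)[m.valid] / (M @ m.occupancy_s)[m.valid]
        assert np.allclose(m.r_smooth[m.valid], oracle, atol=1e-12)

    def test_occupancy_probabilities_sum_to_one(self, cfg, traj20, mask20):
        spec = CellTuningSpec(field_centre_cm=60, direction="right")
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=5)
        m = compute_rate_map(ev["t_s"].to_numpy(), traj20, mask20, cfg, "right")
        assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmax(m.r_norm) == pytest.approx(1.0)

    def test_zero_occupancy_direction_raises(self, cfg):
        t = np.arange(10) * 0.1
        traj_like = _make_traj(t, np.full(10, 70.0))
        mask = RunningMask(accepted=np.zeros(10, bool))
        with pytest.raises(EmptyMapError):
            compute_rate_map(np.array([0.5]), traj_like, mask, cfg, "right")


def _make_traj(t, x, direction=1):
    from placefields.signals import Trajectory

    n = len(t)
    return Trajectory(
        t=t, x=x, v=np.full(n, 20.0), lap=np.zeros(n, int),
        direction=np.full(n, direction, np.int8),
    )


class TestPlaceField:
    def test_worked_example_with_75pct_rule(self):
        r_norm = np.array([0.0, 0.5, 1.0, 0.8, 0.7, 0.0])
        centre, bins, width = detect_place_field(r_norm)
        assert centre == 2
        assert list(bins) == [2, 3]  # 0.7 < 0.75 stops expansion; 0.5 below too
        cfg = TrackConfig()
        _, _, width_cm = detect_place_field_map(r_norm, cfg)
        assert width_cm == pytest.approx(2 * 2.75)

    def test_single_nonzero_bin(self):
        r = np.zeros(40)
        r[11] = 0.3
        centre, bins, _ = detect_place_field(r)
        assert centre == 11 and list(bins) == [11]

    def test_uniform_map_ties_to_lowest_bin_and_spans_all(self):
        r = np.ones(10)
        centre, bins, _ = detect_place_field(r)
        assert centre == 0
        assert len(bins) == 10

    def test_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(2)
        r = rng.random(40)
        a = detect_place_field(r)
        b = detect_place_field(r * 37.5)
        assert a[0] == b[0] and list(a[1]) == list(b[1])

    def test_all_zero_map_raises(self):
        with pytest.raises(NoFieldError):
            detect_place_field(np.zeros(10))


def detect_place_field_map(r_norm, cfg):
    """Helper: field geometry in cm on a given config's grid."""
    centre, bins, _ = detect_place_field(r_norm)
    return centre, bins, bins.size * cfg.bin_width_cm


class TestShuffleTest:
    def test_silent_cell_is_not_a_place_cell(self, cfg, traj20, mask20):
        res = place_cell_test(np.empty(0), traj20, mask20, cfg, "right", seed=0)
        assert not res.is_place_cell and res.degenerate
        assert res.si_bits == 0.0

    def test_strongly_tuned_cell_detected_with_centre_recovery(self, cfg, traj20, mask20):
        spec = CellTuningSpec(field_centre_cm=70, field_sd_cm=8, peak_rate_hz=5.0,
                              direction="right", baseline_rate_hz=0.05)
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=6)
        res = place_cell_test(ev["t_s"].to_numpy(), traj20, mask20, cfg, "right", seed=7)
        assert res.is_place_cell
        assert res.z > 3
        assert abs(res.field_centre_bin - cfg.bin_of(np.array([70.0]))[0]) <= 1

    def test_min_shuffles_enforced(self, cfg, traj20, mask20):
        with pytest.raises(ValueError):
            place_cell_test(np.array([5.0]), traj20, mask20, cfg, "right", n_shuffles=10)

    def test_determinism_given_seed(self, cfg, traj20, mask20):
        spec = CellTuningSpec(field_centre_cm=50, direction="right")
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=8)
        t = ev["t_s"].to_numpy()
        a = place_cell_test(t, traj20, mask20, cfg, "right", seed=9)
        b = place_cell_test(t, traj20, mask20, cfg, "right", seed=9)
        assert a.p_value == b.p_value and a.null_mean == b.null_mean


class TestResolveDirection:
    def _res(self, is_pc, rate, direction="right"):
        from placefields.placecells import PlaceCellResult

        return PlaceCellResult(
            direction=direction, si_bits=1.0, null_mean=0.0, null_sd=1.0, z=3.0,
            p_value=0.01 if is_pc else 0.5, is_place_cell=is_pc,
            field_centre_bin=5, field_bins=np.array([5]), field_width_cm=2.75,
            mean_rate_hz=rate, n_events=10, degenerate=False, map=None,
        )

    def test_single_direction_place_cell_retained(self):
        left = self._res(True, 0.2, "left")
        right = self._res(False, 0.4, "right")
        assert resolve_direction(left, right).direction == "left"

    def test_both_directions_keeps_higher_rate(self):
        left = self._res(True, 0.2, "left")
        right = self._res(True, 0.1, "right")
        assert resolve_direction(left, right).direction == "left"

    def test_neither_direction_returns_none(self):
        assert resolve_direction(self._res(False, 0.2), self._res(False, 0.1)) is None

    def test_tie_keeps_right_with_warning(self):
        left = self._res(True, 0.2, "left")
        right = self._res(True, 0.2, "right")
        with pytest.warns(UserWarning):
            assert resolve_direction(left, right).direction == "right"


class TestEvenOdd:
    def test_stable_tuning_gives_high_split_correlation(self, cfg, traj20, mask20):
        spec = CellTuningSpec(field_centre_cm=60, field_sd_cm=8, peak_rate_hz=8.0,
                              direction="right", baseline_rate_hz=0.1)
        ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=10)
        table, even, odd = even_odd_consistency(ev, traj20, mask20, cfg, "right")
        assert len(table) == 1
        assert table["r_even_odd"].iloc[0] > 0.7
        assert even.shape == odd.shape == (1, cfg.n_bins)

    def test_cell_silent_on_one_split_excluded(self, cfg, traj20, mask20):
        # all events on even-rank rightward traversals only
        right_laps = np.unique(traj20.lap[traj20.direction == 1])
        even_rank = set(right_laps[::2])
        sel = np.isin(traj20.lap, list(even_rank)) & (traj20.direction == 1)
        ev = pd.DataFrame(dict(cell_id=0, t_s=traj20.t[sel][:20], amplitude=1.0))
        table, _, _ = even_odd_consistency(ev, traj20, mask20, cfg, "right")
        assert len(table) == 0

    def test_coin_flip_assignment_nonnegative_mean_correlation(self, cfg, traj20, mask20):
        rng = np.random.default_rng(11)
        rs = []
        spec = CellTuningSpec(field_centre_cm=75, field_sd_cm=10, peak_rate_hz=6.0,
                              direction="right", baseline_rate_hz=0.3)
        for s in range(10):
            ev, _ = simulate_place_cell_events(traj20, [spec], cfg, seed=20 + s)
            table, _, _ = even_odd_consistency(ev, traj20, mask20, cfg, "right")
            if len(table):
                rs.append(table["r_even_odd"].iloc[0])
        assert np.mean(rs) > 0
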