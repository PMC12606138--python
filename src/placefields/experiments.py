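"""Seeded end-to-end validation experiments.

Each experiment generates synthetic sessions with the generator's default
study conditions, runs the analysis pipeline on them, and measures a
recovery or calibration quantity against the generator's ground truth. They
back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ttest_ind

from .config import AnalysisParams, TrackConfig
from .pipeline import analyze_session, compare_sessions, thinning_control, zone_event_rates
from .placecells import place_cell_test
from .registration import register_sessions
from .signals import running_mask
from .synth import (
    CellTuningSpec,
    SessionPairSpec,
    random_tuning_specs,
    simulate_footprints,
    simulate_olm_traces,
    simulate_place_cell_events,
    simulate_session_pair,
    simulate_trajectory,
)

DEFAULT_ZONES = dict(opto_zone=(26.0, 59.0), control_zone=(59.0, 92.0))

# Session-level experiments use 20 round-trip laps (40 end-to-end traversals):
# on a linear track a "lap" is conventionally out-and-back, giving each
# direction-selective cell ~20 passes through its field.


def default_config() -> TrackConfig:
    return TrackConfig(**DEFAULT_ZONES)


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def type_i_calibration(
    n_cells: int = 500,
    n_laps: int = 40,
    rate_hz: float = 0.5,
    seed: int = 0,
    n_shuffles: int = 1000,
) -> dict:
    """False-positive fraction of the shuffle test on untuned Poisson cells.

    Homogeneous cells carry no spatial information, so the fraction of
    cell-directions classified as place cells estimates the test's type-I
    error at the nominal alpha.
    """
    cfg = default_config()
    s_traj, s_ev, s_test = _sub_seeds(seed, 3)
    traj = simulate_trajectory(cfg, n_laps, seed=s_traj)
    mask = running_mask(traj.v, traj)
    specs = [
        CellTuningSpec(field_centre_cm=70.0, peak_rate_hz=rate_hz,
                       baseline_rate_hz=rate_hz, direction="both")
        for _ in range(n_cells)
    ]
    events, _ = simulate_place_cell_events(traj, specs, cfg, seed=s_ev)
    test_seeds = _sub_seeds(s_test, n_cells)
    n_pos = 0
    for cid in range(n_cells):
        times = events.loc[events["cell_id"] == cid, "t_s"].to_numpy()
        res = place_cell_test(
            times, traj, mask, cfg, "right", n_shuffles=n_shuffles, seed=test_seeds[cid]
        )
        n_pos += res.is_place_cell
    return dict(false_positive_rate=n_pos / n_cells, n=n_cells)


def detection_recovery(
    n_cells: int = 100,
    n_laps: int = 40,
    peak_rate_hz: float = 5.0,
    field_sd_cm: float = 8.0,
    seed: int = 0,
) -> dict:
    """Sensitivity and field-centre accuracy on strongly tuned cells.

    Field centres are kept one tuning width inside the analysed region so
    the true field is fully sampled.
    """
    cfg = default_config()
    s_traj, s_spec, s_ev, s_an = _sub_seeds(seed, 4)
    traj = simulate_trajectory(cfg, n_laps, seed=s_traj)
    specs = random_tuning_specs(
        cfg, n_cells, np.random.default_rng(s_spec),
        peak_rate_hz=peak_rate_hz, field_sd_cm=field_sd_cm, margin_cm=field_sd_cm,
    )
    events, truth = simulate_place_cell_events(traj, specs, cfg, seed=s_ev)
    analysis = analyze_session(traj, events, cfg, seed=s_an)
    detected = analysis.table[analysis.table["is_place_cell"]]
    merged = detected.merge(truth, on="cell_id")
    true_bins = cfg.bin_of(merged["centre_cm"].to_numpy())
    err_bins = np.abs(merged["field_centre_bin"].to_numpy() - true_bins)
    return dict(
        sensitivity=len(detected) / n_cells,
        frac_centre_within_1_bin=float(np.mean(err_bins <= 1)) if len(merged) else 0.0,
        n=n_cells,
    )


def mixture_recovery(
    n_cells: int = 150,
    probs: tuple = (0.5, 0.3, 0.2),
    n_laps: int = 40,
    seed: int = 0,
) -> dict:
    """Retention-class proportions on a session pair with a known mixture."""
    cfg = default_config()
    s_spec, s_pair, s_a1, s_a2 = _sub_seeds(seed, 4)
    specs = random_tuning_specs(
        cfg, n_cells, np.random.default_rng(s_spec), peak_rate_hz=5.0, margin_cm=8.0
    )
    pair = SessionPairSpec(p_stable=probs[0], p_remap=probs[1], p_lost=probs[2])
    sp = simulate_session_pair(cfg, specs, pair, n_laps=n_laps, seed=s_pair)
    a1 = analyze_session(sp.session1.traj, sp.session1.events, cfg, seed=s_a1)
    a2 = analyze_session(sp.session2.traj, sp.session2.events, cfg, seed=s_a2)
    report = compare_sessions(a1, a2)
    counts = report.table["retention"].value_counts()
    n_pc = len(report.table)
    props = {k: counts.get(k, 0) / n_pc for k in ("stable", "remapped", "lost")}
    return dict(
        stable=props["stable"],
        remapped=props["remapped"],
        lost=props["lost"],
        n_place_cells=n_pc,
        partition_exact=int(counts.sum()) == n_pc,
        truth=dict(stable=probs[0], remapped=probs[1], lost=probs[2]),
    )


def registration_recovery(
    n_cells: int = 40,
    shift_px: tuple = (4.0, -3.0),
    rotation_deg: float = 3.0,
    jitter_px: float = 1.0,
    drop_fraction: float = 0.2,
    seed: int = 0,
) -> dict:
    """Rigid-transform and pairing recovery on jittered footprint stacks."""
    A, B, truth = simulate_footprints(
        n_cells, (128, 128), shift_px=shift_px, rotation_deg=rotation_deg,
        jitter_px=jitter_px, drop_fraction=drop_fraction, seed=seed,
    )
    res = register_sessions(A, B, threshold=0.5)
    inv = res.transform.inverse()
    true_map = dict(truth)
    hits = sum(1 for a, b, _ in res.pairs if true_map.get(a) == b)
    dropped = set(range(n_cells)) - set(true_map)
    false_dropped = sum(1 for a, _, _ in res.pairs if a in dropped)
    return dict(
        rotation_error_deg=abs(inv.rotation_deg - rotation_deg),
        shift_error_px=float(np.hypot(inv.shift[0] - shift_px[0], inv.shift[1] - shift_px[1])),
        pair_recall=hits / len(truth),
        false_matches_of_dropped=false_dropped,
        n=n_cells,
    )


def opto_zone_rate_experiment(
    opto_gain: float = 0.5,
    n_cells: int = 10,
    n_laps: int = 30,
    seed: int = 0,
) -> dict:
    """Opto- vs control-zone population event rate under a known gain."""
    cfg = default_config()
    s_traj, s_ev = _sub_seeds(seed, 2)
    traj = simulate_trajectory(cfg, n_laps, seed=s_traj)
    mask = running_mask(traj.v, traj)
    specs = [
        CellTuningSpec(field_centre_cm=70.0, peak_rate_hz=3.0,
                       baseline_rate_hz=3.0, direction="both")
        for _ in range(n_cells)
    ]
    events, _ = simulate_place_cell_events(traj, specs, cfg, seed=s_ev, opto_gain=opto_gain)
    zs = zone_event_rates(events, traj, mask, cfg)
    return dict(
        rate_ratio=zs.population_mean["opto"] / zs.population_mean["control"],
        true_gain=opto_gain,
        n=n_cells,
    )


def thinning_experiment(
    n_seeds: int = 20,
    n_cells: int = 40,
    n_laps: int = 20,
    fraction: float = 0.30,
    seed: int = 0,
) -> dict:
    """Event thinning reduces in-zone place cells but not survivor stability.

    Emulates the control dataset (no optogenetic effect in the generator);
    removes the stated fraction of in-zone events; compares in-zone
    place-cell counts and the across-session spatial correlations of
    surviving in-zone place cells between thinned and unthinned runs.
    """
    cfg = default_config()
    params = AnalysisParams()
    seeds = _sub_seeds(seed, 5 * n_seeds)
    n_un = n_th = 0
    corr_un: list = []
    corr_th: list = []

    def inzone(analysis):
        out = []
        for cid, res in analysis.retained.items():
            c = cfg.bin_centres[res.field_centre_bin]
            lo, hi = cfg.zone_interval("opto", res.direction)
            if lo <= c < hi:
                out.append(cid)
        return out

    def surviving_corrs(report, cells):
        t = report.table.set_index("cell_id")
        return [
            float(t.loc[c, "spatial_r"])
            for c in cells
            if c in t.index and not t.loc[c, "corr_excluded"]
        ]

    for k in range(n_seeds):
        s_spec, s_pair, s_a1, s_a2, s_thin = seeds[5 * k : 5 * k + 5]
        specs = random_tuning_specs(
            cfg, n_cells, np.random.default_rng(s_spec), peak_rate_hz=(0.5, 3.0)
        )
        pair = SessionPairSpec(p_stable=0.6, p_remap=0.2, p_lost=0.2)
        sp = simulate_session_pair(cfg, specs, pair, n_laps=n_laps, seed=s_pair)
        a2 = analyze_session(sp.session2.traj, sp.session2.events, cfg, params, seed=s_a2)
        a1 = analyze_session(sp.session1.traj, sp.session1.events, cfg, params, seed=s_a1)
        thin = thinning_control(
            sp.session1.events, sp.session1.traj, cfg, fraction=fraction, seed=s_thin
        )
        a1t = analyze_session(sp.session1.traj, thin, cfg, params, seed=s_a1)
        iz, izt = inzone(a1), inzone(a1t)
        n_un += len(iz)
        n_th += len(izt)
        corr_un += surviving_corrs(compare_sessions(a1, a2), iz)
        corr_th += surviving_corrs(compare_sessions(a1t, a2), izt)
    p = float(ttest_ind(corr_un, corr_th).pvalue)
    return dict(
        n_inzone_unthinned=n_un,
        n_inzone_thinned=n_th,
        corr_mean_unthinned=float(np.mean(corr_un)),
        corr_mean_thinned=float(np.mean(corr_th)),
        corr_ttest_p=p,
        n_seeds=n_seeds,
    )


def olm_novelty_experiment(
    novelty_factor: float = 0.5,
    n_cells: int = 35,
    n_laps: int = 15,
    seed: int = 0,
) -> dict:
    """Novel- vs familiar-environment interneuron activity recovery.

    The generator suppresses velocity-coupled interneuron activity by the
    novelty factor; the lap-activity pipeline should recover that ratio
    from the last familiar laps vs the first novel laps.
    """
    from .pipeline import olm_environment_means, olm_lap_activity

    s1, s2, s3 = _sub_seeds(seed, 3)
    cfg = default_config()
    traj_fam = simulate_trajectory(cfg, n_laps, seed=s1)
    traj_nov = simulate_trajectory(cfg, n_laps, seed=s2)
    fam = simulate_olm_traces(traj_fam, novelty_factor=1.0, noise_sd=0.01,
                              n_cells=n_cells, seed=s3)
    nov = simulate_olm_traces(traj_nov, novelty_factor=novelty_factor, noise_sd=0.01,
                              n_cells=n_cells, seed=s3)
    env = olm_environment_means(
        olm_lap_activity(fam.dff, traj_fam), olm_lap_activity(nov.dff, traj_nov)
    )
    return dict(
        activity_ratio=float(env["env2_mean"].mean() / env["env1_mean"].mean()),
        true_factor=novelty_factor,
        n=n_cells,
    )
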