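"""Per-session and across-session analysis orchestration.

Runs the place-cell detector over all cells of a session, resolves
directions, assembles zone statistics, the event-thinning control, and
interneuron (OLM) activity summaries; pairs of analysed sessions are
compared into a stability report.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .config import AnalysisParams, TrackConfig, direction_code
from .placecells import (
    EmptyMapError,
    PlaceCellResult,
    place_cell_test,
    resolve_direction,
)
from .signals import RunningMask, Trajectory, running_mask
from .stability import StabilityReport, build_stability_table, pv_matrix, zone_pv_score

ZONE_LABELS = ("opto", "control", "ends")


def _cell_seed(base_seed: int, key) -> int:
    """Stable per-cell seed, independent of iteration order and process."""
    digest = zlib.crc32(repr(key).encode())
    ss = np.random.SeedSequence([int(base_seed), digest])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SessionAnalysis:
    """All per-cell detector outcomes for one session."""

    cfg: TrackConfig
    params: AnalysisParams
    traj: Trajectory
    mask: RunningMask
    results: dict  # cell_id -> {'left': PlaceCellResult, 'right': ...}
    retained: dict  # place-cell id -> retained PlaceCellResult
    table: pd.DataFrame

    @property
    def place_cell_ids(self) -> list:
        return list(self.retained.keys())


def analyze_session(
    traj: Trajectory,
    events: pd.DataFrame,
    cfg: TrackConfig,
    params: AnalysisParams | None = None,
    seed: int = 0,
    cell_ids: list | None = None,
) -> SessionAnalysis:
    """Run the place-cell pipeline on every cell of a session.

    Each cell is tested independently in both directions with the shuffle
    test; cells qualifying in both keep only the higher-rate direction.
    The returned table has one row per cell with the retained direction's
    statistics (non-place cells report their best direction).
    """
    params = params or AnalysisParams()
    mask = running_mask(
        traj.v, traj, threshold=params.run_threshold_cms,
        min_distance=params.run_min_distance_cm,
    )
    if cell_ids is None:
        cell_ids = sorted(events["cell_id"].unique())
    grouped = {cid: g["t_s"].to_numpy() for cid, g in events.groupby("cell_id")}
    results: dict = {}
    retained: dict = {}
    rows = []
    for cid in cell_ids:
        times = grouped.get(cid, np.empty(0))
        per_dir = {}
        for dname in ("left", "right"):
            try:
                per_dir[dname] = place_cell_test(
                    times, traj, mask, cfg, dname,
                    n_shuffles=params.n_shuffles,
                    alpha=params.alpha,
                    seed=_cell_seed(seed, (cid, dname)),
                    sigma_bins=params.sigma_bins,
                    field_threshold=params.field_threshold,
                )
            except EmptyMapError:
                continue
        if not per_dir:
            continue
        results[cid] = per_dir
        if "left" in per_dir and "right" in per_dir:
            best = resolve_direction(per_dir["left"], per_dir["right"])
        else:
            only = next(iter(per_dir.values()))
            best = only if only.is_place_cell else None
        if best is not None:
            retained[cid] = best
            shown = best
        else:
            shown = max(per_dir.values(), key=lambda r: (not np.isnan(r.z) and r.z) or -np.inf)
        centre_cm = (
            cfg.bin_centres[shown.field_centre_bin]
            if shown.field_centre_bin is not None
            else np.nan
        )
        rows.append(
            dict(
                cell_id=cid,
                direction=shown.direction,
                si_bits=shown.si_bits,
                z=shown.z,
                p_value=shown.p_value,
                is_place_cell=best is not None,
                field_centre_bin=shown.field_centre_bin,
                field_centre_cm=centre_cm,
                field_width_cm=shown.field_width_cm,
                mean_rate_hz=shown.mean_rate_hz,
                n_events=shown.n_events,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "direction", "si_bits", "z", "p_value", "is_place_cell",
            "field_centre_bin", "field_centre_cm", "field_width_cm",
            "mean_rate_hz", "n_events",
        ],
    )
    return SessionAnalysis(
        cfg=cfg, params=params, traj=traj, mask=mask,
        results=results, retained=retained, table=table,
    )


def compare_sessions(
    a1: SessionAnalysis, a2: SessionAnalysis, zone_directions: str = "right"
) -> StabilityReport:
    """Stability of session-1 place cells into session 2.

    Session-2 maps use each cell's session-1 retained direction,
    irrespective of the cell's session-2 place-cell status. The
    population-vector matrix is computed from max-normalised maps; zone
    scores average its diagonal over the configured zone bins.
    """
    cfg = a1.cfg
    # every session-1 place cell is compared; a cell silent in session 2 has
    # no session-2 map (correlation excluded) and counts as lost
    cells = list(a1.place_cell_ids)
    maps1, maps2, centres1, centres2, pc2 = {}, {}, {}, {}, {}
    for cid in cells:
        res1 = a1.retained[cid]
        maps1[cid] = res1.map
        centres1[cid] = res1.field_centre_bin
        res2_dir = a2.results.get(cid, {}).get(res1.direction)
        if res2_dir is not None:
            maps2[cid] = res2_dir.map
        is_pc2 = cid in a2.retained
        pc2[cid] = is_pc2
        if is_pc2:
            centres2[cid] = a2.retained[cid].field_centre_bin
    table = build_stability_table(
        cells, maps1, maps2, pc2, centres1, centres2, cfg,
        tol_bins=a1.params.retention_tol_bins,
        r_threshold=a1.params.stability_r_threshold,
    )
    pv = None
    zone_scores: dict = {}
    with_maps = [cid for cid in cells if cid in maps2]
    if len(with_maps) >= 2:
        m1 = np.vstack([np.nan_to_num(maps1[c].r_norm, nan=0.0) for c in with_maps])
        m2 = []
        for c in with_maps:
            r = maps2[c].r_smooth
            peak = np.nanmax(r)
            m2.append(np.nan_to_num(r / peak if peak > 0 else r, nan=0.0))
        pv = pv_matrix(m1, np.vstack(m2))
        for zone in ("opto", "control"):
            try:
                bins = cfg.zone_bins(zone, zone_directions)
                zone_scores[zone] = zone_pv_score(pv, bins)
            except (KeyError, ValueError):
                continue
        if cfg.opto_zone is not None and cfg.control_zone is not None:
            inzone = np.zeros(cfg.n_bins, dtype=bool)
            inzone[cfg.zone_bins("opto", zone_directions)] = True
            inzone[cfg.zone_bins("control", zone_directions)] = True
            ends = np.flatnonzero(~inzone)
            if ends.size:
                try:
                    zone_scores["ends"] = zone_pv_score(pv, ends)
                except ValueError:
                    pass
    return StabilityReport(table=table, pv=pv, zone_scores=zone_scores)


# ---------------------------------------------------------------------------
# zone statistics
# ---------------------------------------------------------------------------

def zone_labels_per_sample(traj: Trajectory, cfg: TrackConfig) -> np.ndarray:
    """Zone label per sample ('opto', 'control', 'ends', '' outside analysis).

    Zone intervals are direction-specific to support staggered optogenetic
    zones per lap direction.
    """
    labels = np.full(traj.n_samples, "", dtype=object)
    analysed = (traj.x >= cfg.analysed_start) & (traj.x <= cfg.analysed_stop)
    labels[analysed] = "ends"
    for zone in ("opto", "control"):
        z = {"opto": cfg.opto_zone, "control": cfg.control_zone}[zone]
        if z is None:
            continue
        for dname in ("left", "right"):
            lo, hi = cfg.zone_interval(zone, dname)
            sel = analysed & (traj.direction == direction_code(dname)) & (traj.x >= lo) & (traj.x < hi)
            labels[sel] = zone
    return labels


@dataclass
class ZoneStats:
    """Per-cell and population event rates per track zone."""

    per_cell: pd.DataFrame  # cell_id × zone rate columns
    occupancy_s: dict
    population_mean: dict


def zone_event_rates(
    events: pd.DataFrame,
    traj: Trajectory,
    mask: RunningMask,
    cfg: TrackConfig,
) -> ZoneStats:
    """Running event rate per cell within each zone.

    Rate = in-zone running events / in-zone running occupancy; zones with
    zero running occupancy yield NaN rates. Zone event counts plus the
    'ends' remainder recompose the total running event count exactly.
    """
    labels = zone_labels_per_sample(traj, cfg)
    run = mask.accepted
    dt = traj.dt
    occ = {z: float(np.sum(run & (labels == z))) * dt for z in ZONE_LABELS}
    cell_ids = sorted(events["cell_id"].unique())
    ev_idx = traj.sample_of(events["t_s"].to_numpy()) if len(events) else np.empty(0, int)
    ev_zone = labels[ev_idx] if len(events) else np.empty(0, object)
    ev_run = run[ev_idx] if len(events) else np.empty(0, bool)
    rows = []
    for cid in cell_ids:
        sel = (events["cell_id"] == cid).to_numpy()
        row = {"cell_id": cid}
        for z in ZONE_LABELS:
            n = int(np.sum(sel & ev_run & (ev_zone == z)))
            row[f"n_{z}"] = n
            row[f"rate_{z}"] = n / occ[z] if occ[z] > 0 else np.nan
        rows.append(row)
    per_cell = pd.DataFrame(rows)
    population_mean = {
        z: float(per_cell[f"rate_{z}"].mean()) if len(per_cell) else np.nan
        for z in ZONE_LABELS
    }
    return ZoneStats(per_cell=per_cell, occupancy_s=occ, population_mean=population_mean)


def zone_place_cell_proportions(analysis: SessionAnalysis) -> dict:
    """Fraction of place cells whose field centre falls in each zone.

    Centres are assigned using the retained direction's zone intervals;
    centres outside both zones count toward the 'ends' label. Raises on an
    empty place-cell set.
    """
    cfg = analysis.cfg
    if not analysis.retained:
        raise ValueError("no place cells to assign")
    counts = {z: 0 for z in ZONE_LABELS}
    for cid, res in analysis.retained.items():
        centre_cm = cfg.bin_centres[res.field_centre_bin]
        label = "ends"
        for zone in ("opto", "control"):
            z = {"opto": cfg.opto_zone, "control": cfg.control_zone}[zone]
            if z is None:
                continue
            lo, hi = cfg.zone_interval(zone, res.direction)
            if lo <= centre_cm < hi:
                label = zone
                break
        counts[label] += 1
    n = len(analysis.retained)
    return {z: counts[z] / n for z in ZONE_LABELS}


def thinning_control(
    events: pd.DataFrame,
    traj: Trajectory,
    cfg: TrackConfig,
    zone: str = "opto",
    fraction: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """Remove a fixed fraction of each cell's in-zone events.

    Per cell, exactly ``floor(fraction × n_zone)`` in-zone events are removed
    by seeded sampling without replacement; out-of-zone events are
    untouched. Mimics the rate effect of inhibition confined to the
    optogenetic zone without touching the Poisson generator.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    if len(events) == 0 or fraction == 0:
        return events.copy().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = traj.sample_of(events["t_s"].to_numpy())
    x = traj.x[idx]
    d = traj.direction[idx]
    inzone = np.zeros(len(events), dtype=bool)
    for dname in ("left", "right"):
        lo, hi = cfg.zone_interval(zone, dname)
        inzone |= (d == direction_code(dname)) & (x >= lo) & (x < hi)
    drop = np.zeros(len(events), dtype=bool)
    for cid in sorted(events["cell_id"].unique()):
        rows = np.flatnonzero((events["cell_id"] == cid).to_numpy() & inzone)
        k = int(np.floor(fraction * rows.size))
        if k > 0:
            drop[rng.choice(rows, size=k, replace=False)] = True
    return events.loc[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# interneuron (OLM) summaries
# ---------------------------------------------------------------------------

@dataclass
class OlmSummary:
    """Per-lap running-gated activity and velocity coupling of interneurons."""

    lap_means: pd.DataFrame  # index: lap, columns: cell index
    velocity_curve: pd.DataFrame | None = None
    velocity_r: np.ndarray | None = None


def olm_lap_activity(
    dff: np.ndarray,
    traj: Trajectory,
    run_threshold: float = 7.0,
) -> OlmSummary:
    """Mean running-gated ΔF/F per lap per cell.

    Laps without running samples get NaN means. Environment summaries
    average the per-lap means (mean of lap means, not pooled samples).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if dff.shape[1] != traj.n_samples:
        raise ValueError("dff must be aligned to the trajectory")
    run = traj.v > run_threshold
    laps = np.unique(traj.lap)
    out = np.full((laps.size, dff.shape[0]), np.nan)
    for k, lap in enumerate(laps):
        sel = run & (traj.lap == lap)
        if sel.any():
            out[k] = np.nanmean(dff[:, sel], axis=1)
    return OlmSummary(lap_means=pd.DataFrame(out, index=laps))


def olm_environment_means(
    summary_session1: OlmSummary,
    summary_session2: OlmSummary,
    last_n: int = 10,
    first_n: int = 10,
) -> pd.DataFrame:
    """Per-cell means over the last laps of session 1 and first of session 2.

    Windows shrink when a session has fewer laps than requested; the number
    of laps actually used is reported alongside the means.
    """
    lm1, lm2 = summary_session1.lap_means, summary_session2.lap_means
    n1 = min(last_n, len(lm1))
    n2 = min(first_n, len(lm2))
    env1 = lm1.iloc[-n1:].mean(axis=0)
    env2 = lm2.iloc[:n2].mean(axis=0)
    return pd.DataFrame(
        dict(
            env1_mean=env1,
            env2_mean=env2,
            diff=env2 - env1,
            n_laps_env1=n1,
            n_laps_env2=n2,
        )
    )


def olm_velocity_profile(
    dff: np.ndarray,
    v: np.ndarray,
    bin_width: float = 5.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Velocity-binned activity curve and per-cell activity–velocity r.

    The curve is the across-cell mean of each cell's mean ΔF/F per velocity
    bin; empty bins are absent. Per-cell Pearson correlations use all
    samples.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    v = np.asarray(v, dtype=float)
    if dff.shape[1] != v.size:
        raise ValueError("dff and v must be aligned")
    edges = np.arange(0.0, v.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    which = np.digitize(v, edges) - 1
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            dict(
                v_lo=edges[b],
                v_hi=edges[b + 1],
                v_mid=0.5 * (edges[b] + edges[b + 1]),
                dff_mean=float(np.nanmean(dff[:, sel])),
                n_samples=int(sel.sum()),
            )
        )
    curve = pd.DataFrame(rows)
    rs = np.full(dff.shape[0], np.nan)
    for i in range(dff.shape[0]):
        row = dff[i]
        ok = np.isfinite(row)
        if ok.sum() >= 2 and np.ptp(row[ok]) > 0 and np.ptp(v[ok]) > 0:
            rs[i] = pearsonr(row[ok], v[ok])[0]
    return curve, rs
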