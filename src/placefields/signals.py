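"""Behavioural and fluorescence preprocessing.

Velocity from tracked position, sliding-percentile ΔF/F baselines, running
epoch detection and cell quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .config import TrackConfig, direction_code


@dataclass
class Trajectory:
    """Timestamped 1-D position on the track with derived labels.

    Attributes
    ----------
    t : array, seconds, strictly increasing and ~uniform
    x : array, cm from the left track end
    v : array, smoothed running speed (cm/s, nonnegative); direction is
        carried separately by ``direction``
    lap : int array, 0-based traversal counter
    direction : int8 array, +1 rightward / -1 leftward per sample
    """

    t: np.ndarray
    x: np.ndarray
    v: np.ndarray
    lap: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.lap = np.asarray(self.lap, dtype=int)
        self.direction = np.asarray(self.direction, dtype=np.int8)
        n = self.t.size
        if any(a.size != n for a in (self.x, self.v, self.lap, self.direction)):
            raise ValueError("trajectory arrays must share length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trajectory time must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.dt)

    def sample_of(self, times: np.ndarray) -> np.ndarray:
        """Nearest-sample index for each event time."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.t, times)
        idx = np.clip(idx, 1, self.t.size - 1)
        left = times - self.t[idx - 1] <= self.t[idx] - times
        idx[left] -= 1
        return idx


@dataclass
class RunningMask:
    """Accepted running samples plus the epoch list that produced them."""

    accepted: np.ndarray
    epochs: list = field(default_factory=list)  # (start, stop_exclusive, displacement_cm)

    def __post_init__(self):
        self.accepted = np.asarray(self.accepted, dtype=bool)


@dataclass
class TraceSet:
    """Fluorescence traces on the imaging time grid."""

    t: np.ndarray
    F: np.ndarray  # (n_cells, n_samples)
    cell_ids: list
    dff: np.ndarray | None = None
    flagged: np.ndarray | None = None  # cells with non-positive baseline

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        if self.F.shape[1] != self.t.size:
            raise ValueError("F must be (n_cells, n_samples)")
        if len(self.cell_ids) != self.F.shape[0]:
            raise ValueError("cell_ids length must match F rows")


def compute_velocity(t: np.ndarray, x: np.ndarray, window_s: float = 2.0) -> np.ndarray:
    """Running speed |dx/dt| smoothed with a centred moving average.

    The window shrinks one-sidedly at the ends of the recording so every
    sample gets a defined value.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("time must be strictly increasing")
    if np.ptp(dts) > 0.01 * np.median(dts) + 1e-12:
        raise ValueError("sampling must be uniform to within 1%")
    speed = np.abs(np.gradient(x, t))
    w = max(1, int(round(window_s / np.median(dts))))
    if w % 2 == 0:
        w += 1
    return (
        pd.Series(speed).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def compute_dff(
    F: np.ndarray,
    frame_rate_hz: float,
    window_s: float = 10.0,
    pct: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ΔF/F₀ with a sliding-window percentile baseline.

    The baseline at each sample is the ``pct``-th percentile of the raw
    fluorescence within a centred window of ``window_s`` seconds (shrunken at
    the recording edges). Cells whose baseline is non-positive anywhere are
    flagged and their ΔF/F set to NaN at those samples.

    Returns
    -------
    dff : array, same shape as ``F``
    flagged : boolean array per cell
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if not np.all(np.isfinite(F)):
        raise ValueError("fluorescence must be finite")
    w = max(2, int(round(window_s * frame_rate_hz)))
    if w % 2 == 0:
        w += 1
    dff = np.empty_like(F)
    flagged = np.zeros(F.shape[0], dtype=bool)
    q = pct / 100.0
    for i, row in enumerate(F):
        base = (
            pd.Series(row)
            .rolling(window=w, center=True, min_periods=1)
            .quantile(q)
            .to_numpy()
        )
        bad = base <= 0
        if bad.any():
            flagged[i] = True
        with np.errstate(divide="ignore", invalid="ignore"):
            dff[i] = (row - base) / base
        dff[i, bad] = np.nan
    return dff, flagged


def running_mask(
    v: np.ndarray,
    traj: Trajectory,
    threshold: float = 7.0,
    min_distance: float = 10.0,
) -> RunningMask:
    """Running epochs: maximal runs with v > threshold covering ≥ min_distance.

    Displacement is the path length (sum of |Δx|) within the epoch; epochs
    falling short of ``min_distance`` cm are rejected wholesale.
    """
    v = np.asarray(v, dtype=float)
    if v.size != traj.n_samples:
        raise ValueError("v must be aligned to the trajectory")
    above = v > threshold
    accepted = np.zeros_like(above)
    epochs = []
    if above.any():
        padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        stops = np.flatnonzero(padded == -1)
        for s, e in zip(starts, stops):
            disp = float(np.sum(np.abs(np.diff(traj.x[s:e])))) if e - s > 1 else 0.0
            if disp >= min_distance:
                accepted[s:e] = True
                epochs.append((int(s), int(e), disp))
    return RunningMask(accepted=accepted, epochs=epochs)


def estimate_snr(dff_row: np.ndarray, frame_rate_hz: float) -> float:
    """Peak ΔF/F over a MAD-based noise scale of the detrended trace.

    The trace is detrended with a ~2 s median filter; the noise scale is
    1.4826 × median absolute deviation of the residual. A zero noise scale
    yields infinite SNR.
    """
    row = np.asarray(dff_row, dtype=float)
    row = row[np.isfinite(row)]
    if row.size == 0:
        return 0.0
    k = max(3, int(round(2.0 * frame_rate_hz)) | 1)
    resid = row - median_filter(row, size=k, mode="nearest")
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    peak = float(np.max(row))
    if noise == 0:
        return np.inf if peak > 0 else 0.0
    return peak / noise


def qc_filter_cells(
    traces: TraceSet,
    events: pd.DataFrame,
    frame_rate_hz: float,
    snr_min: float = 10.0,
    rate_min_hz: float = 0.005,
) -> list:
    """Keep cells with SNR ≥ snr_min and event rate ≥ rate_min_hz.

    ``events`` is the long-format event table (cell_id, t_s, amplitude).
    Cells present in the event table but missing a trace are an error.
    """
    ids = set(traces.cell_ids)
    missing = set(events["cell_id"].unique()) - ids
    if missing:
        raise ValueError(f"events reference cells without traces: {sorted(missing)}")
    duration = traces.t[-1] - traces.t[0] + float(np.median(np.diff(traces.t)))
    counts = events.groupby("cell_id").size()
    dff = traces.dff
    if dff is None:
        dff, _ = compute_dff(traces.F, frame_rate_hz)
    kept = []
    for i, cid in enumerate(traces.cell_ids):
        rate = counts.get(cid, 0) / duration
        if rate < rate_min_hz:
            continue
        if estimate_snr(dff[i], frame_rate_hz) < snr_min:
            continue
        kept.append(cid)
    return kept


def label_laps(x: np.ndarray, track_length_cm: float, end_margin_cm: float | None = None):
    """Derive lap index and direction labels from a raw position trace.

    A lap is an end-to-end traversal; the turn point is detected when the
    animal enters an end margin (default: 10% of the track) and reverses.
    Returns (lap, direction) arrays.
    """
    x = np.asarray(x, dtype=float)
    if end_margin_cm is None:
        end_margin_cm = 0.1 * track_length_cm
    direction = np.zeros(x.size, dtype=np.int8)
    lap = np.zeros(x.size, dtype=int)
    cur_dir = 1 if x[min(10, x.size - 1)] >= x[0] else -1
    cur_lap = 0
    for i in range(x.size):
        if cur_dir == 1 and x[i] >= track_length_cm - end_margin_cm:
            # wait for actual reversal before flipping
            if i + 1 < x.size and x[i + 1] < x[i]:
                direction[i] = cur_dir
                lap[i] = cur_lap
                cur_dir = -1
                cur_lap += 1
                continue
        elif cur_dir == -1 and x[i] <= end_margin_cm:
            if i + 1 < x.size and x[i + 1] > x[i]:
                direction[i] = cur_dir
                lap[i] = cur_lap
                cur_dir = 1
                cur_lap += 1
                continue
        direction[i] = cur_dir
        lap[i] = cur_lap
    return lap, direction


def make_trajectory(
    t: np.ndarray,
    x: np.ndarray,
    cfg: TrackConfig,
    lap: np.ndarray | None = None,
    direction=None,
    velocity_window_s: float = 2.0,
) -> Trajectory:
    """Assemble a Trajectory, deriving velocity (and laps if absent)."""
    v = compute_velocity(t, x, window_s=velocity_window_s)
    if lap is None or direction is None:
        lap, direction = label_laps(x, cfg.track_length_cm)
    else:
        direction = np.asarray(
            [direction_code(d) if not np.issubdtype(type(d), np.integer) else d for d in direction],
            dtype=np.int8,
        )
    return Trajectory(t=t, x=x, v=v, lap=lap, direction=direction)
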