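"""Synthetic linear-track sessions with ground truth.

Every generator is a pure function of its seed. The statistical structure
mirrors the experimental design the analysis assumes: back-and-forth laps on
a 140 cm track with 15 cm reward zones, direction-selective Gaussian-tuned
Poisson place cells, multiplicative optogenetic-zone and novelty rate
modulation, across-session stability mixtures (stable / remapped / lost),
velocity-coupled interneuron ΔF/F with a novelty suppression factor, and 2-D
Gaussian footprints with across-session rigid jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RIGHT, TrackConfig, direction_code
from .signals import Trajectory, compute_velocity

EVENT_COLUMNS = ["cell_id", "t_s", "amplitude"]


@dataclass(frozen=True)
class CellTuningSpec:
    """Gaussian spatial tuning of one simulated pyramidal cell."""

    field_centre_cm: float
    field_sd_cm: float = 8.0
    peak_rate_hz: float = 5.0
    direction: str = "both"  # 'left', 'right' or 'both'
    baseline_rate_hz: float = 0.0

    def __post_init__(self):
        if not self.peak_rate_hz >= self.baseline_rate_hz >= 0:
            raise ValueError("need peak_rate_hz >= baseline_rate_hz >= 0")
        if self.direction not in ("left", "right", "both"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class SessionPairSpec:
    """Across-session mixture and rate modulation for a session pair."""

    p_stable: float = 0.5
    p_remap: float = 0.3
    p_lost: float = 0.2
    shift_sd_bins: float = 0.5
    opto_gain: float = 1.0
    novelty_gain: float = 1.0

    def __post_init__(self):
        if abs(self.p_stable + self.p_remap + self.p_lost - 1.0) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")
        if self.opto_gain <= 0 or self.novelty_gain <= 0:
            raise ValueError("gains must be positive")


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def simulate_trajectory(
    cfg: TrackConfig,
    n_laps: int,
    mean_speed: float = 15.0,
    pause_s: float = 1.0,
    seed: int = 0,
    speed_noise_frac: float = 0.1,
    lap_speed_spread: float = 0.3,
) -> Trajectory:
    """End-to-end traversals with reward-zone dwell pauses.

    One lap is one full traversal. Each lap draws a target speed uniformly
    within ``±lap_speed_spread`` of ``mean_speed`` (mice vary their pace
    lap to lap; this variability also keeps lap durations incommensurate,
    which the circular-shift null relies on), with additional per-frame
    Gaussian noise of sd ``speed_noise_frac`` × mean, floored at 10% of the
    mean so motion stays monotone within a lap. Pauses hold position at the
    track end for ``pause_s`` seconds.
    """
    if n_laps < 1:
        raise ValueError("n_laps must be >= 1")
    if mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    if pause_s < 0:
        raise ValueError("pause_s must be nonnegative")
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.frame_rate_hz
    n_pause = int(round(pause_s * cfg.frame_rate_hz))
    L = cfg.track_length_cm

    xs, laps, dirs = [0.0], [0], [RIGHT]
    pos, d, lap = 0.0, RIGHT, 0
    lap_speed = mean_speed * rng.uniform(1 - lap_speed_spread, 1 + lap_speed_spread)
    while lap < n_laps:
        speed = max(0.1 * mean_speed, rng.normal(lap_speed, speed_noise_frac * mean_speed))
        pos = pos + d * speed * dt
        if pos >= L or pos <= 0.0:
            pos = L if d == RIGHT else 0.0
            xs.append(pos), laps.append(lap), dirs.append(d)
            for _ in range(n_pause):
                xs.append(pos), laps.append(lap), dirs.append(d)
            d = -d
            lap += 1
            lap_speed = mean_speed * rng.uniform(1 - lap_speed_spread, 1 + lap_speed_spread)
        else:
            xs.append(pos), laps.append(lap), dirs.append(d)
    x = np.asarray(xs)
    t = np.arange(x.size) * dt
    v = compute_velocity(t, x, window_s=2.0)
    return Trajectory(
        t=t, x=x, v=v,
        lap=np.asarray(laps, dtype=int),
        direction=np.asarray(dirs, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# pyramidal cell events
# ---------------------------------------------------------------------------

def _rate_on_samples(
    traj: Trajectory,
    spec: CellTuningSpec,
    cfg: TrackConfig,
    novelty_gain: float,
    opto_gain: float,
) -> np.ndarray:
    """Inhomogeneous Poisson rate λ(t) on the trajectory samples."""
    tuned = spec.baseline_rate_hz + (spec.peak_rate_hz - spec.baseline_rate_hz) * np.exp(
        -((traj.x - spec.field_centre_cm) ** 2) / (2.0 * spec.field_sd_cm**2)
    )
    if spec.direction != "both":
        lam = np.where(traj.direction == direction_code(spec.direction), tuned, spec.baseline_rate_hz)
    else:
        lam = tuned
    lam = lam * novelty_gain
    if opto_gain != 1.0 and cfg.opto_zone is not None:
        for dname in ("left", "right"):
            lo, hi = cfg.zone_interval("opto", dname)
            inzone = (traj.direction == direction_code(dname)) & (traj.x >= lo) & (traj.x < hi)
            lam = np.where(inzone, lam * opto_gain, lam)
    return lam


def simulate_place_cell_events(
    traj: Trajectory,
    specs: list[CellTuningSpec],
    cfg: TrackConfig,
    seed: int = 0,
    novelty_gain: float = 1.0,
    opto_gain: float = 1.0,
    cell_ids: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw deconvolved event trains for each tuning spec.

    Events are per-frame Poisson counts of the gated, modulated rate; event
    times sit on the behaviour frame grid and amplitudes are Gamma(2, 0.5)
    distributed (amplitudes are ignored by the rate-map analysis).

    Returns the long-format event table and a ground-truth table.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    dt = traj.dt
    if cell_ids is None:
        cell_ids = list(range(len(specs)))
    rows, truth = [], []
    for cid, spec in zip(cell_ids, specs):
        lam = _rate_on_samples(traj, spec, cfg, novelty_gain, opto_gain)
        counts = rng.poisson(lam * dt)
        idx = np.repeat(np.arange(traj.n_samples), counts)
        amps = rng.gamma(2.0, 0.5, size=idx.size)
        for i, a in zip(idx, amps):
            rows.append((cid, traj.t[i], a))
        truth.append(
            dict(
                cell_id=cid,
                centre_cm=spec.field_centre_cm,
                field_sd_cm=spec.field_sd_cm,
                peak_rate_hz=spec.peak_rate_hz,
                baseline_rate_hz=spec.baseline_rate_hz,
                direction=spec.direction,
            )
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# session pairs with a stability mixture
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSession:
    traj: Trajectory
    events: pd.DataFrame
    truth: pd.DataFrame
    cfg: TrackConfig


@dataclass
class SessionPair:
    session1: SyntheticSession
    session2: SyntheticSession
    truth: pd.DataFrame  # per-cell: class, centre1_cm, centre2_cm, direction


def random_tuning_specs(
    cfg: TrackConfig,
    n_cells: int,
    rng: np.random.Generator,
    peak_rate_hz=5.0,
    field_sd_cm: float = 8.0,
    baseline_rate_hz: float = 0.05,
    margin_cm: float = 5.0,
) -> list[CellTuningSpec]:
    """Tuned cells with centres uniform over the analysed region.

    ``peak_rate_hz`` may be a scalar or a (lo, hi) range sampled log-uniformly.
    """
    lo, hi = cfg.analysed_start + margin_cm, cfg.analysed_stop - margin_cm
    specs = []
    for _ in range(n_cells):
        centre = rng.uniform(lo, hi)
        if np.iterable(peak_rate_hz):
            a, b = peak_rate_hz
            peak = float(np.exp(rng.uniform(np.log(a), np.log(b))))
        else:
            peak = float(peak_rate_hz)
        direction = "right" if rng.random() < 0.5 else "left"
        specs.append(
            CellTuningSpec(
                field_centre_cm=centre,
                field_sd_cm=field_sd_cm,
                peak_rate_hz=peak,
                direction=direction,
                baseline_rate_hz=min(baseline_rate_hz, peak),
            )
        )
    return specs


def derive_session2_specs(
    specs: list[CellTuningSpec],
    pair: SessionPairSpec,
    cfg: TrackConfig,
    rng: np.random.Generator,
    margin_cm: float = 5.0,
) -> tuple[list[CellTuningSpec], list[str]]:
    """Second-session tuning according to the stability mixture.

    Stable cells keep their centre up to Gaussian jitter of
    ``shift_sd_bins`` bins; remapped cells draw a new centre uniformly over
    the analysed region excluding ±2 bins around the original; lost cells
    fall silent.
    """
    bw = cfg.bin_width_cm
    lo, hi = cfg.analysed_start + margin_cm, cfg.analysed_stop - margin_cm
    classes = rng.choice(
        ["stable", "remapped", "lost"],
        size=len(specs),
        p=[pair.p_stable, pair.p_remap, pair.p_lost],
    )
    out = []
    for spec, cls in zip(specs, classes):
        if cls == "lost":
            out.append(
                CellTuningSpec(
                    field_centre_cm=spec.field_centre_cm,
                    field_sd_cm=spec.field_sd_cm,
                    peak_rate_hz=0.0,
                    direction=spec.direction,
                    baseline_rate_hz=0.0,
                )
            )
        elif cls == "stable":
            centre = spec.field_centre_cm + rng.normal(0.0, pair.shift_sd_bins * bw)
            centre = float(np.clip(centre, lo, hi))
            out.append(
                CellTuningSpec(
                    field_centre_cm=centre,
                    field_sd_cm=spec.field_sd_cm,
                    peak_rate_hz=spec.peak_rate_hz,
                    direction=spec.direction,
                    baseline_rate_hz=spec.baseline_rate_hz,
                )
            )
        else:  # remapped
            while True:
                centre = float(rng.uniform(lo, hi))
                if abs(centre - spec.field_centre_cm) > 2.0 * bw:
                    break
            out.append(
                CellTuningSpec(
                    field_centre_cm=centre,
                    field_sd_cm=spec.field_sd_cm,
                    peak_rate_hz=spec.peak_rate_hz,
                    direction=spec.direction,
                    baseline_rate_hz=spec.baseline_rate_hz,
                )
            )
    return out, list(classes)


def simulate_session_pair(
    cfg: TrackConfig,
    specs: list[CellTuningSpec],
    pair: SessionPairSpec,
    n_laps: int = 20,
    mean_speed: float = 15.0,
    pause_s: float = 1.0,
    seed: int = 0,
    opto_gain_session2: float = 1.0,
) -> SessionPair:
    """Two sessions from the same cells under the stability mixture.

    ``pair.opto_gain`` modulates the optogenetic zone in session 1 (the
    manipulation session); session 2 uses ``opto_gain_session2``.
    ``pair.novelty_gain`` multiplies all rates in both sessions.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=5)
    traj1 = simulate_trajectory(cfg, n_laps, mean_speed, pause_s, seed=int(sub[0]))
    traj2 = simulate_trajectory(cfg, n_laps, mean_speed, pause_s, seed=int(sub[1]))
    specs2, classes = derive_session2_specs(specs, pair, cfg, rng)
    ev1, t1 = simulate_place_cell_events(
        traj1, specs, cfg, seed=int(sub[2]),
        novelty_gain=pair.novelty_gain, opto_gain=pair.opto_gain,
    )
    ev2, t2 = simulate_place_cell_events(
        traj2, specs2, cfg, seed=int(sub[3]),
        novelty_gain=pair.novelty_gain, opto_gain=opto_gain_session2,
    )
    truth = pd.DataFrame(
        dict(
            cell_id=t1["cell_id"],
            stability_class=classes,
            centre1_cm=t1["centre_cm"],
            centre2_cm=t2["centre_cm"],
            direction=t1["direction"],
            peak_rate_hz=t1["peak_rate_hz"],
        )
    )
    s1 = SyntheticSession(traj=traj1, events=ev1, truth=t1, cfg=cfg)
    s2 = SyntheticSession(traj=traj2, events=ev2, truth=t2, cfg=cfg)
    return SessionPair(session1=s1, session2=s2, truth=truth)


# ---------------------------------------------------------------------------
# fluorescence forward models
# ---------------------------------------------------------------------------

def simulate_fluorescence(
    events: pd.DataFrame,
    t: np.ndarray,
    cell_ids: list,
    kernel_rise_s: float = 0.1,
    kernel_decay_s: float = 0.6,
    baseline_f: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> np.ndarray:
    """Traces = baseline + Σ amplitude × double-exponential kernel + noise.

    The kernel ``exp(-Δt/τ_decay) − exp(-Δt/τ_rise)`` is normalised to unit
    peak so event amplitudes are in trace units.
    """
    if not kernel_decay_s > kernel_rise_s > 0:
        raise ValueError("need kernel_decay_s > kernel_rise_s > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.asarray(t, dtype=float)
    tau_d, tau_r = kernel_decay_s, kernel_rise_s
    t_peak = tau_d * tau_r / (tau_d - tau_r) * np.log(tau_d / tau_r)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    F = np.full((len(cell_ids), t.size), float(baseline_f))
    for i, cid in enumerate(cell_ids):
        sub = events[events["cell_id"] == cid]
        for te, amp in zip(sub["t_s"].to_numpy(), sub["amplitude"].to_numpy()):
            dt_ = t - te
            m = dt_ >= 0
            F[i, m] += amp / peak * (np.exp(-dt_[m] / tau_d) - np.exp(-dt_[m] / tau_r))
    if noise_sd > 0:
        F += rng.normal(0.0, noise_sd, size=F.shape)
    return F


@dataclass
class OlmTraces:
    """Velocity-coupled interneuron ΔF/F-like traces with true gains."""

    t: np.ndarray
    dff: np.ndarray  # (n_cells, n_samples)
    gains: np.ndarray  # true per-cell gain (ΔF/F per cm/s)
    novelty_factor: float


def simulate_olm_traces(
    traj: Trajectory,
    gain_per_cm_s: float = 0.01,
    novelty_factor: float = 1.0,
    noise_sd: float = 0.01,
    n_cells: int = 8,
    seed: int = 0,
    gain_spread: float = 0.2,
) -> OlmTraces:
    """Interneuron activity ∝ running speed, suppressed by novelty.

    E[ΔF/F] = gain_i × v(t) × novelty_factor, with per-cell gains log-normal
    around ``gain_per_cm_s`` (σ = ``gain_spread`` in log space) plus white
    noise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 < novelty_factor <= 1:
        raise ValueError("novelty_factor must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    gains = gain_per_cm_s * np.exp(rng.normal(0.0, gain_spread, size=n_cells))
    dff = gains[:, None] * traj.v[None, :] * novelty_factor
    if noise_sd > 0:
        dff = dff + rng.normal(0.0, noise_sd, size=dff.shape)
    return OlmTraces(t=traj.t, dff=dff, gains=gains, novelty_factor=novelty_factor)


# ---------------------------------------------------------------------------
# spatial footprints
# ---------------------------------------------------------------------------

@dataclass
class FootprintStack:
    """Per-cell nonnegative weight images on a common field of view."""

    images: np.ndarray  # (n_cells, H, W)
    cell_ids: list

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_cells, H, W)")
        if len(self.cell_ids) != self.images.shape[0]:
            raise ValueError("cell_ids length mismatch")

    @property
    def fov(self) -> np.ndarray:
        return self.images.sum(axis=0)


def _render_blobs(centres: np.ndarray, fov_shape, sigma: float) -> np.ndarray:
    H, W = fov_shape
    yy, xx = np.mgrid[0:H, 0:W]
    imgs = np.empty((centres.shape[0], H, W))
    for i, (cy, cx) in enumerate(centres):
        imgs[i] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        imgs[i][imgs[i] < 1e-6] = 0.0
    return imgs


def simulate_footprints(
    n_cells: int,
    fov_shape=(128, 128),
    shift_px=(0.0, 0.0),
    rotation_deg: float = 0.0,
    jitter_px: float = 0.0,
    drop_fraction: float = 0.0,
    seed: int = 0,
    blob_sigma: float = 2.0,
) -> tuple[FootprintStack, FootprintStack, list[tuple[int, int]]]:
    """A footprint stack and its rigidly transformed counterpart.

    Stack B is stack A rotated by ``rotation_deg`` about the FOV centre then
    shifted by ``shift_px`` = (dy, dx), with per-cell Gaussian centroid
    jitter and ``round(drop_fraction × n_cells)`` cells removed. Blob
    centroids are rejection-sampled with a minimum separation of twice the
    blob radius (radius = 3σ). Returns (A, B, true_matching) where the
    matching maps A indices to B indices.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    H, W = fov_shape
    radius = 3.0 * blob_sigma
    min_sep = 2.0 * radius
    margin = radius + max(abs(shift_px[0]), abs(shift_px[1])) + 0.15 * max(H, W) * abs(
        np.sin(np.deg2rad(rotation_deg))
    ) + 2.0
    centres = []
    tries = 0
    while len(centres) < n_cells:
        tries += 1
        if tries > 20000:
            raise RuntimeError("cannot place footprints: field of view overcrowded")
        c = rng.uniform([margin, margin], [H - margin, W - margin])
        if all(np.hypot(c[0] - p[0], c[1] - p[1]) >= min_sep for p in centres):
            centres.append(c)
    centres = np.asarray(centres)

    theta = np.deg2rad(rotation_deg)
    Rm = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    ctr = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    centres_b = (centres - ctr) @ Rm.T + ctr + np.asarray(shift_px, dtype=float)
    if jitter_px > 0:
        centres_b = centres_b + rng.normal(0.0, jitter_px, size=centres_b.shape)

    n_drop = int(round(drop_fraction * n_cells))
    dropped = set(rng.choice(n_cells, size=n_drop, replace=False).tolist()) if n_drop else set()
    keep = [i for i in range(n_cells) if i not in dropped]

    stack_a = FootprintStack(_render_blobs(centres, fov_shape, blob_sigma), list(range(n_cells)))
    stack_b = FootprintStack(
        _render_blobs(centres_b[keep], fov_shape, blob_sigma), list(range(len(keep)))
    )
    matching = [(i, j) for j, i in enumerate(keep)]
    return stack_a, stack_b, matching
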