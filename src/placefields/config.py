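"""Track geometry and session configuration.

All positions are in cm measured from the left end of the track. The analysed
region excludes a reward zone at each end; spatial bins tile the analysed
region with half-open intervals ``[lo, hi)`` except the final bin, which is
closed. With the default 140 cm track, 15 cm reward zones and 40 bins the bin
width is 2.75 cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

#: Direction codes used throughout: +1 = rightward traversal, -1 = leftward.
RIGHT = 1
LEFT = -1

_DIR_CODE = {"right": RIGHT, "left": LEFT, RIGHT: RIGHT, LEFT: LEFT}
_DIR_NAME = {RIGHT: "right", LEFT: "left"}


def direction_code(direction) -> int:
    """Normalise 'left'/'right' (or ±1) to the internal ±1 code."""
    try:
        return _DIR_CODE[direction]
    except KeyError:
        raise ValueError(f"unknown direction {direction!r}") from None


def direction_name(code: int) -> str:
    return _DIR_NAME[int(code)]


def _normalise_zone(zone) -> dict[str, tuple[float, float]] | None:
    """Zones may be a single (lo, hi) interval or a per-direction mapping.

    Per-direction intervals support staggered optogenetic zones that
    compensate a fixed tracking latency on each lap direction.
    """
    if zone is None:
        return None
    if isinstance(zone, Mapping):
        out = {}
        for key, iv in zone.items():
            name = direction_name(direction_code(key))
            lo, hi = float(iv[0]), float(iv[1])
            if not hi > lo:
                raise ValueError(f"zone interval {iv} is empty")
            out[name] = (lo, hi)
        if set(out) != {"left", "right"}:
            raise ValueError("per-direction zone must define both directions")
        return out
    lo, hi = float(zone[0]), float(zone[1])
    if not hi > lo:
        raise ValueError(f"zone interval {zone} is empty")
    return {"left": (lo, hi), "right": (lo, hi)}


@dataclass(frozen=True)
class TrackConfig:
    """Geometry and acquisition parameters of a linear-track session.

    Parameters
    ----------
    track_length_cm:
        Full track length, reward zone to reward zone.
    reward_zone_cm:
        Length excluded from spatial analysis at *each* end of the track.
    n_bins:
        Number of spatial bins tiling the analysed region.
    opto_zone, control_zone:
        Optional (lo, hi) intervals in cm, or per-direction mappings
        ``{"left": (lo, hi), "right": (lo, hi)}``.
    frame_rate_hz:
        Imaging frame rate; behaviour is resampled onto this grid.
    """

    track_length_cm: float = 140.0
    reward_zone_cm: float = 15.0
    n_bins: int = 40
    opto_zone: object = None
    control_zone: object = None
    frame_rate_hz: float = 10.0

    def __post_init__(self):
        if self.track_length_cm - 2 * self.reward_zone_cm <= 0:
            raise ValueError("reward zones cover the whole track")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        object.__setattr__(self, "opto_zone", _normalise_zone(self.opto_zone))
        object.__setattr__(self, "control_zone", _normalise_zone(self.control_zone))
        for zone in (self.opto_zone, self.control_zone):
            if zone is None:
                continue
            for lo, hi in zone.values():
                if lo < self.analysed_start - 1e-9 or hi > self.analysed_stop + 1e-9:
                    raise ValueError("zone lies outside the analysed region")

    # -- geometry -----------------------------------------------------------
    @property
    def analysed_start(self) -> float:
        return self.reward_zone_cm

    @property
    def analysed_stop(self) -> float:
        return self.track_length_cm - self.reward_zone_cm

    @property
    def bin_width_cm(self) -> float:
        return (self.track_length_cm - 2 * self.reward_zone_cm) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.analysed_start, self.analysed_stop, self.n_bins + 1)

    @property
    def bin_centres(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])

    def bin_of(self, x: np.ndarray) -> np.ndarray:
        """Spatial bin index per position; -1 outside the analysed region."""
        x = np.asarray(x, dtype=float)
        idx = np.floor((x - self.analysed_start) / self.bin_width_cm).astype(int)
        # the final bin is closed at the right edge
        idx[np.isclose(x, self.analysed_stop)] = self.n_bins - 1
        idx[(x < self.analysed_start) | (x > self.analysed_stop)] = -1
        idx[idx >= self.n_bins] = -1
        return idx

    def zone_interval(self, zone: str, direction="right") -> tuple[float, float]:
        """(lo, hi) of a named zone ('opto' or 'control') for a direction."""
        z = {"opto": self.opto_zone, "control": self.control_zone}[zone]
        if z is None:
            raise ValueError(f"{zone} zone is not configured")
        return z[direction_name(direction_code(direction))]

    def zone_bins(self, zone: str, direction="right") -> np.ndarray:
        """Indices of bins whose centres fall inside the named zone."""
        lo, hi = self.zone_interval(zone, direction)
        c = self.bin_centres
        return np.flatnonzero((c >= lo) & (c < hi))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrackConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TrackConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class AnalysisParams:
    """Every numeric analysis constant, named and overridable.

    Defaults are the values used throughout the in vivo analysis: a 7 cm/s
    running threshold sustained over at least 10 cm, 2 s velocity smoothing,
    a 10 s / 1st-percentile ΔF/F baseline, σ = 1.5 bins of rate-map
    smoothing, 1000 circular-shift shuffles at α = 0.05, the 75% field
    threshold, a 2-bin stability tolerance, 0.5 correlation thresholds for
    stability categories and footprint matching, 30% event thinning, and QC
    cutoffs of SNR 10 and 0.005 Hz.
    """

    run_threshold_cms: float = 7.0
    run_min_distance_cm: float = 10.0
    velocity_window_s: float = 2.0
    dff_window_s: float = 10.0
    dff_percentile: float = 1.0
    sigma_bins: float = 1.5
    n_shuffles: int = 1000
    alpha: float = 0.05
    field_threshold: float = 0.75
    retention_tol_bins: int = 2
    stability_r_threshold: float = 0.5
    ncc_threshold: float = 0.5
    thin_fraction: float = 0.30
    snr_min: float = 10.0
    rate_min_hz: float = 0.005

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisParams":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})
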