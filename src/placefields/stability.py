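"""Across-session stability and remapping statistics.

Per-cell spatial correlations (with Fisher transformation for group tests),
place-field shifts, retention classes, stable/unstable categories, and the
population-vector correlation matrix with zone scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .config import TrackConfig
from .placecells import RateMap

_R_CLIP = 1.0 - 1e-6


def fisher_z(r: float) -> float:
    """atanh of the correlation, clipped to ±(1 − 1e-6) so r = ±1 maps stay finite."""
    return float(np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP)))


@dataclass
class SpatialCorrelation:
    r: float | None
    z: float | None
    excluded: bool
    reason: str = ""


def spatial_correlation(map1: RateMap, map2: RateMap) -> SpatialCorrelation:
    """Pearson correlation between a cell's maps in two sessions.

    Computed over bins occupied in both sessions. Excluded — not scored
    zero — when the session-2 activity is entirely zero, or when either map
    is constant over the shared bins (undefined correlation).
    """
    if map1.n_bins != map2.n_bins:
        raise ValueError("maps must share the bin grid")
    both = map1.valid & map2.valid
    if both.sum() < 2:
        return SpatialCorrelation(None, None, True, "insufficient shared occupancy")
    a = map1.r_smooth[both]
    b = map2.r_smooth[both]
    if not np.any(map2.r_smooth[map2.valid] > 0):
        return SpatialCorrelation(None, None, True, "session-2 activity is zero")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return SpatialCorrelation(None, None, True, "constant map")
    r, _ = pearsonr(a, b)
    return SpatialCorrelation(float(r), fisher_z(float(r)), False)


def field_shift(centre1_bin: int, centre2_bin: int, cfg: TrackConfig) -> tuple[int, float]:
    """Signed place-field shift (session 2 − session 1) in bins and cm."""
    shift_bins = int(centre2_bin) - int(centre1_bin)
    return shift_bins, shift_bins * cfg.bin_width_cm


def classify_retention(
    is_place_cell_2: bool, shift_bins: int | None, tol_bins: int = 2
) -> str:
    """Retention class of a session-1 place cell.

    'lost' if no longer a place cell; among retained cells, 'stable' if the
    field centres are within ``tol_bins`` bins (inclusive), 'remapped' if
    more than ``tol_bins`` bins apart.
    """
    if not is_place_cell_2:
        return "lost"
    if shift_bins is None:
        return "lost"
    return "stable" if abs(shift_bins) <= tol_bins else "remapped"


def categorize_stability(spatial_r: float | None, threshold: float = 0.5) -> str | None:
    """'stable' iff the spatial correlation is ≥ threshold (inclusive)."""
    if spatial_r is None:
        return None
    return "stable" if spatial_r >= threshold else "unstable"


# ---------------------------------------------------------------------------
# population vectors
# ---------------------------------------------------------------------------

def pv_matrix(maps1: np.ndarray, maps2: np.ndarray) -> np.ndarray:
    """Population-vector correlation matrix between two sessions.

    ``maps1`` and ``maps2`` are (n_cells, n_bins) activity matrices for the
    same cells. Entry (i, j) is the Pearson correlation across cells between
    the session-1 population vector at bin i and the session-2 vector at
    bin j. Entries where either vector is constant (or contains NaN cells)
    are NaN.
    """
    maps1 = np.asarray(maps1, dtype=float)
    maps2 = np.asarray(maps2, dtype=float)
    if maps1.shape[0] != maps2.shape[0]:
        raise ValueError("sessions must contain the same cells")
    if maps1.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    n1, n2 = maps1.shape[1], maps2.shape[1]
    out = np.full((n1, n2), np.nan)
    for i in range(n1):
        a = maps1[:, i]
        if not np.all(np.isfinite(a)) or np.ptp(a) == 0:
            continue
        for j in range(n2):
            b = maps2[:, j]
            if not np.all(np.isfinite(b)) or np.ptp(b) == 0:
                continue
            out[i, j] = pearsonr(a, b)[0]
    return out


def zone_pv_score(matrix: np.ndarray, zone_bins: np.ndarray) -> float:
    """Mean of the matrix diagonal over a zone's bins (NaNs excluded)."""
    zone_bins = np.asarray(zone_bins, dtype=int)
    if zone_bins.size == 0:
        raise ValueError("zone has no bins")
    diag = np.diagonal(matrix)[zone_bins]
    if np.all(np.isnan(diag)):
        raise ValueError("all diagonal entries in zone are undefined")
    return float(np.nanmean(diag))


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Per-cell stability table plus population-vector summaries."""

    table: pd.DataFrame
    pv: np.ndarray | None = None
    zone_scores: dict = field(default_factory=dict)


def build_stability_table(
    cells: list,
    maps1: dict,
    maps2: dict,
    pc2_status: dict,
    centres1: dict,
    centres2: dict,
    cfg: TrackConfig,
    tol_bins: int = 2,
    r_threshold: float = 0.5,
) -> pd.DataFrame:
    """Assemble the per-cell stability table for session-1 place cells.

    ``cells`` are session-1 place-cell ids; dictionaries map cell id to the
    session-1 retained map / field centre and the same cell's session-2 map,
    place-cell status and centre (None when undetected).
    """
    rows = []
    for cid in cells:
        m1, m2 = maps1[cid], maps2.get(cid)
        sc = (
            spatial_correlation(m1, m2)
            if m2 is not None
            else SpatialCorrelation(None, None, True, "no session-2 map")
        )
        c1 = centres1[cid]
        c2 = centres2.get(cid)
        if c2 is not None and pc2_status.get(cid, False):
            shift_bins, shift_cm = field_shift(c1, c2, cfg)
        else:
            shift_bins = shift_cm = None
        retention = classify_retention(pc2_status.get(cid, False), shift_bins, tol_bins)
        rows.append(
            dict(
                cell_id=cid,
                spatial_r=sc.r,
                fisher_z=sc.z,
                corr_excluded=sc.excluded,
                shift_bins=shift_bins,
                shift_cm=shift_cm,
                retention=retention,
                category=categorize_stability(sc.r, r_threshold),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "spatial_r", "fisher_z", "corr_excluded",
            "shift_bins", "shift_cm", "retention", "category",
        ],
    )
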