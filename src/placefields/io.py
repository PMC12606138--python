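"""Session container I/O.

A session lives in a directory: behaviour table (CSV), events table (CSV),
optional traces (HDF5) and footprints (TIFF stack), configuration (YAML) and
an optional ground-truth table plus a provenance block (JSON). Tables are
human-inspectable; arrays are binary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AnalysisParams, TrackConfig
from .signals import Trajectory, TraceSet, make_trajectory
from .synth import EVENT_COLUMNS, FootprintStack


class SessionLoadError(ValueError):
    """Schema or invariant violation while loading a session."""


@dataclass
class SessionContainer:
    """On-disk session: behaviour, events, optional traces and footprints."""

    behaviour: pd.DataFrame  # t_s, x_cm[, lap, direction]
    events: pd.DataFrame  # cell_id, t_s, amplitude
    cfg: TrackConfig
    traces: TraceSet | None = None
    footprints: FootprintStack | None = None
    ground_truth: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def trajectory(self, params: AnalysisParams | None = None) -> Trajectory:
        params = params or AnalysisParams()
        beh = self.behaviour
        lap = beh["lap"].to_numpy() if "lap" in beh else None
        direction = beh["direction"].to_numpy() if "direction" in beh else None
        return make_trajectory(
            beh["t_s"].to_numpy(),
            beh["x_cm"].to_numpy(),
            self.cfg,
            lap=lap,
            direction=direction,
            velocity_window_s=params.velocity_window_s,
        )


def resample_behaviour(behaviour: pd.DataFrame, target_t: np.ndarray) -> pd.DataFrame:
    """Nearest-timestamp resampling of the behaviour table onto a time grid.

    Used to bring 30 fps tracking onto the 10 Hz imaging grid.
    """
    t = behaviour["t_s"].to_numpy()
    idx = np.searchsorted(t, target_t)
    idx = np.clip(idx, 1, t.size - 1)
    left = target_t - t[idx - 1] <= t[idx] - target_t
    idx[left] -= 1
    out = behaviour.iloc[idx].copy()
    out["t_s"] = target_t
    return out.reset_index(drop=True)


def write_session(session: SessionContainer, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.behaviour.to_csv(path / "behaviour.csv", index=False)
    session.events.to_csv(path / "events.csv", index=False)
    session.cfg.to_yaml(path / "config.yaml")
    if session.ground_truth is not None:
        session.ground_truth.to_csv(path / "ground_truth.csv", index=False)
    if session.traces is not None:
        with h5py.File(path / "traces.h5", "w") as fh:
            fh.create_dataset("t", data=session.traces.t)
            fh.create_dataset("F", data=session.traces.F)
            fh.create_dataset(
                "cell_ids", data=np.asarray([str(c) for c in session.traces.cell_ids], dtype="S")
            )
    if session.footprints is not None:
        tifffile.imwrite(
            path / "footprints.tif",
            session.footprints.images.astype(np.float32),
            photometric="minisblack",
        )
        (path / "footprint_ids.json").write_text(
            json.dumps([str(c) for c in session.footprints.cell_ids])
        )
    prov = dict(session.provenance)
    prov.setdefault("package_version", __version__)
    (path / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return path


def read_session(path, cfg: TrackConfig | None = None) -> SessionContainer:
    """Load and validate a session directory.

    Checks: strictly increasing behaviour time, positions within the track,
    event times within the behaviour range, event cell ids known to the
    traces when traces are present.
    """
    path = Path(path)
    try:
        behaviour = pd.read_csv(path / "behaviour.csv")
        events = pd.read_csv(path / "events.csv")
    except FileNotFoundError as exc:
        raise SessionLoadError(f"missing session file: {exc.filename}") from exc
    if cfg is None:
        cfg_path = path / "config.yaml"
        if not cfg_path.exists():
            raise SessionLoadError("no config.yaml and no cfg given")
        cfg = TrackConfig.from_yaml(cfg_path)

    for col in ("t_s", "x_cm"):
        if col not in behaviour:
            raise SessionLoadError(f"behaviour.csv lacks column {col!r}")
    t = behaviour["t_s"].to_numpy()
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
        raise SessionLoadError(f"behaviour t_s not strictly increasing at row {row}")
    x = behaviour["x_cm"].to_numpy()
    bad = (x < -1e-6) | (x > cfg.track_length_cm + 1e-6)
    if bad.any():
        raise SessionLoadError(
            f"behaviour x_cm outside track at row {int(np.flatnonzero(bad)[0])}"
        )
    for col in EVENT_COLUMNS:
        if col not in events:
            raise SessionLoadError(f"events.csv lacks column {col!r}")
    if len(events):
        et = events["t_s"].to_numpy()
        if et.min() < t[0] - 1e-6 or et.max() > t[-1] + 1e-6:
            raise SessionLoadError("event times outside the behaviour time range")

    traces = None
    if (path / "traces.h5").exists():
        with h5py.File(path / "traces.h5", "r") as fh:
            traces = TraceSet(
                t=fh["t"][:],
                F=fh["F"][:],
                cell_ids=[c.decode() for c in fh["cell_ids"][:]],
            )
        known = set(traces.cell_ids)
        unknown = {str(c) for c in events["cell_id"].unique()} - known
        if unknown:
            raise SessionLoadError(f"events reference unknown cell_id(s): {sorted(unknown)}")
        if traces.t.size != t.size or not np.allclose(traces.t, t):
            behaviour = resample_behaviour(behaviour, traces.t)

    footprints = None
    if (path / "footprints.tif").exists():
        imgs = tifffile.imread(path / "footprints.tif")
        ids_path = path / "footprint_ids.json"
        ids = (
            json.loads(ids_path.read_text())
            if ids_path.exists()
            else list(range(imgs.shape[0]))
        )
        footprints = FootprintStack(images=np.atleast_3d(imgs), cell_ids=ids)

    ground_truth = None
    if (path / "ground_truth.csv").exists():
        ground_truth = pd.read_csv(path / "ground_truth.csv")
    provenance = {}
    if (path / "provenance.json").exists():
        provenance = json.loads((path / "provenance.json").read_text())
    return SessionContainer(
        behaviour=behaviour,
        events=events,
        cfg=cfg,
        traces=traces,
        footprints=footprints,
        ground_truth=ground_truth,
        provenance=provenance,
    )


def write_results(path, tables: dict, summary: dict | None = None, matrices: dict | None = None) -> Path:
    """Write analysis outputs: CSV tables, a JSON summary, HDF5 matrices.

    Column order is preserved as given, so identical inputs produce
    byte-identical CSVs.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.csv", index=False)
    if summary is not None:
        (path / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if matrices:
        with h5py.File(path / "matrices.h5", "w") as fh:
            for name, arr in matrices.items():
                fh.create_dataset(name, data=np.asarray(arr))
    return path
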