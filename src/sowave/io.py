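"""Data model and file I/O for multichannel LFP recordings.

Recordings are stored in a single HDF5 container: ``/lfp`` holds the
channels x samples array (float32, microvolts) with attributes ``fs`` (Hz),
``t0`` (s) and free-form metadata; ``/geometry`` holds per-channel (x, y)
electrode positions in millimetres.  Electrode geometry can also be read
from a plain CSV with columns ``channel,x,y``.

Units are fixed package-wide: microvolts, seconds, millimetres, hertz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ElectrodeGeometry",
    "FormatError",
    "load_recording",
    "save_recording",
    "load_geometry",
    "save_geometry",
    "linear_geometry",
    "grid_geometry",
]


class FormatError(ValueError):
    """Raised when a container file is missing required fields."""


@dataclass
class ElectrodeGeometry:
    """Electrode positions in mm.

    ``layout`` is ``"linear"`` (depth probe, all x equal) or ``"grid"``
    (surface array).  ``spacing`` is the nominal inter-electrode distance.
    """

    positions: np.ndarray  # (n_channels, 2), mm
    spacing: float  # mm
    layout: str  # "linear" | "grid"
    channel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n_channels, 2)")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(len(self.positions))]
        if len(self.channel_ids) != len(self.positions):
            raise ValueError("one position per channel required")
        uniq = {tuple(p) for p in np.round(self.positions, 9)}
        if len(uniq) != len(self.positions):
            raise ValueError("electrode positions must be unique")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.layout not in ("linear", "grid"):
            raise ValueError(f"unknown layout {self.layout!r}")

    @property
    def n_channels(self) -> int:
        return len(self.positions)


def linear_geometry(n_channels: int = 16, spacing: float = 0.1) -> ElectrodeGeometry:
    """Linear depth probe: x = 0, y = depth (mm). Default 16 ch at 100 um."""
    pos = np.column_stack([np.zeros(n_channels), np.arange(n_channels) * spacing])
    return ElectrodeGeometry(pos, spacing, "linear")


def grid_geometry(n_cols: int = 8, n_rows: int = 4, spacing: float = 0.55) -> ElectrodeGeometry:
    """Rectangular surface grid. Default 32 ch (8 x 4) at 550 um."""
    xs, ys = np.meshgrid(np.arange(n_cols) * spacing, np.arange(n_rows) * spacing)
    pos = np.column_stack([xs.ravel(), ys.ravel()])
    return ElectrodeGeometry(pos, spacing, "grid")


@dataclass
class Recording:
    """A multichannel extracellular recording.

    signals: (n_channels, n_samples) array, microvolts.
    fs: sampling rate, Hz.  channel_ids: ordered labels.  t0: start time, s.
    metadata: free-form (animal id, group WT|WBS, condition ...).
    geometry: optional electrode layout.
    """

    signals: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    t0: float = 0.0
    metadata: dict = field(default_factory=dict)
    geometry: ElectrodeGeometry | None = None

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.signals.size == 0:
            raise ValueError("recording has no samples")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(self.signals.shape[0])]
        if len(self.channel_ids) != self.signals.shape[0]:
            raise ValueError("channel_ids must match number of signal rows")
        bad = [cid for cid, row in zip(self.channel_ids, self.signals) if np.isnan(row).any()]
        if bad:
            raise ValueError(f"NaN samples in channels: {bad}")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def save_recording(rec: Recording, path) -> None:
    """Write a Recording to an HDF5 container (see module docstring)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=rec.signals.astype(np.float32))
        d.attrs["fs"] = float(rec.fs)
        d.attrs["t0"] = float(rec.t0)
        d.attrs["channel_ids"] = json.dumps(rec.channel_ids)
        d.attrs["metadata"] = json.dumps(rec.metadata)
        if rec.geometry is not None:
            g = f.create_dataset("geometry", data=rec.geometry.positions)
            g.attrs["spacing"] = float(rec.geometry.spacing)
            g.attrs["layout"] = rec.geometry.layout
            g.attrs["channel_ids"] = json.dumps(rec.geometry.channel_ids)


def load_recording(path) -> Recording:
    """Load an HDF5 recording container written by :func:`save_recording`."""
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise FormatError("container missing /lfp dataset")
        d = f["lfp"]
        if "fs" not in d.attrs:
            raise FormatError("container missing required attribute 'fs'")
        geometry = None
        if "geometry" in f:
            g = f["geometry"]
            gids = json.loads(g.attrs.get("channel_ids", "[]"))
            geometry = ElectrodeGeometry(
                positions=np.asarray(g),
                spacing=float(g.attrs.get("spacing", 1.0)),
                layout=str(g.attrs.get("layout", "grid")),
                channel_ids=gids or [],
            )
        return Recording(
            signals=np.asarray(d),
            fs=float(d.attrs["fs"]),
            channel_ids=json.loads(d.attrs.get("channel_ids", "[]")),
            t0=float(d.attrs.get("t0", 0.0)),
            metadata=json.loads(d.attrs.get("metadata", "{}")),
            geometry=geometry,
        )


def _infer_layout(positions: np.ndarray) -> str:
    # all x equal (depth probe) -> linear
    return "linear" if np.allclose(positions[:, 0], positions[0, 0]) else "grid"


def _infer_spacing(positions: np.ndarray, layout: str) -> float:
    if layout == "linear":
        y = np.sort(positions[:, 1])
        return float(np.median(np.diff(y)))
    # nearest-neighbour distance for grids
    from scipy.spatial.distance import pdist, squareform

    dm = squareform(pdist(positions))
    np.fill_diagonal(dm, np.inf)
    return float(np.median(dm.min(axis=1)))


def load_geometry(path) -> ElectrodeGeometry:
    """Read electrode geometry from CSV with columns channel,x,y (mm)."""
    df = pd.read_csv(path)
    missing = {"channel", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"geometry CSV missing columns: {sorted(missing)}")
    if df["channel"].duplicated().any():
        dupes = df["channel"][df["channel"].duplicated()].tolist()
        raise ValueError(f"duplicate channel ids: {dupes}")
    try:
        pos = df[["x", "y"]].astype(float).to_numpy()
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-numeric coordinate in geometry CSV: {e}") from e
    layout = _infer_layout(pos)
    spacing = _infer_spacing(pos, layout)
    return ElectrodeGeometry(pos, spacing, layout, [str(c) for c in df["channel"]])


def save_geometry(geom: ElectrodeGeometry, path) -> None:
    pd.DataFrame(
        {"channel": geom.channel_ids, "x": geom.positions[:, 0], "y": geom.positions[:, 1]}
    ).to_csv(path, index=False)
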