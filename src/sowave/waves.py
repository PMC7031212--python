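"""Slow-wave reconstruction, time-lag interpolation, speed maps and pattern entropy.

Individual slow waves are reconstructed by merging Down->Up transitions that
occur on a majority of channels within a short interval, expressed as
per-channel time lags relative to the mean wave time.  Lags are interpolated
on the electrode plane with an exact (zero-smoothing) thin-plate spline
T(x, y); the local propagation speed is V(x, y) = 1 / |grad T|.  Pattern
diversity is the Shannon entropy of wave occupancy in the plane of the first
two principal components of the lag matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator

from .config import WaveConfig
from .io import ElectrodeGeometry

__all__ = [
    "WaveSet", "TimeLagField", "cluster_waves", "interpolate_timelag_field",
    "speed_map", "wave_pca_entropy",
]


@dataclass
class WaveSet:
    """Per-wave per-channel transition times and zero-mean lags (NaN = missing)."""

    times: np.ndarray       # (n_waves, n_channels) absolute transition times, s
    mean_time: np.ndarray   # (n_waves,) s
    lag_matrix: np.ndarray  # (n_waves, n_channels) s, zero mean over present channels

    @property
    def n_waves(self) -> int:
        return self.lag_matrix.shape[0]


@dataclass
class TimeLagField:
    grid_x: np.ndarray   # (ny, nx) mm
    grid_y: np.ndarray
    T: np.ndarray        # interpolated lag surface, s
    V: np.ndarray | None = None      # speed surface, mm/s
    valid_mask: np.ndarray | None = None  # interior points with usable gradient


def cluster_waves(transitions: list, n_channels: int | None = None,
                  max_span: float = 0.25,
                  min_channel_fraction: float = 0.5) -> WaveSet:
    """Merge per-channel Down->Up transitions into global waves.

    ``transitions`` is one array of transition times per channel.  Sorted
    transitions are greedily grouped: a transition joins the current wave if
    it lies within ``max_span`` of the wave's running mean and its channel is
    not yet part of it.  Waves seen on fewer than ``min_channel_fraction`` of
    channels are discarded; missing channels stay NaN (never imputed as 0).
    """
    n_channels = n_channels or len(transitions)
    events = sorted(
        (t, ch) for ch, ts in enumerate(transitions) for t in np.atleast_1d(ts))
    if sum(len(np.atleast_1d(ts)) > 0 for ts in transitions) < 2:
        raise ValueError("need transitions on at least 2 channels")
    waves: list[dict] = []
    current: dict = {}
    for t, ch in events:
        if current:
            mean = np.mean(list(current.values()))
            if abs(t - mean) <= max_span and ch not in current:
                current[ch] = t
                continue
            waves.append(current)
            current = {}
        current = {ch: t}
    if current:
        waves.append(current)

    min_n = int(np.ceil(min_channel_fraction * n_channels))
    kept = [w for w in waves if len(w) >= min_n]
    if not kept:
        warnings.warn("no wave met the channel-participation criterion")
        empty = np.empty((0, n_channels))
        return WaveSet(times=empty, mean_time=np.empty(0), lag_matrix=empty)
    times = np.full((len(kept), n_channels), np.nan)
    for k, w in enumerate(kept):
        for ch, t in w.items():
            times[k, ch] = t
    mean_time = np.nanmean(times, axis=1)
    lags = times - mean_time[:, None]
    return WaveSet(times=times, mean_time=mean_time, lag_matrix=lags)


def interpolate_timelag_field(lags: np.ndarray, geometry: ElectrodeGeometry,
                              grid_step: float = 0.05) -> TimeLagField:
    """Exact thin-plate-spline interpolation of per-channel lags on a grid.

    Missing (NaN) channels are excluded from the fit; the interpolant passes
    through every observed lag exactly (no smoothing penalty) and is
    evaluated on a regular grid spanning the array bounding box.
    """
    lags = np.asarray(lags, dtype=float)
    present = np.isfinite(lags)
    pts = geometry.positions[present]
    vals = lags[present]
    if len(pts) < 4:
        raise ValueError("insufficient support for 2D interpolation (need >= 4 electrodes)")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("insufficient support for 2D interpolation (collinear electrodes)")
    tps = RBFInterpolator(pts, vals, kernel="thin_plate_spline", smoothing=0.0, degree=1)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    gx = np.arange(x0, x1 + grid_step / 2, grid_step)
    gy = np.arange(y0, y1 + grid_step / 2, grid_step)
    grid_x, grid_y = np.meshgrid(gx, gy)
    flat = np.column_stack([grid_x.ravel(), grid_y.ravel()])
    T = tps(flat).reshape(grid_x.shape)
    return TimeLagField(grid_x=grid_x, grid_y=grid_y, T=T)


def speed_map(field: TimeLagField, speed_ceiling: float = 1e4) -> tuple[TimeLagField, float]:
    """Propagation speed V = 1/|grad T| (mm/s) with a flat-gradient mask.

    The gradient uses central differences; the one-pixel grid border (one-
    sided differences) and points where |grad T| < 1/speed_ceiling — i.e.
    implied speeds above the ceiling, arising where the wavefront is locally
    flat — are masked out.  The summary speed is the median of V over the
    valid mask.
    """
    dy = float(field.grid_y[1, 0] - field.grid_y[0, 0]) if field.grid_y.shape[0] > 1 else 1.0
    dx = float(field.grid_x[0, 1] - field.grid_x[0, 0]) if field.grid_x.shape[1] > 1 else 1.0
    Ty, Tx = np.gradient(field.T, dy, dx)
    gnorm = np.hypot(Tx, Ty)
    valid = gnorm >= 1.0 / speed_ceiling
    valid[0, :] = valid[-1, :] = False
    valid[:, 0] = valid[:, -1] = False
    if not valid.any():
        raise ValueError("flat lag field: no usable gradient anywhere")
    with np.errstate(divide="ignore"):
        V = np.where(gnorm > 0, 1.0 / gnorm, np.inf)
    field.V = V
    field.valid_mask = valid
    return field, float(np.median(V[valid]))


def wave_speeds(waveset: WaveSet, geometry: ElectrodeGeometry,
                cfg: WaveConfig | None = None) -> np.ndarray:
    """Per-wave summary propagation speed (mm/s) for all complete waves."""
    cfg = cfg or WaveConfig()
    speeds = []
    for lags in waveset.lag_matrix:
        if np.isfinite(lags).sum() < 4:
            continue
        try:
            field = interpolate_timelag_field(lags, geometry, cfg.grid_step)
            _, s = speed_map(field, cfg.speed_ceiling)
            speeds.append(s)
        except ValueError:
            continue
    return np.asarray(speeds)


def wave_pca_entropy(lag_matrix: np.ndarray, k_bins: int = 8,
                     impute_missing: bool = False) -> float:
    """Shannon entropy (bits) of wave occupancy in the PC1-PC2 plane.

    The lag matrix is column-centred and projected onto its first two
    principal components; the PC plane is partitioned into a k x k grid
    spanning the data extent and the entropy of the normalized occupancy
    histogram is returned.  Waves with missing channels are excluded unless
    ``impute_missing`` (per-channel mean imputation).
    """
    M = np.asarray(lag_matrix, dtype=float)
    if impute_missing:
        col_mean = np.nanmean(M, axis=0)
        M = np.where(np.isfinite(M), M, col_mean[None, :])
    else:
        M = M[np.isfinite(M).all(axis=1)]
    if M.shape[0] < 10:
        raise ValueError("need at least 10 complete waves for entropy")
    M = M - M.mean(axis=0)
    # PCA via SVD; projection is coordinate-free up to sign
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    proj = M @ Vt[:2].T
    extents = proj.max(axis=0) - proj.min(axis=0)
    if np.all(extents <= 0):
        return 0.0  # all waves identical: a single occupied cell
    counts, _, _ = np.histogram2d(
        proj[:, 0], proj[:, 1], bins=k_bins,
        range=[[proj[:, 0].min(), proj[:, 0].max() + 1e-12],
               [proj[:, 1].min(), proj[:, 1].max() + 1e-12]])
    p = counts.ravel() / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())
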