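"""Functional connectivity: correlation matrices and graph metrics.

LFPs are downsampled (anti-aliased) and optionally zero-phase Butterworth
band-filtered, then pairwise Pearson-correlated into a weight matrix W.
Graph analyses convert correlation to distance as D_ij = 1/W_ij (weights at
or below a floor are treated as absent edges), run seeded best-of-n Louvain
community detection for modularity Q, compute the characteristic path
length L as the mean Dijkstra shortest-path distance over reachable pairs,
and summarize the breadth of the correlation distribution as the functional
complexity C in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import signal, stats

from .config import ConnectivityConfig
from .io import Recording

__all__ = [
    "ConnectivityGraph", "preprocess", "correlation_matrix",
    "correlation_distribution", "weight_to_distance", "louvain_modularity",
    "characteristic_path_length", "functional_complexity", "analyze_connectivity",
    "band_sweep",
]


@dataclass
class ConnectivityGraph:
    W: np.ndarray                 # Pearson correlation matrix
    band: str = "wideband"
    D: np.ndarray | None = None   # 1/W distances (inf = absent edge)
    partition: np.ndarray | None = None
    Q: float | None = None        # modularity
    L: float | None = None        # characteristic path length
    C: float | None = None        # functional complexity in [0, 1]
    meta: dict = field(default_factory=dict)


def preprocess(rec: Recording, downsample_to: float = 250.0,
               band: tuple[float, float] | None = None,
               butter_order: int = 4) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation and optional zero-phase Butterworth bandpass.

    Returns (signals, new sampling rate).  The bandpass is applied
    forward-backward (sosfiltfilt), so the passband has zero net phase.
    """
    if downsample_to > rec.fs:
        raise ValueError("downsample_to exceeds the recording sampling rate")
    up, down = 1, int(round(rec.fs / downsample_to))
    fs_new = rec.fs / down
    x = signal.resample_poly(rec.signals, up, down, axis=-1) if down > 1 else rec.signals
    if band is not None:
        lo, hi = band
        if hi >= fs_new / 2:
            raise ValueError(f"band {band} exceeds Nyquist ({fs_new / 2} Hz) after downsampling")
        sos = signal.butter(butter_order, [lo, hi], btype="bandpass", fs=fs_new, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1)
    return x, fs_new


def correlation_matrix(signals: np.ndarray) -> np.ndarray:
    """Symmetric Pearson correlation matrix with unit diagonal."""
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    sd = x.std(axis=1)
    dead = np.where(sd == 0)[0]
    if len(dead):
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    W = np.corrcoef(x)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    return np.clip(W, -1.0, 1.0)


def _upper(W: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(W.shape[0], k=1)
    vals = W[iu]
    if vals.size == 0:
        raise ValueError("empty upper triangle")
    return vals


def correlation_distribution(W_a, W_b) -> dict:
    """Pooled upper-triangle correlation distributions of two groups + KS test.

    Each argument is a matrix or a list of matrices (one per animal); values
    are pooled per group.
    """
    def pool(Ws):
        Ws = [Ws] if isinstance(Ws, np.ndarray) and Ws.ndim == 2 else list(Ws)
        return np.concatenate([_upper(np.asarray(W)) for W in Ws])

    a, b = pool(W_a), pool(W_b)
    D, p = stats.ks_2samp(a, b, method="asymp")
    return {"values_a": a, "values_b": b, "median_a": float(np.median(a)),
            "median_b": float(np.median(b)), "ks_D": float(D), "ks_p": float(p)}


def weight_to_distance(W: np.ndarray, weight_floor: float = 0.05) -> np.ndarray:
    """D_ij = 1/W_ij; correlations at or below the floor become absent edges.

    Negative or near-zero correlations have no meaningful reciprocal
    distance, so they are infinite (no edge).  Diagonal is 0.
    """
    W = np.asarray(W, dtype=float)
    with np.errstate(divide="ignore"):
        D = np.where(W > weight_floor, 1.0 / W, np.inf)
    np.fill_diagonal(D, 0.0)
    return D


def _floored_graph(W: np.ndarray, weight_floor: float) -> nx.Graph:
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if W[i, j] > weight_floor:
            G.add_edge(int(i), int(j), weight=float(W[i, j]))
    return G


def louvain_modularity(W: np.ndarray, n_restarts: int = 20, seed: int = 0,
                       resolution: float = 1.0,
                       weight_floor: float = 0.05) -> tuple[np.ndarray, float]:
    """Best-of-n-restarts Louvain partition and Newman-Girvan modularity Q.

    Edge weights are the floored correlations (self-loops removed); Louvain
    is stochastic, so the best-Q partition over seeded restarts is kept.
    """
    G = _floored_graph(W, weight_floor)
    if G.number_of_edges() == 0:
        raise ValueError("no edges above the weight floor")
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + r)
        q = nx.community.modularity(G, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_part = q, comms
    labels = np.empty(W.shape[0], dtype=int)
    for lab, nodes in enumerate(best_part):
        for node in nodes:
            labels[node] = lab
    return labels, float(best_q)


def characteristic_path_length(D: np.ndarray) -> tuple[float, float]:
    """Mean Dijkstra shortest-path distance over reachable ordered pairs.

    Returns (L, unreachable fraction).  Raises if no pair is reachable.
    """
    from scipy.sparse.csgraph import dijkstra

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    A = np.where(np.isfinite(D), D, 0.0)
    np.fill_diagonal(A, 0.0)
    sp = dijkstra(A, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    if not finite.any():
        raise ValueError("graph fully disconnected")
    frac_unreachable = float((off & ~finite).sum() / off.sum())
    return float(sp[finite].mean()), frac_unreachable


def functional_complexity(W: np.ndarray, n_bins: int = 20) -> float:
    """Breadth of the |r| distribution: C = 1 - (M/(2(M-1))) * sum_m |p_m - 1/M|.

    p is the histogram of upper-triangle absolute correlations over M equal
    bins on [0, 1].  C = 0 for a delta-like distribution (all values in one
    bin) and C = 1 for exactly uniform bin occupancy.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.abs(_upper(np.asarray(W, dtype=float)))
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    M = n_bins
    c = 1.0 - (M / (2.0 * (M - 1.0))) * np.abs(p - 1.0 / M).sum()
    return float(min(1.0, max(0.0, c)))


def analyze_connectivity(rec: Recording, band: tuple[float, float] | None = None,
                         band_name: str = "wideband",
                         cfg: ConnectivityConfig | None = None,
                         seed: int = 0) -> ConnectivityGraph:
    """Full connectivity analysis of one recording in one band."""
    cfg = cfg or ConnectivityConfig()
    rate = cfg.downsample_to if band is None else min(
        max(4.0 * band[1], 2.5 * band[1] + 1.0), rec.fs)
    x, _ = preprocess(rec, rate, band, cfg.butter_order)
    W = correlation_matrix(x)
    D = weight_to_distance(W, cfg.weight_floor)
    partition, Q = louvain_modularity(W, cfg.n_restarts, seed, cfg.resolution,
                                      cfg.weight_floor)
    L, unreachable = characteristic_path_length(D)
    C = functional_complexity(W, cfg.complexity_bins)
    return ConnectivityGraph(W=W, band=band_name, D=D, partition=partition,
                             Q=Q, L=L, C=C,
                             meta={"weight_floor": cfg.weight_floor,
                                   "unreachable_fraction": unreachable,
                                   "seed": seed})


def band_sweep(rec: Recording, cfg: ConnectivityConfig | None = None,
               seed: int = 0) -> dict[str, ConnectivityGraph]:
    """Wideband plus every configured band: preprocess -> correlate -> metrics."""
    cfg = cfg or ConnectivityConfig()
    out = {"wideband": analyze_connectivity(rec, None, "wideband", cfg, seed)}
    for name, band in cfg.bands.items():
        out[name] = analyze_connectivity(rec, band, name, cfg, seed)
    return out
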