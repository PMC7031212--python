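"""Up/Down state detection and slow-oscillation metrics.

States are detected with a per-channel threshold on the logarithmically
scaled MUA: the threshold sits at the valley of the (smoothed) log-MUA
histogram between its two largest modes, above-threshold runs become Up
states, and runs shorter than a minimum duration are absorbed into the
flanking state so that labels always alternate.

From the segmentation the module computes the standard slow-oscillation
metrics: mean Up/Down durations and their coefficients of variation, SO
frequency (mean of per-cycle inverse Up+Down durations), relative Up/Down
firing rates, the Down-to-Up transition slope in degrees under a fixed axis
standardization, and Up-state band power (Welch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal.windows import hann

from .config import DetectionConfig
from .mua import MUATrace

__all__ = [
    "StateSegmentation", "SOMetrics", "choose_threshold", "detect_states",
    "segment_recording", "so_metrics", "upward_slope", "up_state_psd",
    "task_normalized_fr", "state_mask", "transition_times",
]

UP, DOWN = "Up", "Down"


@dataclass
class StateSegmentation:
    """Per-channel alternating (label, start, end) intervals + thresholds used."""

    intervals: list  # per channel: list of (label, start s, end s)
    thresholds: np.ndarray  # per-channel log-MUA threshold
    channel_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for ch, ints in enumerate(self.intervals):
            for k in range(1, len(ints)):
                if ints[k][0] == ints[k - 1][0]:
                    raise ValueError(f"channel {ch}: labels do not alternate")
                if abs(ints[k][1] - ints[k - 1][2]) > 1e-9:
                    raise ValueError(f"channel {ch}: gap/overlap between intervals")


@dataclass
class SOMetrics:
    up_dur_mean: float
    down_dur_mean: float
    so_freq: float
    cv_up: float
    cv_down: float
    cv_so: float
    up_fr_rel: float | None = None
    down_fr: float | None = None
    upward_slope: float | None = None
    band_psd: dict = field(default_factory=dict)


def state_mask(intervals: list, times: np.ndarray, label: str) -> np.ndarray:
    """Boolean mask over ``times`` of samples lying in intervals of ``label``."""
    mask = np.zeros(len(times), dtype=bool)
    for lab, s, e in intervals:
        if lab == label:
            mask |= (times >= s) & (times < e)
    return mask


def transition_times(intervals: list) -> np.ndarray:
    """Down->Up transition times (Up-state onsets, excluding a leading edge Up)."""
    out = []
    for k, (lab, s, e) in enumerate(intervals):
        if lab == UP and k > 0:
            out.append(s)
    return np.array(out)


def choose_threshold(log_mua: np.ndarray, bins: int = 100,
                     smooth_bins: float = 3.0) -> float:
    """Valley of the smoothed log-MUA histogram between its two largest modes.

    Falls back to the midpoint of the 10th/90th percentiles when the
    histogram is unimodal.  Raises on a (near-)constant trace.
    """
    x = np.asarray(log_mua, dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError("no bistability: log MUA is constant")
    counts, edges = np.histogram(x, bins=bins)
    sm = gaussian_filter1d(counts.astype(float), smooth_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    interior = np.arange(1, bins - 1)
    is_peak = (sm[interior] >= sm[interior - 1]) & (sm[interior] >= sm[interior + 1])
    peaks = interior[is_peak]
    # include the edge bins as candidate modes
    if sm[0] > sm[1]:
        peaks = np.r_[0, peaks]
    if sm[-1] > sm[-2]:
        peaks = np.r_[peaks, bins - 1]
    # modes must be real, not tail wiggles
    peaks = peaks[sm[peaks] >= 0.1 * sm.max()]
    if len(peaks) < 2:
        lo, hi = np.percentile(x, [10, 90])
        return float(0.5 * (lo + hi))
    top2 = peaks[np.argsort(sm[peaks])[-2:]]
    a, b = np.sort(top2)
    if b - a < 2:
        lo, hi = np.percentile(x, [10, 90])
        return float(0.5 * (lo + hi))
    valley = a + 1 + np.argmin(sm[a + 1: b])
    return float(centers[valley])


def _runs(above: np.ndarray) -> list:
    """Consecutive runs of a boolean array as [label, i0, i1] (inclusive)."""
    runs = []
    start = 0
    for i in range(1, len(above) + 1):
        if i == len(above) or above[i] != above[start]:
            runs.append([bool(above[start]), start, i - 1])
            start = i
    return runs


def detect_states(log_mua: np.ndarray, times: np.ndarray, threshold: float,
                  min_up: float = 0.05, min_down: float = 0.05) -> list:
    """Threshold the log MUA into alternating Up/Down intervals.

    Runs shorter than the per-state minimum duration are merged into the
    flanking state (shortest first) so the output always alternates.
    Interval boundaries are placed midway between window centres.
    """
    if len(log_mua) == 0:
        raise ValueError("empty trace")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    step = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    runs = _runs(np.asarray(log_mua) >= threshold)

    def dur(r):
        return (r[2] - r[1] + 1) * step

    def min_dur(r):
        return min_up if r[0] else min_down

    while len(runs) > 1:
        short = [k for k, r in enumerate(runs) if dur(r) < min_dur(r)]
        if not short:
            break
        k = min(short, key=lambda k: dur(runs[k]))
        runs[k][0] = not runs[k][0]  # absorb into flanking state
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged

    t0 = times[0] - step / 2
    t_end = times[-1] + step / 2

    def left(i0):
        return t0 if i0 == 0 else 0.5 * (times[i0 - 1] + times[i0])

    def right(i1):
        return t_end if i1 == len(times) - 1 else 0.5 * (times[i1] + times[i1 + 1])

    return [((UP if up else DOWN), left(i0), right(i1)) for up, i0, i1 in runs]


def segment_recording(mua: MUATrace, cfg: DetectionConfig | None = None) -> StateSegmentation:
    """Smooth, threshold and segment every channel of a MUATrace."""
    cfg = cfg or DetectionConfig()
    step = float(np.median(np.diff(mua.times)))
    n_sm = max(1, int(round(cfg.smooth_window / step)))
    intervals, thresholds = [], []
    for i in range(mua.log_mua.shape[0]):
        x = uniform_filter1d(mua.log_mua[i], n_sm) if n_sm > 1 else mua.log_mua[i]
        thr = choose_threshold(x, cfg.hist_bins, cfg.hist_smooth_bins)
        intervals.append(detect_states(x, mua.times, thr, cfg.min_up, cfg.min_down))
        thresholds.append(thr)
    return StateSegmentation(intervals, np.asarray(thresholds), list(mua.channel_ids))


def _pop_cv(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    return float(x.std() / m) if m != 0 else np.nan


def so_metrics(intervals: list, mua_ch: np.ndarray | None = None,
               times: np.ndarray | None = None) -> SOMetrics:
    """Slow-oscillation metrics of one channel's segmentation.

    Edge-truncated first/last intervals are excluded.  The SO frequency is
    the mean of per-cycle inverse (Up + following Down) durations; CVs use
    the population (/N) standard deviation.
    """
    inner = intervals[1:-1]
    ups = np.array([e - s for lab, s, e in inner if lab == UP])
    downs = np.array([e - s for lab, s, e in inner if lab == DOWN])
    cycles = []
    for k in range(len(inner) - 1):
        if inner[k][0] == UP and inner[k + 1][0] == DOWN:
            cycles.append((inner[k][2] - inner[k][1]) + (inner[k + 1][2] - inner[k + 1][1]))
    cycles = np.asarray(cycles)
    if len(cycles) < 2:
        raise ValueError("fewer than 2 complete SO cycles")
    inv = 1.0 / cycles
    up_fr_rel = down_fr = None
    if mua_ch is not None and times is not None:
        up_mask = state_mask(intervals, times, UP)
        down_mask = state_mask(intervals, times, DOWN)
        if not down_mask.any():
            raise ValueError("no Down windows")
        up_fr_rel = float(mua_ch[up_mask].mean() / mua_ch[down_mask].mean())
        down_fr = float(mua_ch[down_mask].mean())
    return SOMetrics(
        up_dur_mean=float(ups.mean()),
        down_dur_mean=float(downs.mean()),
        so_freq=float(inv.mean()),
        cv_up=_pop_cv(ups),
        cv_down=_pop_cv(downs),
        cv_so=_pop_cv(inv),
        up_fr_rel=up_fr_rel,
        down_fr=down_fr,
    )


def upward_slope(log_mua: np.ndarray, times: np.ndarray, transitions: np.ndarray,
                 fit_window: float = 0.1, mean_cycle: float | None = None,
                 span: float | None = None) -> float:
    """Mean Down->Up transition slope, degrees, on standardized axes.

    Around each Down->Up crossing a least-squares line is fitted to the log
    MUA with time expressed in units of the mean SO cycle and amplitude in
    units of the Up-Down log-MUA span; the slope is reported as its
    arctangent in degrees, averaged over transitions.  Degrees are
    meaningless without an axis convention; this one is fixed and
    configurable.
    """
    transitions = np.asarray(transitions, dtype=float)
    if len(transitions) < 5:
        raise ValueError("need at least 5 transitions for a stable slope")
    if mean_cycle is None:
        mean_cycle = float(np.mean(np.diff(np.sort(transitions))))
    if span is None:
        lo, hi = np.percentile(log_mua, [10, 90])
        span = float(hi - lo)
    if span <= 0 or mean_cycle <= 0:
        raise ValueError("degenerate standardization axes")
    angles = []
    for t0 in transitions:
        sel = (times >= t0 - fit_window / 2) & (times <= t0 + fit_window / 2)
        if sel.sum() < 3 or times[sel][0] > t0 or times[sel][-1] < t0:
            warnings.warn(f"transition at {t0:.3f}s skipped: window out of bounds")
            continue
        x = (times[sel] - t0) / mean_cycle
        y = (log_mua[sel] - log_mua[sel].min()) / span
        b = np.polyfit(x, y, 1)[0]
        angles.append(np.degrees(np.arctan(b)))
    if not angles:
        raise ValueError("all transitions skipped")
    return float(np.mean(angles))


def up_state_psd(x: np.ndarray, fs: float, intervals: list,
                 bands: dict | None = None, seg_len: float = 0.25) -> dict:
    """Welch band power (uV^2/Hz) over concatenated Up epochs.

    Hann-windowed 50%-overlap segments are taken inside each Up epoch
    (epochs shorter than one segment are dropped) and their periodograms
    averaged; band power is the mean density over each band.
    """
    bands = bands or {"alpha": (8.0, 12.0), "beta": (15.0, 32.0), "gamma": (32.0, 100.0)}
    nper = int(round(seg_len * fs))
    hop = nper // 2
    win = hann(nper, sym=False)
    scale = 2.0 / (fs * (win**2).sum())
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    for name, (lo, hi) in bands.items():
        if hi > fs / 2:
            raise ValueError(f"band {name} exceeds Nyquist frequency")
    acc = np.zeros(len(freqs))
    count = 0
    total_up = sum(e - s for lab, s, e in intervals if lab == UP)
    if total_up < 2.0:
        raise ValueError("need at least 2 s of Up state for a stable PSD")
    for lab, s, e in intervals:
        if lab != UP:
            continue
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        seg = np.asarray(x[i0:i1], dtype=float)
        for start in range(0, len(seg) - nper + 1, hop):
            chunk = seg[start: start + nper]
            chunk = chunk - chunk.mean()
            p = np.abs(np.fft.rfft(win * chunk))**2 * scale
            acc += p
            count += 1
    if count == 0:
        raise ValueError("no Up epoch long enough for a Welch segment")
    psd = acc / count
    return {name: float(psd[(freqs >= lo) & (freqs <= hi)].mean())
            for name, (lo, hi) in bands.items()}


def task_normalized_fr(mua_ch: np.ndarray, times: np.ndarray, t_task_start: float,
                       window: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean MUA normalized to the window at task initiation.

    Returns (window centre times, normalized firing rate); the first value
    is 1 by construction.
    """
    if times[-1] < t_task_start + window:
        raise ValueError("recording does not cover the task start plus one window")
    edges = np.arange(t_task_start, times[-1] + 1e-9, window)
    centers, values = [], []
    for k in range(len(edges) - 1):
        sel = (times >= edges[k]) & (times < edges[k + 1])
        if sel.any():
            centers.append(0.5 * (edges[k] + edges[k + 1]))
            values.append(mua_ch[sel].mean())
    values = np.asarray(values)
    if values[0] == 0:
        raise ValueError("zero baseline at task initiation")
    return np.asarray(centers), values / values[0]
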