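"""Population firing-rate (MUA) estimation from high-frequency LFP power.

The multiunit activity is estimated from the 200-1500 Hz content of the LFP
short-time spectrum.  Each frequency bin is normalized by its own
whole-recording time average before averaging across the band: at these
frequencies the normalized spectral density is proportional to aggregate
spiking of the nearby population, and the per-bin normalization removes the
electrode's frequency response and the 1/f background, making the estimate
exactly invariant to per-channel gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .config import MuaConfig
from .io import Recording

__all__ = ["Spectrogram", "MUATrace", "compute_spectrogram", "normalize_mua", "relative_up_fr"]


@dataclass
class Spectrogram:
    """Short-time power estimates: power is (channels, freqs, windows), uV^2/Hz."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # window centres, s
    window: float
    step: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass
class MUATrace:
    """Normalized MUA per channel: dimensionless, whole-recording mean 1."""

    mua: np.ndarray       # (channels, windows)
    log_mua: np.ndarray   # log of mua, floored
    times: np.ndarray     # s
    channel_ids: list
    meta: dict


def compute_spectrogram(rec: Recording, window: float = 0.005,
                        step: float = 0.001) -> Spectrogram:
    """Hann-tapered one-sided short-time power spectrum of every channel.

    Frames are fully supported (no zero-padded edges); the FFT length is
    padded to the next fast size, which only refines the frequency grid.
    Scaling is PSD (uV^2/Hz): summing power x bin width over one frame
    approximates the frame's variance (Parseval).
    """
    nperseg = int(round(window * rec.fs))
    hop = int(round(step * rec.fs))
    if nperseg < 2 or hop < 1:
        raise ValueError("window/step too short for this sampling rate")
    if rec.n_samples < nperseg:
        raise ValueError("recording shorter than one spectrogram window")
    from numpy.lib.stride_tricks import sliding_window_view
    from scipy.fft import next_fast_len

    win = hann(nperseg, sym=False)
    nfft = next_fast_len(nperseg)
    frames = sliding_window_view(rec.signals, nperseg, axis=-1)[..., ::hop, :]
    # float64 throughout: per-bin normalization downstream must cancel an
    # overall gain to better than 1e-10, which single precision cannot
    spec = np.fft.rfft(frames * win, n=nfft, axis=-1)
    scale = 2.0 / (rec.fs * (win**2).sum())
    power = ((spec.real**2 + spec.imag**2) * scale).transpose(0, 2, 1)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rec.fs)
    n_frames = frames.shape[-2]
    times = rec.t0 + (np.arange(n_frames) * hop + (nperseg - 1) / 2) / rec.fs
    return Spectrogram(power=power, freqs=freqs, times=times,
                       window=window, step=step)


def normalize_mua(spec: Spectrogram, band: tuple[float, float] = (200.0, 1500.0),
                  log_floor: float = 1e-3, channel_ids: list | None = None) -> MUATrace:
    """Average per-bin-normalized band power into a unit-mean MUA trace.

    Every bin inside ``band`` is divided by its own time average across the
    whole recording (removing electrode gain and spectral coloring), then the
    normalized bins are averaged across the band.  The result has mean 1 per
    channel by construction; ``log_mua`` is its log, floored at ``log_floor``.
    """
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} not covered by spectrogram frequencies")
    bp = spec.power[:, sel, :].astype(np.float64)
    denom = bp.mean(axis=-1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("degenerate recording: a frequency bin has zero average power")
    mua = (bp / denom).mean(axis=1)
    log_mua = np.log(np.maximum(mua, log_floor))
    ids = channel_ids if channel_ids is not None else [f"ch{i}" for i in range(mua.shape[0])]
    meta = {"band": band, "window": spec.window, "step": spec.step,
            "log_floor": log_floor, "averaging": "power"}
    return MUATrace(mua=mua, log_mua=log_mua, times=spec.times, channel_ids=ids, meta=meta)


def compute_mua(rec: Recording, cfg: MuaConfig | None = None) -> MUATrace:
    """Recording -> MUATrace with the configured window, step and band."""
    cfg = cfg or MuaConfig()
    spec = compute_spectrogram(rec, cfg.window, cfg.step)
    return normalize_mua(spec, cfg.band, cfg.log_floor, rec.channel_ids)


def relative_up_fr(mua: MUATrace, segmentation) -> np.ndarray:
    """Per-channel mean MUA in Up windows divided by mean MUA in Down windows."""
    from .updown import state_mask  # local import to avoid a cycle

    out = np.empty(mua.mua.shape[0])
    for i in range(mua.mua.shape[0]):
        up = state_mask(segmentation.intervals[i], mua.times, "Up")
        down = state_mask(segmentation.intervals[i], mua.times, "Down")
        if not down.any():
            raise ValueError(f"channel {i}: no Down windows to normalize against")
        if not up.any():
            raise ValueError(f"channel {i}: no Up windows")
        out[i] = mua.mua[i, up].mean() / mua.mua[i, down].mean()
    return out
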