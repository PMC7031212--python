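"""Synthetic multichannel LFP with known ground truth.

Emulates anesthetized cortical recordings dominated by the slow oscillation:
bistable Up/Down alternation with gamma-distributed state durations,
gamma-band content confined to Up states, high-band (200-1500 Hz) noise whose
standard deviation tracks a firing-rate parameter, a colored 1/f^x background,
wavefronts propagating across the electrode array, and block-structured
inter-channel correlation via shared-signal mixing.

The generator is statistical, not biophysical: each component is matched to
what the downstream analysis measures (band power, transition times,
pairwise correlation), so every stage can be validated against exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .io import ElectrodeGeometry, Recording, grid_geometry, linear_geometry

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "sample_state_sequence",
    "synthesize_channel",
    "apply_propagation",
    "mix_shared_signal",
    "generate_recording",
    "generate_cohort",
    "PRESETS",
]

UP, DOWN = "Up", "Down"


@dataclass
class SyntheticConfig:
    """All knobs of the generator. Units: s, Hz, microvolts, mm, mm/s."""

    n_channels: int = 16
    geometry: ElectrodeGeometry | None = None
    fs: float = 5000.0
    duration: float = 60.0
    up_mean: float = 0.39        # mean Up-state duration, s
    down_mean: float = 0.82      # mean Down-state duration, s
    up_cv: float = 0.51          # coefficient of variation of Up durations
    down_cv: float = 0.49
    gamma_freq: float = 60.0     # Hz, Up-state gamma rhythm
    gamma_amp_up: float = 10.0   # uV, gamma amplitude during Up states
    hf_rate_up: float = 3.0      # a.u., firing-rate level scaling 200-1500 Hz SD in Up
    hf_rate_down: float = 1.0    # a.u., same during Down
    hf_scale: float = 5.0        # uV per unit firing rate
    slow_amp: float = 30.0       # uV, Up/Down slow-deflection amplitude
    one_over_f_amp: float = 40.0  # uV, SD of the colored background
    background_exponent: float = 2.0  # power ~ 1/f^x
    channel_gains: np.ndarray | None = None  # per-channel multipliers
    wave_mode: str = "planar"    # planar | radial | none
    wave_speed: float = 20.0     # mm/s
    wave_directions: tuple = ((1.0, 0.0), (-1.0, 0.0))  # alternating planar directions
    module_assignment: np.ndarray | None = None  # per-channel community label
    shared_fraction: float = 0.0  # within-community common-signal weight, [0, 1)
    global_fraction: float = 0.0  # all-channel common-signal weight, [0, 1)
    shared_band: tuple[float, float] | None = (1.0, 15.0)  # Hz band of common signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.up_mean <= 0 or self.down_mean <= 0:
            raise ValueError("state mean durations must be > 0")
        if self.up_cv < 0 or self.down_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not (0 <= self.shared_fraction < 1 and 0 <= self.global_fraction < 1):
            raise ValueError("shared/global fractions must be in [0, 1)")
        if self.shared_fraction + self.global_fraction >= 1:
            raise ValueError("shared_fraction + global_fraction must be < 1")
        for name in ("gamma_amp_up", "hf_scale", "slow_amp", "one_over_f_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wave_mode not in ("planar", "radial", "none"):
            raise ValueError(f"unknown wave_mode {self.wave_mode!r}")
        if self.wave_mode != "none" and self.wave_speed <= 0:
            raise ValueError("wave_speed must be > 0")
        if self.geometry is None:
            self.geometry = (
                linear_geometry(self.n_channels)
                if self.n_channels <= 16
                else grid_geometry()
            )
        if self.geometry.n_channels != self.n_channels:
            raise ValueError("geometry does not match n_channels")
        if self.module_assignment is None:
            # default: two communities, array split in half
            half = self.n_channels // 2
            self.module_assignment = np.array(
                [0] * half + [1] * (self.n_channels - half)
            )
        self.module_assignment = np.asarray(self.module_assignment)
        if len(self.module_assignment) != self.n_channels:
            raise ValueError("module_assignment must have one label per channel")
        if self.channel_gains is None:
            self.channel_gains = np.ones(self.n_channels)
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    state_intervals: list  # per channel: list of (label, start, end)
    true_transition_times: list  # per channel: Down->Up times, s
    true_wave_lags: np.ndarray | None  # (n_waves, n_channels), s, zero-mean rows
    true_partition: np.ndarray  # per-channel community label
    config: SyntheticConfig | None = None


def _gamma_durations(mean: float, cv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if cv < 1e-6:  # degenerate: effectively deterministic durations
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=n)


def sample_state_sequence(cfg: SyntheticConfig, rng: np.random.Generator) -> list:
    """Draw an alternating Down/Up interval sequence tiling [0, duration].

    Durations are gamma-distributed with the configured mean and CV
    (degenerate constant at CV = 0).  The sequence starts in Down and the
    final interval is truncated at the recording end.
    """
    cycle = cfg.up_mean + cfg.down_mean
    if cfg.duration < cycle:
        raise ValueError("duration shorter than one mean Up+Down cycle")
    n_est = int(np.ceil(cfg.duration / cycle * 3)) + 10
    ups = _gamma_durations(cfg.up_mean, cfg.up_cv, n_est, rng)
    downs = _gamma_durations(cfg.down_mean, cfg.down_cv, n_est, rng)
    intervals = []
    t = 0.0
    for d, u in zip(downs, ups):
        for label, dur in ((DOWN, d), (UP, u)):
            end = min(t + dur, cfg.duration)
            intervals.append((label, t, end))
            t = end
            if t >= cfg.duration:
                return intervals
    raise RuntimeError("insufficient pre-drawn durations")  # pragma: no cover


def _indicator(intervals: list, n: int, fs: float) -> np.ndarray:
    """Binary Up indicator on the sample grid."""
    u = np.zeros(n)
    for label, start, end in intervals:
        if label == UP:
            u[int(round(start * fs)): int(round(end * fs))] = 1.0
    return u


def _colored_noise(n: int, fs: float, exponent: float, rng: np.random.Generator,
                   f_min: float = 1.0) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^exponent above f_min."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(f)
    above = f >= f_min
    shaping[above] = (f_min / f[above]) ** (exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _unit_bandpassed(n: int, fs: float, band: tuple[float, float],
                     rng: np.random.Generator) -> np.ndarray:
    hi = min(band[1], 0.499 * fs)
    sos = signal.butter(4, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def synthesize_channel(intervals: list, cfg: SyntheticConfig,
                       rng: np.random.Generator, gain: float = 1.0) -> np.ndarray:
    """Render one LFP trace (uV) from a state-interval sequence.

    Composition: negative slow deflection during Up states, a stochastic-phase
    gamma oscillation confined to Up states, 200-1500 Hz Gaussian noise whose
    SD follows the state firing-rate level, and a 1/f^x background; the sum
    is multiplied by the channel gain.
    """
    if cfg.fs <= 2 * cfg.gamma_freq:
        raise ValueError("fs too low for gamma_freq (Nyquist)")
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    u = _indicator(intervals, n, cfg.fs)
    # smooth state envelope: ~10 ms transition
    env = gaussian_filter1d(u, sigma=0.010 * cfg.fs)

    trace = -cfg.slow_amp * env  # Up states deflect negative at depth

    if cfg.gamma_amp_up > 0:
        phase = 2 * np.pi * cfg.gamma_freq * t + rng.uniform(0, 2 * np.pi)
        phase += np.cumsum(rng.standard_normal(n)) * np.sqrt(2 * np.pi * 2.0 / cfg.fs)
        trace += cfg.gamma_amp_up * np.sin(phase) * env

    if cfg.hf_scale > 0:
        carrier = _unit_bandpassed(n, cfg.fs, (200.0, 1500.0), rng)
        sd_env = cfg.hf_scale * (cfg.hf_rate_up * u + cfg.hf_rate_down * (1.0 - u))
        trace += carrier * sd_env

    if cfg.one_over_f_amp > 0:
        trace += cfg.one_over_f_amp * _colored_noise(n, cfg.fs, cfg.background_exponent, rng)

    return trace * gain


def apply_propagation(intervals: list, geometry: ElectrodeGeometry,
                      cfg: SyntheticConfig):
    """Shift the global Up intervals per channel to make travelling waves.

    Each global Down->Up transition is one wave; channel i's copy is offset
    by lag = (position projected on the wave direction) / speed (planar) or
    (distance from the array centre) / speed (radial).  Per-wave lags are
    recentred to zero mean and returned as ground truth.

    Returns (per_channel_intervals, true_wave_lags).
    """
    pos = geometry.positions
    n_ch = geometry.n_channels
    ups = [(s, e) for lab, s, e in intervals if lab == UP]
    n_waves = len(ups)
    lags = np.zeros((n_waves, n_ch))
    if cfg.wave_mode == "none":
        return [list(intervals) for _ in range(n_ch)], lags
    if cfg.wave_speed <= 0:
        raise ValueError("wave_speed must be > 0")
    center = pos.mean(axis=0)
    for w in range(n_waves):
        if cfg.wave_mode == "planar":
            d = np.asarray(cfg.wave_directions[w % len(cfg.wave_directions)], float)
            d = d / np.linalg.norm(d)
            raw = pos @ d / cfg.wave_speed
        else:  # radial from array centre
            raw = np.linalg.norm(pos - center, axis=1) / cfg.wave_speed
        lags[w] = raw - raw.mean()

    per_channel = []
    for i in range(n_ch):
        shifted_ups = []
        prev_end = 0.0
        for w, (s, e) in enumerate(ups):
            s2 = max(s + lags[w, i], prev_end)
            e2 = min(max(e + lags[w, i], s2), cfg.duration)
            if e2 > s2:
                shifted_ups.append((s2, e2))
                prev_end = e2
        ch_ints = []
        t = 0.0
        for s, e in shifted_ups:
            if s > t:
                ch_ints.append((DOWN, t, s))
            ch_ints.append((UP, s, e))
            t = e
        if t < cfg.duration:
            ch_ints.append((DOWN, t, cfg.duration))
        per_channel.append(ch_ints)
    return per_channel, lags


def mix_shared_signal(traces: np.ndarray, module_assignment, shared_fraction: float,
                      rng: np.random.Generator, global_fraction: float = 0.0,
                      band: tuple[float, float] | None = None,
                      fs: float | None = None) -> np.ndarray:
    """Blend a per-community common signal into each channel.

    Each channel becomes sqrt(1-f-g)*own + sqrt(f)*c_community + sqrt(g)*c_global,
    with the common signals scaled to the channel's own SD so that the expected
    within-community Pearson correlation is f+g and the across-community
    correlation is g (for independent inputs).  ``band`` optionally limits the
    common signals' spectrum (requires ``fs``).
    """
    traces = np.asarray(traces, dtype=float)
    labels = np.asarray(module_assignment)
    if len(labels) != traces.shape[0]:
        raise ValueError("unknown community assignment: one label per channel required")
    f, g = float(shared_fraction), float(global_fraction)
    if not (0 <= f < 1 and 0 <= g < 1 and f + g < 1):
        raise ValueError("fractions must be in [0, 1) with f + g < 1")
    if f == 0 and g == 0:
        return traces.copy()
    n = traces.shape[1]

    def _common() -> np.ndarray:
        if band is not None:
            if fs is None:
                raise ValueError("fs required when band is given")
            return _unit_bandpassed(n, fs, band, rng)
        return rng.standard_normal(n)

    commons = {lab: _common() for lab in np.unique(labels)}
    c_glob = _common() if g > 0 else np.zeros(n)
    out = np.empty_like(traces)
    for i, lab in enumerate(labels):
        sd = traces[i].std()
        out[i] = (np.sqrt(1 - f - g) * traces[i]
                  + np.sqrt(f) * sd * commons[lab]
                  + np.sqrt(g) * sd * c_glob)
    return out


def generate_recording(cfg: SyntheticConfig) -> tuple[Recording, GroundTruth]:
    """Render a full synthetic Recording plus its GroundTruth.

    Fully deterministic in (cfg, cfg.seed): the state sequence, each channel's
    noise and the shared signals draw from independent substreams spawned
    from the seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_channels + 2)
    rng_states = np.random.default_rng(children[0])
    rng_mix = np.random.default_rng(children[1])

    global_states = sample_state_sequence(cfg, rng_states)
    per_channel, wave_lags = apply_propagation(global_states, cfg.geometry, cfg)

    traces = np.empty((cfg.n_channels, int(round(cfg.duration * cfg.fs))))
    for i in range(cfg.n_channels):
        rng_i = np.random.default_rng(children[2 + i])
        traces[i] = synthesize_channel(per_channel[i], cfg, rng_i, cfg.channel_gains[i])

    if cfg.shared_fraction > 0 or cfg.global_fraction > 0:
        traces = mix_shared_signal(
            traces, cfg.module_assignment, cfg.shared_fraction, rng_mix,
            global_fraction=cfg.global_fraction, band=cfg.shared_band, fs=cfg.fs)

    rec = Recording(
        signals=traces, fs=cfg.fs, t0=0.0,
        metadata={"seed": cfg.seed, "synthetic": True},
        geometry=cfg.geometry)
    truth = GroundTruth(
        state_intervals=per_channel,
        true_transition_times=[
            np.array([s for lab, s, e in ints if lab == UP]) for ints in per_channel],
        true_wave_lags=wave_lags,
        true_partition=cfg.module_assignment.copy(),
        config=cfg)
    return rec, truth


# Group presets: WT-like baseline; the WBS-like preset differs only in lower
# Up firing rate, lower Up gamma amplitude, higher Down-duration CV, and a
# higher shared (global) correlation fraction.
PRESETS = {
    "WT": {},
    "WBS": {
        "hf_rate_up": 2.35,
        "gamma_amp_up": 8.2,
        "down_cv": 0.60,
        "global_fraction": 0.25,
    },
}
_WT_BASE = dict(shared_fraction=0.25, global_fraction=0.08)
_JITTERED = ("up_mean", "down_mean", "up_cv", "down_cv", "gamma_amp_up",
             "hf_rate_up", "hf_rate_down")


def generate_cohort(preset: str, n_animals: int, seed: int,
                    duration: float = 60.0, n_channels: int = 16,
                    fs: float = 5000.0,
                    geometry: ElectrodeGeometry | None = None,
                    **overrides) -> list[tuple[Recording, GroundTruth]]:
    """Generate a cohort of synthetic animals from a group preset.

    Per-animal parameters are jittered by 5% multiplicative lognormal noise
    around the preset means (jitter RNG seeded from (seed, animal index)),
    giving realistic between-animal variance for group statistics.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    base = dict(_WT_BASE)
    base.update(PRESETS[preset])
    base.update(overrides)
    cohort = []
    for a in range(n_animals):
        jrng = np.random.default_rng(np.random.SeedSequence([seed, a]))
        params = dict(base)
        cfg0 = SyntheticConfig(n_channels=n_channels, fs=fs, duration=duration,
                               geometry=geometry, **params)
        jitter = {name: getattr(cfg0, name) * np.exp(0.05 * jrng.standard_normal())
                  for name in _JITTERED}
        cfg = replace(cfg0, seed=int(jrng.integers(2**31)), **jitter)
        rec, truth = generate_recording(cfg)
        rec.metadata.update({"animal": f"{preset}{a}", "group": preset})
        cohort.append((rec, truth))
    return cohort
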