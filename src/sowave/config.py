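"""Pipeline configuration: every tunable of every stage, with validated defaults.

Loadable from YAML; each field is range-checked at construction time so a
bad config fails at load, not deep inside a stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["MuaConfig", "DetectionConfig", "WaveConfig", "ConnectivityConfig", "PipelineConfig"]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config: {msg}")


@dataclass
class MuaConfig:
    window: float = 0.005        # s, spectrogram window
    step: float = 0.001          # s, spectrogram hop
    band: tuple[float, float] = (200.0, 1500.0)  # Hz, MUA band
    log_floor: float = 1e-3      # floor inside log to survive silent windows
    power_averaging: bool = True  # average normalized power (not amplitude) across bins

    def __post_init__(self) -> None:
        _check(self.window > 0 and self.step > 0, "window/step must be > 0")
        _check(self.step <= self.window, "step must not exceed window")
        _check(0 < self.band[0] < self.band[1], "band must be increasing and positive")
        _check(self.log_floor > 0, "log_floor must be > 0")


@dataclass
class DetectionConfig:
    min_up: float = 0.05         # s, minimum Up duration
    min_down: float = 0.05       # s, minimum Down duration
    smooth_window: float = 0.02  # s, moving-average on log MUA before thresholding
    hist_bins: int = 100         # histogram bins for threshold search
    hist_smooth_bins: float = 3.0  # gaussian sigma (in bins) for histogram smoothing
    slope_window: float = 0.1    # s, window around Down->Up crossing for slope fit
    welch_segment: float = 0.25  # s, Welch segment for Up-state PSD
    bands: dict = field(default_factory=lambda: {
        "alpha": (8.0, 12.0), "beta": (15.0, 32.0), "gamma": (32.0, 100.0)})

    def __post_init__(self) -> None:
        _check(self.min_up > 0 and self.min_down > 0, "minimum durations must be > 0")
        _check(self.smooth_window >= 0, "smooth_window must be >= 0")
        _check(self.hist_bins >= 10, "hist_bins must be >= 10")
        _check(self.slope_window > 0, "slope_window must be > 0")
        for name, (lo, hi) in self.bands.items():
            _check(0 < lo < hi, f"band {name} must be increasing and positive")


@dataclass
class WaveConfig:
    max_span: float = 0.25            # s, transitions within this of a wave's mean merge
    min_channel_fraction: float = 0.5  # "majority of channels" participation rule
    grid_step: float = 0.05           # mm, interpolation grid resolution
    entropy_bins: int = 8             # K for the K x K PC-plane occupancy grid
    speed_ceiling: float = 1e4        # mm/s; gradients flatter than 1/this are masked
    impute_missing: bool = False      # mean-impute missing channels for PCA

    def __post_init__(self) -> None:
        _check(self.max_span > 0, "max_span must be > 0")
        _check(0 < self.min_channel_fraction <= 1, "min_channel_fraction in (0, 1]")
        _check(self.grid_step > 0, "grid_step must be > 0")
        _check(self.entropy_bins >= 2, "entropy_bins must be >= 2")
        _check(self.speed_ceiling > 0, "speed_ceiling must be > 0")


@dataclass
class ConnectivityConfig:
    downsample_to: float = 250.0  # Hz, wideband correlation rate
    butter_order: int = 4         # applied forward-backward (zero phase)
    weight_floor: float = 0.05    # correlations at/below this are absent edges
    n_restarts: int = 20          # Louvain restarts, best Q kept
    resolution: float = 1.0       # Louvain resolution
    complexity_bins: int = 20     # M for functional complexity
    bands: dict = field(default_factory=lambda: {
        "SO": (0.1, 1.0), "alpha": (8.0, 12.0), "beta": (15.0, 32.0),
        "lowgamma": (32.0, 50.0), "midgamma": (50.0, 70.0), "highgamma": (70.0, 100.0)})

    def __post_init__(self) -> None:
        _check(self.downsample_to > 0, "downsample_to must be > 0")
        _check(self.butter_order >= 1, "butter_order must be >= 1")
        _check(0 <= self.weight_floor < 1, "weight_floor in [0, 1)")
        _check(self.n_restarts >= 1, "n_restarts must be >= 1")
        _check(self.complexity_bins >= 2, "complexity_bins must be >= 2")


@dataclass
class PipelineConfig:
    mua: MuaConfig = field(default_factory=MuaConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    waves: WaveConfig = field(default_factory=WaveConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        sub = {"mua": MuaConfig, "detection": DetectionConfig,
               "waves": WaveConfig, "connectivity": ConnectivityConfig}
        for name, typ in sub.items():
            if name in d:
                known = {f.name for f in fields(typ)}
                unknown = set(d[name]) - known
                if unknown:
                    raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
                section = dict(d[name])
                for k in ("band",):
                    if k in section and isinstance(section[k], list):
                        section[k] = tuple(section[k])
                if "bands" in section:
                    section["bands"] = {k: tuple(v) for k, v in section["bands"].items()}
                kwargs[name] = typ(**section)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)
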