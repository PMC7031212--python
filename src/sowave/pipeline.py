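"""End-to-end convenience layer: recording -> per-channel and per-animal metrics.

Thin orchestration over mua/updown/waves/connectivity; every step is the
corresponding module function with the shared PipelineConfig.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectivity import analyze_connectivity
from .io import Recording
from .mua import compute_mua
from .updown import (UP, segment_recording, so_metrics, transition_times,
                     up_state_psd, upward_slope)

__all__ = ["recording_so_metrics", "cohort_so_table"]


def recording_so_metrics(rec: Recording, cfg: PipelineConfig | None = None,
                         channels: list[int] | None = None,
                         compute_psd: bool = True,
                         compute_slope: bool = True) -> pd.DataFrame:
    """Per-channel slow-oscillation metrics of one recording.

    ``channels`` restricts the analysis (e.g. the depth range with the
    highest firing rates); default is all channels.
    """
    cfg = cfg or PipelineConfig()
    mua = compute_mua(rec, cfg.mua)
    seg = segment_recording(mua, cfg.detection)
    channels = channels if channels is not None else list(range(rec.n_channels))
    rows = []
    for i in channels:
        m = so_metrics(seg.intervals[i], mua.mua[i], mua.times)
        row = {"channel": rec.channel_ids[i], "up_dur_mean": m.up_dur_mean,
               "down_dur_mean": m.down_dur_mean, "so_freq": m.so_freq,
               "cv_up": m.cv_up, "cv_down": m.cv_down, "cv_so": m.cv_so,
               "up_fr_rel": m.up_fr_rel, "down_fr": m.down_fr}
        if compute_slope:
            trans = transition_times(seg.intervals[i])
            try:
                row["upward_slope"] = upward_slope(
                    mua.log_mua[i], mua.times, trans, cfg.detection.slope_window,
                    mean_cycle=m.up_dur_mean + m.down_dur_mean)
            except ValueError:
                row["upward_slope"] = np.nan
        if compute_psd:
            psd = up_state_psd(rec.signals[i], rec.fs, seg.intervals[i],
                               cfg.detection.bands, cfg.detection.welch_segment)
            for name, val in psd.items():
                row[f"{name}_psd"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_so_table(cohort, cfg: PipelineConfig | None = None,
                    channels: list[int] | None = None,
                    with_connectivity: bool = False,
                    compute_psd: bool = True,
                    compute_slope: bool = True,
                    seed: int = 0) -> pd.DataFrame:
    """Long-format (animal, group, metric, value) table of channel-averaged metrics.

    ``cohort`` is a list of (Recording, GroundTruth) or plain Recordings.
    With ``with_connectivity`` the wideband graph metrics (Q, L, C, median r)
    are appended per animal.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for item in cohort:
        rec = item[0] if isinstance(item, tuple) else item
        animal = rec.metadata.get("animal", "?")
        group = rec.metadata.get("group", "?")
        df = recording_so_metrics(rec, cfg, channels, compute_psd, compute_slope)
        for metric in df.columns.drop("channel"):
            rows.append((animal, group, metric, float(df[metric].mean())))
        if with_connectivity:
            g = analyze_connectivity(rec, cfg=cfg.connectivity, seed=seed)
            iu = np.triu_indices(g.W.shape[0], k=1)
            rows += [(animal, group, "Q", g.Q), (animal, group, "L", g.L),
                     (animal, group, "C", g.C),
                     (animal, group, "median_r", float(np.median(g.W[iu])))]
    return pd.DataFrame(rows, columns=["animal", "group", "metric", "value"])
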