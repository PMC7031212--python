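"""Estimate MUA from the LFP spectrum and detect Up/Down states.

MUA = 200-1500 Hz spectral power, each bin normalized by its own recording
average (removing electrode gain and 1/f coloring), averaged across the
band.  States come from a histogram-valley threshold on log MUA.
"""

import sowave as sw

rec, truth = sw.generate_recording(sw.SyntheticConfig(duration=60.0, seed=2))

mua = sw.compute_mua(rec)
seg = sw.segment_recording(mua)
m = sw.so_metrics(seg.intervals[0], mua.mua[0], mua.times)

import numpy as np
true_up = np.mean([e - s for lab, s, e in truth.state_intervals[0][1:-1] if lab == "Up"])
true_down = np.mean([e - s for lab, s, e in truth.state_intervals[0][1:-1] if lab == "Down"])

print(f"MUA grand mean (per construction = 1): {mua.mua.mean():.6f}")
print(f"Up duration   {m.up_dur_mean:.3f} s   (this recording's truth {true_up:.3f} s)")
print(f"Down duration {m.down_dur_mean:.3f} s (truth {true_down:.3f} s)")
print(f"SO frequency  {m.so_freq:.2f} Hz (mean per-cycle inverse duration)")
print(f"CV Down       {m.cv_down:.2f}")
print(f"Up/Down firing-rate ratio {m.up_fr_rel:.1f} "
      f"(band SD ratio 3 -> power ratio ~9)")
# Detected durations track the realized ground-truth intervals within a few
# percent; the firing-rate ratio is in normalized band-power units.
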