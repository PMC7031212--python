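"""Reconstruct slow waves on a 32-channel surface grid and map their speed.

Down->Up transitions are clustered into waves, per-wave channel lags are
interpolated with an exact thin-plate spline T(x, y), and the local speed is
V = 1/|grad T|.  Pattern diversity is the entropy of the waves in their
PC1-PC2 plane.
"""

import numpy as np

import sowave as sw

cfg = sw.SyntheticConfig(n_channels=32, geometry=sw.grid_geometry(),
                         duration=60.0, seed=3, wave_speed=20.0)
rec, truth = sw.generate_recording(cfg)

mua = sw.compute_mua(rec)
seg = sw.segment_recording(mua)
trans = [sw.transition_times(ints) for ints in seg.intervals]
ws = sw.cluster_waves(trans, 32)
speeds = sw.wave_speeds(ws, rec.geometry)
entropy = sw.wave_pca_entropy(ws.lag_matrix, impute_missing=True)

print(f"waves detected:      {ws.n_waves} (truth: {truth.true_wave_lags.shape[0]})")
print(f"median speed:        {np.median(speeds):.1f} mm/s (generator 20 mm/s)")
print(f"pattern entropy:     {entropy:.2f} bits (8x8 PC-plane bins)")
# Two alternating planar directions give two clusters in the PC plane; the
# 1 ms detection step spreads each cluster over a few bins, so the entropy
# lands a little above the ideal 1 bit.  A richer wave repertoire raises it.
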