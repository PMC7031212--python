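import numpy as np
import pytest

import sowave as sw
from sowave.updown import (DOWN, UP, choose_threshold, detect_states, so_metrics,
                           task_normalized_fr, up_state_psd, upward_slope)


def test_threshold_splits_two_gaussian_mixture(rng):
    """Equal-weight modes at log levels -2 and 0 -> valley near -1."""
    x = np.concatenate([rng.normal(-2.0, 0.3, 20000), rng.normal(0.0, 0.3, 20000)])
    thr = choose_threshold(x)
    assert thr == pytest.approx(-1.0, abs=0.15)


def test_threshold_rejects_constant_trace():
    with pytest.raises(ValueError, match="bistability"):
        choose_threshold(np.zeros(1000))


def test_threshold_unimodal_fallback(rng):
    x = rng.normal(0.0, 1.0, 20000)
    thr = choose_threshold(x)
    lo, hi = np.percentile(x, [10, 90])
    assert thr == pytest.approx(0.5 * (lo + hi), abs=0.2)


def test_noiseless_square_wave_recovered_exactly():
    """0.4 s high / 0.85 s low square log MUA -> boundaries within one step."""
    step = 0.001
    times = np.arange(0, 20, step)
    phase = np.mod(times, 1.25)
    x = np.where(phase >= 0.85, 1.0, -1.0)
    ints = detect_states(x, times, 0.0, 0.05, 0.05)
    ups = [(s, e) for lab, s, e in ints if lab == UP]
    for s, e in ups[1:-1]:
        assert abs((s - 0.85) % 1.25) < step + 1e-9 or abs(1.25 - (s - 0.85) % 1.25) < step + 1e-9
        assert e - s == pytest.approx(0.4, abs=2 * step)
    assert all(ints[k][0] != ints[k + 1][0] for k in range(len(ints) - 1))


def test_brief_glitch_absorbed_by_refractory_rule():
    """A 2 ms supra-threshold blip inside a Down state does not split it."""
    step = 0.001
    times = np.arange(0, 10, step)
    phase = np.mod(times, 1.25)
    x = np.where(phase >= 0.85, 1.0, -1.0)
    clean = detect_states(x, times, 0.0, 0.05, 0.05)
    glitch = x.copy()
    i = np.argmax(phase > 0.4)  # mid-Down
    glitch[i:i + 2] = 1.0
    with_glitch = detect_states(glitch, times, 0.0, 0.05, 0.05)
    assert len(with_glitch) == len(clean)
    assert all(a[0] == b[0] for a, b in zip(with_glitch, clean))


def test_empty_trace_rejected():
    with pytest.raises(ValueError, match="empty"):
        detect_states(np.array([]), np.array([]), 0.0)


def _periodic_intervals(up, down, n):
    ints = []
    t = 0.0
    for _ in range(n):
        ints.append((DOWN, t, t + down))
        ints.append((UP, t + down, t + down + up))
        t += up + down
    return ints


def test_so_metrics_periodic():
    """0.4/0.85 s periodic states: SO frequency 0.8 Hz, all CVs zero."""
    m = so_metrics(_periodic_intervals(0.4, 0.85, 20))
    assert m.so_freq == pytest.approx(0.8)
    assert m.cv_up == pytest.approx(0, abs=1e-12)
    assert m.cv_down == pytest.approx(0, abs=1e-12)
    assert m.cv_so == pytest.approx(0, abs=1e-12)
    assert m.up_dur_mean == pytest.approx(0.4)
    assert m.down_dur_mean == pytest.approx(0.85)


def test_cv_down_hand_computed():
    """Down durations {0.5, 1.0, 1.5}: population CV = 0.4082/1.0."""
    ints = [("Up", 0.0, 0.4)]
    t = 0.4
    for d in (0.5, 1.0, 1.5):
        ints.append(("Down", t, t + d)); t += d
        ints.append(("Up", t, t + 0.4)); t += 0.4
    m = so_metrics(ints)  # edge Ups excluded; interior Downs are exactly these
    downs = np.array([0.5, 1.0, 1.5])
    assert m.cv_down == pytest.approx(downs.std() / downs.mean(), rel=1e-12)
    assert m.cv_down == pytest.approx(0.408, abs=1e-3)


def test_metrics_scale_equivariance():
    """Doubling all durations halves so_freq and leaves CVs unchanged."""
    rng = np.random.default_rng(0)
    ints = []
    t = 0.0
    for _ in range(30):
        d, u = rng.uniform(0.5, 1.2), rng.uniform(0.2, 0.6)
        ints.append((DOWN, t, t + d)); t += d
        ints.append((UP, t, t + u)); t += u
    scaled = [(lab, 2 * s, 2 * e) for lab, s, e in ints]
    m1, m2 = so_metrics(ints), so_metrics(scaled)
    assert m2.so_freq == pytest.approx(m1.so_freq / 2)
    assert m2.cv_up == pytest.approx(m1.cv_up)
    assert m2.cv_down == pytest.approx(m1.cv_down)
    assert m2.cv_so == pytest.approx(m1.cv_so)


def test_so_metrics_needs_cycles():
    with pytest.raises(ValueError, match="cycles"):
        so_metrics(_periodic_intervals(0.4, 0.85, 1))


def test_upward_slope_step_approaches_vertical():
    """An instantaneous Down->Up step fitted in a 10 ms window is >= 85 deg."""
    times = np.arange(0, 20, 0.001)
    trans = np.arange(1.0, 19.0, 1.25)
    x = np.zeros_like(times)
    for t0 in trans:
        x[(times >= t0) & (times < t0 + 0.4)] = 1.0
    ang = upward_slope(x, times, trans, fit_window=0.01, mean_cycle=1.25, span=1.0)
    assert ang >= 85.0


@pytest.mark.parametrize("rise_per_unit,expected", [(1.0, 45.0), (0.5, 26.565)])
def test_upward_slope_linear_ramp(rise_per_unit, expected):
    """A ramp rising `rise_per_unit` span units per cycle unit -> arctan slope."""
    mean_cycle = 1.0
    times = np.arange(0, 20, 0.001)
    trans = np.arange(1.0, 19.0, 2.0)
    x = np.zeros_like(times)
    for t0 in trans:
        seg = (times >= t0 - 0.25) & (times < t0 + 0.25)
        x[seg] = (times[seg] - (t0 - 0.25)) / mean_cycle * rise_per_unit
    ang = upward_slope(x, times, trans, fit_window=0.2, mean_cycle=mean_cycle, span=1.0)
    assert ang == pytest.approx(expected, abs=0.2)


def test_upward_slope_needs_transitions():
    times = np.arange(0, 5, 0.001)
    with pytest.raises(ValueError, match="transitions"):
        upward_slope(np.zeros_like(times), times, np.array([1.0, 2.0]))


def test_up_state_psd_concentrates_sinusoid_in_gamma():
    """A 40 Hz tone present only in Up states shows up in gamma, not alpha/beta."""
    fs, A = 1000.0, 5.0
    ints = _periodic_intervals(1.0, 1.0, 15)
    t = np.arange(int(30 * fs)) / fs
    x = 0.01 * np.random.default_rng(0).standard_normal(len(t))
    for lab, s, e in ints:
        if lab == UP:
            seg = (t >= s) & (t < e)
            x[seg] += A * np.sin(2 * np.pi * 40.0 * t[seg])
    psd = up_state_psd(x, fs, ints)
    gamma_bandwidth = 100.0 - 32.0
    assert psd["gamma"] == pytest.approx(A**2 / 2 / gamma_bandwidth, rel=0.15)
    assert psd["alpha"] < 0.01 * psd["gamma"]
    assert psd["beta"] < 0.01 * psd["gamma"]


def test_up_state_psd_power_scales_with_amplitude_squared():
    fs = 1000.0
    ints = _periodic_intervals(1.0, 1.0, 12)
    t = np.arange(int(24 * fs)) / fs
    rng = np.random.default_rng(1)

    def make(A):
        x = 0.01 * rng.standard_normal(len(t))
        for lab, s, e in ints:
            if lab == UP:
                seg = (t >= s) & (t < e)
                x[seg] += A * np.sin(2 * np.pi * 40.0 * t[seg])
        return up_state_psd(x, fs, ints)["gamma"]

    assert make(6.0) / make(3.0) == pytest.approx(4.0, rel=0.10)


def test_up_state_psd_band_above_nyquist_rejected():
    ints = _periodic_intervals(1.0, 1.0, 10)
    x = np.zeros(int(20 * 100))
    with pytest.raises(ValueError, match="Nyquist"):
        up_state_psd(x, 100.0, ints, bands={"gamma": (32.0, 100.0)})


def test_task_normalized_fr():
    times = np.arange(0, 100, 0.1)
    mua = np.ones_like(times)
    c, v = task_normalized_fr(mua, times, t_task_start=10.0, window=5.0)
    assert np.allclose(v, 1.0)
    halved = np.where(times < 20.0, 1.0, 0.5)
    c, v = task_normalized_fr(halved, times, t_task_start=10.0, window=5.0)
    assert v[0] == pytest.approx(1.0)
    assert np.allclose(v[3:], 0.5)
    with pytest.raises(ValueError, match="cover"):
        task_normalized_fr(mua, times, t_task_start=99.0, window=5.0)


def test_detection_recovers_generator_truth(wt_recording, wt_mua, wt_segmentation):
    """End-to-end: detected durations track the generator's intervals within 10%."""
    rec, truth = wt_recording
    errs_up, errs_down = [], []
    for ch in range(rec.n_channels):
        m = sw.so_metrics(wt_segmentation.intervals[ch])
        tu = np.mean([e - s for lab, s, e in truth.state_intervals[ch][1:-1] if lab == UP])
        td = np.mean([e - s for lab, s, e in truth.state_intervals[ch][1:-1] if lab == DOWN])
        errs_up.append(abs(m.up_dur_mean - tu) / tu)
        errs_down.append(abs(m.down_dur_mean - td) / td)
    assert np.median(errs_up) < 0.10
    assert np.median(errs_down) < 0.10


def test_segmentation_alternates_and_tiles(wt_segmentation, wt_recording):
    rec, _ = wt_recording
    for ints in wt_segmentation.intervals:
        for k in range(1, len(ints)):
            assert ints[k][0] != ints[k - 1][0]
            assert ints[k][1] == pytest.approx(ints[k - 1][2])
        assert ints[-1][2] - ints[0][1] == pytest.approx(rec.duration, abs=0.05)
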