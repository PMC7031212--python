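import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sowave as sw
from sowave.connectivity import _upper


# ---------------------------------------------------------------- preprocess

def test_bandpass_preserves_passband_tone_with_zero_phase():
    """40 Hz through 32-50 Hz: amplitude within 5%, no phase shift."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    rec = sw.Recording(np.sin(2 * np.pi * 40.0 * t)[None, :], fs=fs)
    x, fs2 = sw.preprocess(rec, fs, band=(32.0, 50.0))
    mid = slice(int(fs), -int(fs))  # ignore filter edges
    ref = np.sin(2 * np.pi * 40.0 * t)[mid]
    out = x[0][mid]
    amp = np.sqrt(2) * out.std()
    assert amp == pytest.approx(1.0, rel=0.05)
    # zero-phase: projection onto the quadrature component is negligible (<1 deg)
    quad = np.cos(2 * np.pi * 40.0 * t)[mid]
    phase = np.arctan2(2 * np.mean(out * quad), 2 * np.mean(out * ref))
    assert abs(np.degrees(phase)) < 1.0


def test_bandpass_stopband_attenuation():
    """A 40 Hz tone through the 8-12 Hz band is suppressed by >= 40 dB."""
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    rec = sw.Recording(np.sin(2 * np.pi * 40.0 * t)[None, :], fs=fs)
    x, _ = sw.preprocess(rec, fs, band=(8.0, 12.0))
    power_ratio = x[0][int(fs):-int(fs)].var() / 0.5
    assert 10 * np.log10(power_ratio) < -40


def test_downsampling_preserves_low_frequency_waveform():
    fs = 5000.0
    t = np.arange(int(4 * fs)) / fs
    rec = sw.Recording(np.sin(2 * np.pi * 10.0 * t)[None, :], fs=fs)
    x, fs2 = sw.preprocess(rec, 250.0)
    assert fs2 == 250.0
    t2 = np.arange(x.shape[1]) / fs2
    ref = np.sin(2 * np.pi * 10.0 * t2)
    mid = slice(50, -50)
    r = np.corrcoef(x[0][mid], ref[mid])[0, 1]
    assert r > 0.999


def test_band_above_nyquist_after_downsampling_rejected():
    rec = sw.Recording(np.random.default_rng(0).standard_normal((2, 20000)), fs=5000.0)
    with pytest.raises(ValueError, match="Nyquist"):
        sw.preprocess(rec, 100.0, band=(32.0, 60.0))


# ------------------------------------------------------- correlation matrix

def test_correlation_duplicate_and_negated_channels(rng):
    x = rng.standard_normal(2000)
    W = sw.correlation_matrix(np.vstack([x, x, -x]))
    assert W[0, 1] == pytest.approx(1.0, abs=1e-12)
    assert W[0, 2] == pytest.approx(-1.0, abs=1e-12)
    assert np.allclose(W, W.T) and np.allclose(np.diag(W), 1.0)


def test_correlation_rejects_dead_channel(rng):
    x = np.vstack([rng.standard_normal(100), np.zeros(100)])
    with pytest.raises(ValueError, match="1"):
        sw.correlation_matrix(x)


def test_correlation_distribution_identical_and_shifted(rng):
    W = sw.correlation_matrix(rng.standard_normal((10, 3000)))
    res = sw.correlation_distribution(W, W)
    assert res["ks_D"] == 0.0 and res["ks_p"] == pytest.approx(1.0)
    # location shift: medians move by ~ the shift and KS flags it
    Ws = [sw.correlation_matrix(rng.standard_normal((32, 3000))) for _ in range(8)]
    Wb = [np.clip(W + 0.2, -1, 1) for W in Ws]
    for W in Wb:
        np.fill_diagonal(W, 1.0)
    res = sw.correlation_distribution(Ws, Wb)
    assert res["median_b"] - res["median_a"] == pytest.approx(0.2, abs=0.02)
    assert res["ks_p"] < 0.01


# ------------------------------------------------------------ distance / Q / L

def test_weight_to_distance_spot_values():
    W = np.array([[1.0, 0.5, -0.3], [0.5, 1.0, 1.0], [-0.3, 1.0, 1.0]])
    D = sw.weight_to_distance(W)
    assert D[0, 1] == 2.0          # 1/0.5
    assert D[1, 2] == 1.0          # 1/1
    assert np.isinf(D[0, 2])       # negative correlation: absent edge
    assert np.all(np.diag(D) == 0)


def _all_partitions(nodes):
    """Every set partition (Bell number enumeration)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for smaller in _all_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller


def test_louvain_matches_exhaustive_modularity_on_two_cliques():
    """Two disconnected 4-cliques: Louvain Q equals the brute-force maximum."""
    W = np.zeros((8, 8))
    for blk in (range(0, 4), range(4, 8)):
        for i, j in itertools.combinations(blk, 2):
            W[i, j] = W[j, i] = 1.0
    np.fill_diagonal(W, 1.0)
    part, Q = sw.louvain_modularity(W, n_restarts=5, seed=0)
    G = nx.Graph()
    G.add_nodes_from(range(8))
    for i, j in zip(*np.triu_indices(8, 1)):
        if W[i, j] > 0:
            G.add_edge(int(i), int(j), weight=W[i, j])
    best = max(nx.community.modularity(G, [set(b) for b in p], weight="weight")
               for p in _all_partitions(list(range(8))))
    assert Q == pytest.approx(best, abs=1e-12)
    assert len(set(part[:4])) == 1 and len(set(part[4:])) == 1
    assert part[0] != part[4]


def test_uniform_complete_graph_has_no_structure():
    W = np.full((12, 12), 0.5)
    np.fill_diagonal(W, 1.0)
    _, Q = sw.louvain_modularity(W, n_restarts=5, seed=1)
    assert Q <= 0.05


def test_planted_two_block_partition_recovered():
    """Within 0.6 / between 0.1 blocks, 32 nodes: partition found reliably."""
    hits = 0
    n_seeds = 20
    rng = np.random.default_rng(7)
    for s in range(n_seeds):
        W = np.full((32, 32), 0.1) + rng.normal(0, 0.01, (32, 32))
        W = 0.5 * (W + W.T)
        W[:16, :16] = 0.6
        W[16:, 16:] = 0.6
        np.fill_diagonal(W, 1.0)
        part, _ = sw.louvain_modularity(W, n_restarts=5, seed=s)
        if len(set(part[:16])) == 1 and len(set(part[16:])) == 1 and part[0] != part[16]:
            hits += 1
    assert hits >= 0.95 * n_seeds


def test_path_length_complete_graph():
    """All W = 0.5: direct edges are optimal, L = 2."""
    W = np.full((10, 10), 0.5)
    np.fill_diagonal(W, 1.0)
    L, unreachable = sw.characteristic_path_length(sw.weight_to_distance(W))
    assert L == 2.0 and unreachable == 0.0


def test_path_length_three_node_line():
    """W = {0.5, 0.5} chain: d(1,3) = 4 via the middle node, L = 8/3."""
    W = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.5], [0.0, 0.5, 1.0]])
    L, _ = sw.characteristic_path_length(sw.weight_to_distance(W))
    assert L == pytest.approx((2 + 4 + 2) / 3)


def _floyd_warshall(D):
    n = D.shape[0]
    sp = D.copy()
    sp[~np.isfinite(sp)] = np.inf
    np.fill_diagonal(sp, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if sp[i, k] + sp[k, j] < sp[i, j]:
                    sp[i, j] = sp[i, k] + sp[k, j]
    off = ~np.eye(n, dtype=bool)
    fin = np.isfinite(sp) & off
    return sp[fin].mean()


def test_path_length_matches_floyd_warshall_oracle():
    """Dijkstra-based L equals brute-force Floyd-Warshall on random graphs."""
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = rng.integers(4, 11)
        W = rng.uniform(-0.2, 1.0, (n, n))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 1.0)
        D = sw.weight_to_distance(W)
        try:
            L, _ = sw.characteristic_path_length(D)
        except ValueError:
            continue
        assert L == pytest.approx(_floyd_warshall(D), abs=1e-12)


# --------------------------------------------------------------- complexity

def test_complexity_delta_and_uniform_are_exact(rng):
    Wd = np.full((10, 10), 0.5)
    np.fill_diagonal(Wd, 1.0)
    assert sw.functional_complexity(Wd, 10) == 0.0
    vals = (np.arange(45) + 0.5) / 45  # exactly uniform occupancy over 9 bins
    Wu = np.zeros((10, 10))
    iu = np.triu_indices(10, 1)
    Wu[iu] = vals
    Wu = Wu + Wu.T
    np.fill_diagonal(Wu, 1.0)
    assert sw.functional_complexity(Wu, 9) == 1.0


def test_complexity_two_spike_hand_value():
    """Half the mass in bin 1, half in bin 10 (M=10): C = 1 - (10/18)*1.6."""
    W = np.zeros((9, 9))
    iu = np.triu_indices(9, 1)
    W[iu] = np.concatenate([np.full(18, 0.05), np.full(18, 0.95)])
    W = W + W.T
    np.fill_diagonal(W, 1.0)
    assert sw.functional_complexity(W, 10) == pytest.approx(1 - (10 / 18) * 1.6, abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), m=st.integers(2, 40))
def test_complexity_bounded(seed, m):
    rng = np.random.default_rng(seed)
    W = np.clip(rng.uniform(-1, 1, (12, 12)), -1, 1)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    assert 0.0 <= sw.functional_complexity(W, m) <= 1.0


# ---------------------------------------------------------------- band sweep

def test_band_limited_shared_signal_elevates_only_its_band(rng):
    """Common signal confined to 50-70 Hz raises only mid-gamma correlations."""
    fs, n = 1000.0, 60_000
    from sowave.synth import _unit_bandpassed
    common = _unit_bandpassed(n, fs, (55.0, 65.0), rng)
    x = rng.standard_normal((12, n)) + 1.2 * common
    rec = sw.Recording(x, fs=fs)
    cfg = sw.ConnectivityConfig(n_restarts=3)
    med = {}
    for name, band in cfg.bands.items():
        if name == "SO":
            continue
        sig, _ = sw.preprocess(rec, min(4 * band[1], fs), band, cfg.butter_order)
        W = sw.correlation_matrix(sig)
        med[name] = np.median(_upper(W))
    assert med["midgamma"] > 0.5
    assert med["midgamma"] == max(med.values())
    # bands not adjacent to the shared content stay at the independence floor
    for name in ("alpha", "beta"):
        assert med[name] < 0.15


def test_analyze_connectivity_end_to_end(wt_recording):
    rec, _ = wt_recording
    g = sw.analyze_connectivity(rec, seed=0)
    assert g.W.shape == (16, 16)
    assert np.allclose(g.W, g.W.T) and np.allclose(np.diag(g.W), 1.0)
    assert np.all(np.diag(g.D) == 0)
    assert -0.5 <= g.Q <= 1.0
    assert g.L >= 1.0
    assert 0.0 <= g.C <= 1.0


def test_shared_fraction_raises_correlation_and_lowers_path_length():
    """Paired seeds: more shared signal -> higher median r, lower L."""
    wins = 0
    for s in range(5):
        r, L = [], []
        for frac in (0.1, 0.5):
            cfg = sw.SyntheticConfig(duration=20.0, seed=100 + s,
                                     shared_fraction=frac,
                                     module_assignment=np.zeros(16, int))
            rec, _ = sw.generate_recording(cfg)
            g = sw.analyze_connectivity(rec, seed=s)
            r.append(np.median(_upper(g.W)))
            L.append(g.L)
        if r[1] > r[0] and L[1] < L[0]:
            wins += 1
    assert wins >= 4
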