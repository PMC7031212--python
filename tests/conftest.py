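import numpy as np
import pytest

import sowave as sw


@pytest.fixture(scope="session")
def wt_recording():
    """One 30 s WT-preset-like recording with ground truth (session-cached)."""
    cfg = sw.SyntheticConfig(duration=30.0, seed=42)
    return sw.generate_recording(cfg)


@pytest.fixture(scope="session")
def wt_mua(wt_recording):
    rec, _ = wt_recording
    return sw.compute_mua(rec)


@pytest.fixture(scope="session")
def wt_segmentation(wt_mua):
    return sw.segment_recording(wt_mua)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
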