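import numpy as np
import pytest

import faceflow as ff


@pytest.fixture(scope="session")
def scheme():
    return ff.default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_series(scheme):
    """A short raw series with one empty frame (frame 3)."""
    rng = np.random.default_rng(7)
    template = ff.canonical_face(scheme, seed=7)
    cfg = ff.SimulationConfig(T=10, missing_rate=0.0, seed=7)
    series, _ = ff.simulate_series(cfg, template, scheme, video_id="small",
                                   rng=np.random.default_rng(7))
    coords = series.coords.copy()
    conf = series.confidence.copy()
    coords[3] = 0.0
    conf[3] = 0.0
    return ff.LandmarkSeries(
        video_id="small", animal_id="a0", fps=25.0,
        coords=coords, confidence=conf, label="positive",
    )


@pytest.fixture()
def normalized_series(small_series, scheme):
    return ff.normalize_series(small_series, scheme)
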