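import numpy as np
import pytest

import physioevents as pe


@pytest.fixture(scope="session")
def mary_session():
    rec, ann = pe.reference_session("mary_like", seed=0)
    clean = pe.preprocess(rec)
    sqi = pe.score_quality(clean.t2, clean.eda, clean.temp)
    return rec, ann, clean, sqi


@pytest.fixture
def small_recording():
    """30 s noiseless three-channel recording at 15 Hz."""
    n = 450
    t = np.arange(n) / 15.0
    return pe.PhysioRecording(
        session_id="small",
        t=t,
        eda=np.full(n, 2.0),
        temp=np.full(n, 33.0),
        hr=np.full(n, 70.0),
        fs=15.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
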