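import numpy as np
import pytest

from hrdelay.design import StudyDesign
from hrdelay.pipeline import analyze_participant
from hrdelay.synth import GeneratorParams, build_ground_truth, simulate_study


@pytest.fixture(scope="session")
def design():
    """Desk-scale study design: study timing, 5 triplets per session."""
    return StudyDesign(n_triplets_per_session=5)


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def effect_participant(design):
    """One synthetic participant with the default (tuned amplitude +
    plaid delay shift) condition effects, sessions simulated and the
    selection cascade fitted per session."""
    params = GeneratorParams()
    truth, meta = build_ground_truth(design, 80, params, seed=101)
    sessions = simulate_study(design, truth, seed=202, params=params, meta=meta)
    selectors = analyze_participant(sessions)
    return truth, sessions, selectors


@pytest.fixture(scope="session")
def null_participant(design):
    """One synthetic participant with zero condition effects."""
    params = GeneratorParams.null()
    truth, meta = build_ground_truth(design, 60, params, seed=303)
    sessions = simulate_study(design, truth, seed=404, params=params, meta=meta)
    selectors = analyze_participant(sessions)
    return truth, sessions, selectors


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
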