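import numpy as np
import pytest

from onestepqtc import AnimalParams, ScenarioConfig, analyze_study, simulate_study


@pytest.fixture(scope="session")
def null_study():
    """A small 4-animal crossover with no drug effect (8 h sessions)."""
    return simulate_study(ScenarioConfig(
        study_id="null_fixture", n_animals=4, session_hours=8.0,
        dose_time_h=2.0, seed=20, drug=None))


@pytest.fixture(scope="session")
def null_result(null_study):
    return analyze_study(null_study.manifest, null_study.beats,
                         models=("onestep",))


@pytest.fixture()
def quiet_params():
    """Deterministic physiology: no noise channels, negligible QT lag."""
    return AnimalParams(circadian_amp=0.0, autonomic_sd=0.0,
                        qt_autonomic_sd=0.0, qt_noise_sd=0.0,
                        hysteresis_tau=1e-3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
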