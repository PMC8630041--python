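import pytest

from rlci import ModelParams, StimulusConfig, simulate_experiment


@pytest.fixture(scope="session")
def config_fast():
    """Fast ramp: short RTs, cheap simulations."""
    return StimulusConfig(alpha=0.2)


@pytest.fixture(scope="session")
def params():
    """The fitted observer constants shipped as defaults."""
    return ModelParams()


@pytest.fixture(scope="session")
def small_log(config_fast, params):
    """300 trials at alpha = 0.2, reused across analysis tests."""
    return simulate_experiment(config_fast, params, 300, seed=1234)


@pytest.fixture(scope="session")
def usable_records(small_log):
    return [r for r in small_log.records if r.correct and not r.timeout]
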