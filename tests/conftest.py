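import pytest

from streamghg.pipeline import run_pipeline
from streamghg.synthetic import (
    CatchmentScenario,
    generate_catchment,
    true_reach_day_table,
)


@pytest.fixture(scope="session")
def zero_noise_case():
    """Zero-noise scenario: data bundle, pipeline result and truth table."""
    scenario = CatchmentScenario(seed=1, zero_noise=True)
    inputs = generate_catchment(scenario)
    result = run_pipeline(inputs)
    truth = true_reach_day_table(scenario, inputs)
    return scenario, inputs, result, truth


@pytest.fixture(scope="session")
def noisy_case():
    """Default (noisy) scenario with its pipeline result and truth table."""
    scenario = CatchmentScenario(seed=2)
    inputs = generate_catchment(scenario)
    result = run_pipeline(inputs)
    truth = true_reach_day_table(scenario, inputs)
    return scenario, inputs, result, truth
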