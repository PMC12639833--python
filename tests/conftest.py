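import pytest

from pabseq import pipeline, simulate


@pytest.fixture(scope="session")
def bundle_one():
    """One-antibody simulation bundle shared across tests."""
    scenario = simulate.SimScenario(n_antibodies=1, seed=11)
    return simulate.simulate_scenario(scenario)


@pytest.fixture(scope="session")
def result_one(bundle_one):
    """Full pipeline result on the one-antibody bundle."""
    inputs = pipeline.InputBundle.from_simulation(bundle_one)
    return pipeline.run_pipeline(inputs)
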