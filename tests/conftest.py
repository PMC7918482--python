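import pytest

from acetylfq import RunConfig, SimulationConfig, build_truth, run_pipeline, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete simulated two-phase experiment."""
    truth = build_truth(SimulationConfig(n_proteins=60), seed=11)
    return simulate_experiment(truth, seed=12)


@pytest.fixture(scope="session")
def small_result(small_experiment):
    """Pipeline output for the small experiment."""
    return run_pipeline(
        RunConfig(),
        proteome_psms=small_experiment.proteome_psms,
        kac_psms=small_experiment.kac_psms,
        annotations=small_experiment.annotations,
    )
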