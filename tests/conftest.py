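import numpy as np
import pytest

from plastisim import (
    EvolutionConfig,
    MutationRates,
    RegulationParams,
    develop_batch,
    make_fixture,
    run_simulation,
)


@pytest.fixture(scope="session")
def params():
    return RegulationParams()


@pytest.fixture(scope="session")
def feedback_batches(params):
    """Low-environment redevelopments of the feedback circuit and its
    mean-matched open-loop control, shared by the noise-buffering tests."""
    n = 1500
    rng = np.random.default_rng(2024)
    perf = develop_batch(make_fixture("perf_feedback"), "performance", 1000.0, n, params, rng)
    open_loop = develop_batch(make_fixture("open_loop_matched"), "none", 1000.0, n, params, rng)
    return perf, open_loop


@pytest.fixture(scope="session")
def mini_experiment_records():
    """Reduced-scale no-signal, constant-low evolutionary replicates
    (N = 100, 150 generations, desk mutation rates), shared between the
    adaptation and plasticity-fraction checks."""
    cfg = EvolutionConfig(
        N=100,
        generations=150,
        treatment="no_signal",
        environment_model="constant_low",
        mutation_rates=MutationRates().scaled(100.0),
        n_found=200,
        assay_n_redevelop=500,
    )
    return [run_simulation(cfg, seed=1000 + i) for i in range(4)]
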