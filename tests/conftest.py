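import numpy as np
import pytest

from cvpop import default_parameters, run_to_steady_state
from cvpop.calibration import ChainConfig, build_population
from cvpop.hemorrhage import run_protocol
from cvpop.target_density import fit_kde, surrogate_sample
from cvpop.workbench import RunConfig, analyze_run, calibrate_run, hemorrhage_run

MASTER_SEED = 1


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline(params):
    """Best-fit steady state shared across tests."""
    state, eq = run_to_steady_state(params)
    return state, eq


@pytest.fixture(scope="session")
def small_population(params):
    """A 60-patient population (3 chains) for module-level tests."""
    samples = surrogate_sample(500, np.random.default_rng(123))
    density = fit_kde(samples)
    cfg = ChainConfig(restarts=3, seed=123)
    return build_population(density, params, cfg, target_samples=samples), samples


@pytest.fixture(scope="session")
def small_hemorrhaged(small_population):
    """The small population with hemorrhage outcomes merged in."""
    pop, _ = small_population
    frame, results, excluded = run_protocol(pop.patients)
    assert not excluded
    return pop.table.merge(frame, on="patient"), results


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One full calibrate -> hemorrhage -> analyze run at the default scale.

    Session-scoped: the acceptance tests all read from this single run.
    """
    out = tmp_path_factory.mktemp("full_run")
    cfg = RunConfig()
    calibrate_run(cfg, MASTER_SEED, out)
    merged = hemorrhage_run(cfg, MASTER_SEED, out)
    report = analyze_run(cfg, MASTER_SEED, out, table=merged)
    return dict(out=out, table=merged, report=report,
                population=calibrate_run.last_population,
                results=hemorrhage_run.last_results)
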