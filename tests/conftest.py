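import numpy as np
import pytest

import genotoxikk as gx


@pytest.fixture(scope="session")
def bestfit() -> gx.ParameterSet:
    return gx.best_fit()


@pytest.fixture(scope="session")
def traj15(bestfit) -> gx.Trajectory:
    """The 15 Gy reference trajectory used across the analysis tests."""
    return gx.simulate(bestfit, gx.StimulusProtocol.from_dose(15.0), horizon=30000.0)


@pytest.fixture(scope="session")
def ss15(bestfit) -> gx.SteadyStateResult:
    return gx.stimulated_steady_state(bestfit, gx.StimulusProtocol.from_dose(15.0))


def random_states(params, n, seed=0):
    """Random strictly positive model states spanning realistic magnitudes."""
    rng = np.random.default_rng(seed)
    scales = 10.0 ** rng.uniform(0, 5, size=(n, gx.model.N_SPECIES))
    return scales * rng.uniform(0.1, 1.0, size=scales.shape)
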