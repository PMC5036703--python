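import numpy as np
import pytest
from hypothesis import settings

import admitsem as a

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_sim():
    """A 40-practice synthetic dataset at the study-default truths."""
    return a.simulate_practice_table(a.GeneratorConfig(I=40), seed=7)


@pytest.fixture(scope="session")
def fitted_model3(small_sim):
    """A short model-3 fit reused by criticism/diagnostics tests."""
    model = a.AdmissionsSEM(small_sim.table, a.ModelConfig(model_id=3))
    return model.fit(chains=2, iterations=1200, burn_in=600, thin=3, seed=11)


@pytest.fixture()
def tiny_table():
    """Hand-built 3-practice table with simple counts."""
    rng = np.random.default_rng(0)
    return a.PracticeTable(
        practice_id=["alpha", "beta", "gamma"],
        Z=np.array([[8, 5], [9, 6], [7, 4]]),
        N=np.array([[10, 10], [10, 10], [10, 10]]),
        W=np.array([[1, 2], [0, 1], [3, 2]]),
        V=np.array([[20, 20], [20, 20], [20, 20]]),
        Y=np.array([4, 2, 6]),
        E=np.array([4.0, 4.0, 4.0]),
        D=np.array([1.0, 2.0, 3.0]),
        Mrate=np.array([5.0, 6.0, 7.5]),
        S1=np.array([0.5, 0.6, 0.7]),
        S2=np.array([4.0, 7.0, 9.0]),
    )
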