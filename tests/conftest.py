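import numpy as np
import pytest

from burstfusion import make_task_config
from burstfusion.task import batch_arrays, sample_batch


@pytest.fixture(scope="session")
def k1_batch():
    """Moderate k=1 batch at the standard parameters (shared across tests)."""
    config = make_task_config(kind="fixed", k=1, seed=101)
    trials = sample_batch(config, 4000, seed=101)
    m, x, e = batch_arrays(trials)
    return config, m, x, e


@pytest.fixture(scope="session")
def k3_batch():
    """Moderate k=3 batch (temporal structure present)."""
    config = make_task_config(kind="fixed", k=3, seed=202)
    trials = sample_batch(config, 4000, seed=202)
    m, x, e = batch_arrays(trials)
    return config, m, x, e


@pytest.fixture(scope="session")
def tiny_config():
    """Tiny task where exact marginalisation is feasible: n=4, Levy L_max=2.

    The sparsity target must exceed the feasibility bound
    E[L] / (n + E[L] - 1) = 1.2 / 4.2, so the tiny task runs denser than the
    standard one.
    """
    return make_task_config(kind="levy", l_max=2, n=4, p_e=0.4, seed=7)
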