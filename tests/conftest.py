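import numpy as np
import pytest

from mrsig.cohort import SimulationConfig, simulate_cohort
from mrsig.containers import ExpressionMatrix, SurvivalOutcome, outcomes_from_arrays


def make_outcomes(times, etypes):
    """Outcome list with synthetic ids s0, s1, ... (event iff type 1)."""
    ids = [f"s{i}" for i in range(len(times))]
    return outcomes_from_arrays(ids, np.asarray(times, dtype=float), np.asarray(etypes))


def random_survival(rng, n, beta=0.0, censor_scale=1.5, x=None):
    """Simple exponential PH draw used by oracle tests; returns (x, outcomes)."""
    if x is None:
        x = rng.standard_normal(n)
    t = rng.exponential(np.exp(-beta * x))
    c = rng.exponential(censor_scale, n)
    time = np.maximum(np.minimum(t, c), 1e-9)
    etype = np.where(t <= c, 1, 0)
    return x, make_outcomes(time, etype)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a real planted signal, shared by several test modules."""
    config = SimulationConfig(
        n_samples=150, n_genes=400, n_prognostic=20, effect_size=0.7, seed=42
    )
    return config, simulate_cohort(config)


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        ["g1", "g2"], ["a", "b"], np.array([[1.0, 2.0], [3.0, 6.0]])
    )
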