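import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sheltering import CONDITIONED_PARAMS, NAIVE_PARAMS, GroupComposition

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params_by_type():
    return {"naive": NAIVE_PARAMS, "conditioned": CONDITIONED_PARAMS}


@pytest.fixture(scope="session")
def naive_composition(params_by_type):
    return GroupComposition(10, 0, params_by_type)


@pytest.fixture(scope="session")
def conditioned_composition(params_by_type):
    return GroupComposition(0, 10, params_by_type)


@pytest.fixture(scope="session")
def mixed_composition(params_by_type):
    return GroupComposition(4, 6, params_by_type)


def make_table(rows):
    """Tiny long-format trial table from (trial, time, ps, cs, out) tuples."""
    return pd.DataFrame(
        [
            {"trial_id": t, "condition": "c", "type": "naive",
             "time_min": tm, "n_ps": ps, "n_cs": cs, "n_out": out}
            for (t, tm, ps, cs, out) in rows
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def gof_pvalue(final_states, dist):
    """Chi-square GOF of empirical (i, j) tallies against a StateDistribution,
    pooling cells with expected count < 5 and dropping an empty tail."""
    from scipy.stats import chisquare

    space = dist.state_space
    counts = np.zeros(space.size)
    for i, j in final_states:
        counts[space.index(int(i), int(j))] += 1
    expected = dist.probs * len(final_states)
    keep = expected >= 5
    obs = np.append(counts[keep], counts[~keep].sum())
    exp = np.append(expected[keep], expected[~keep].sum())
    if exp[-1] <= 0:
        obs, exp = obs[:-1], exp[:-1]
    return chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
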