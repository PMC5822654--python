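import numpy as np
import pandas as pd
import pytest

import friendnet as fn


@pytest.fixture(scope="session")
def small_config():
    return fn.SimulationConfig(n_schools=4, children_per_school=20, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return fn.generate_study(small_config)


@pytest.fixture(scope="session")
def toy_roster():
    """Five children, two schools, mixed sexes."""
    return pd.DataFrame(
        {
            "child_id": ["a", "b", "c", "d", "e"],
            "school_id": ["s1", "s1", "s1", "s2", "s2"],
            "sex": ["F", "F", "M", "M", "M"],
            "bmi_z": [0.1, -0.2, 0.5, 0.0, 1.0],
            "imd": [10.0, 20.0, 15.0, 8.0, 30.0],
            "item1": [1, 2, 0, 3, 1],
            "item2": [0, 1, 2, 3, 0],
            "item3": [3, 0, 1, 2, 2],
            "item4": [1, 1, 1, 0, 3],
        }
    ).assign(activity_score=lambda d: d[["item1", "item2", "item3", "item4"]].sum(axis=1))


@pytest.fixture(scope="session")
def tiny_w():
    """3-node weight matrix from the worked standardisation example."""
    w = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    return fn.WeightMatrix(w, ids=["a", "b", "c"], schools=["s1", "s1", "s1"])


def random_weight_matrix(rng, n, p_edge=0.3, n_schools=1):
    """Random directed row-standardised W, block-diagonal by school."""
    schools = np.sort(rng.integers(0, n_schools, size=n))
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and schools[i] == schools[j] and rng.random() < p_edge:
                w[i, j] = 1.0
    wm = fn.WeightMatrix(w, ids=list(range(n)), schools=[f"s{s}" for s in schools])
    return wm.standardise()
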