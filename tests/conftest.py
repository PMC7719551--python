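import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dichroma as dc

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def caterpillar_index():
    return dc.TreeIndex(dc.read_tree("((A:1.0,B:1.0):1.0,C:2.0);"))


@pytest.fixture(scope="session")
def small_darwinian():
    return dc.simulate_dataset("darwinian", seed=7, n_tips=40)


@pytest.fixture(scope="session")
def small_null():
    return dc.simulate_dataset("shared_null", seed=8, n_tips=40)


@pytest.fixture(scope="session")
def small_analysis(small_darwinian):
    ds = small_darwinian
    return dc.analyze_dataset(ds.index, ds.centroids)


def make_centroids(index, male, female):
    """Build a long centroid table from per-sex (tips x 3) arrays."""
    rows = []
    for arrays, sex in ((male, "male"), (female, "female")):
        for lab, (L, a, b) in zip(index.tip_labels, np.asarray(arrays, dtype=float)):
            rows.append({"species_id": lab, "sex": sex, "L": L, "a": a, "b": b})
    return pd.DataFrame(rows)
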