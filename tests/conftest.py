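import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spicoda as sp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_table():
    """Three samples, four parts, strictly positive, not closed."""
    return sp.CompositionTable(
        ["s1", "s2", "s3"],
        ["Ca", "Mg", "O", "C"],
        np.array(
            [
                [40.0, 5.0, 35.0, 20.0],
                [30.0, 8.0, 42.0, 20.0],
                [25.0, 6.0, 50.0, 19.0],
            ]
        ),
    )


@pytest.fixture
def seven_part_row():
    return sp.CompositionTable(
        ["s1"],
        list(sp.DEFAULT_PARTS),
        np.array([[10.0, 60.0, 25.0, 3.0, 1.0, 0.5, 0.5]]),
    )


@pytest.fixture
def section_table():
    """Synthetic section-condition table with true labels."""
    table, truth = sp.generate_clusters(sp.section_cluster_specs(), seed=42)
    return table, truth


def random_positive_table(rng, n, d):
    vals = np.exp(rng.normal(size=(n, d)))
    return sp.CompositionTable(
        [f"s{i}" for i in range(n)], [f"p{j}" for j in range(d)], vals
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
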