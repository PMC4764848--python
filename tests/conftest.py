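import logging

import numpy as np
import pandas as pd
import pytest

from hybridmet import (
    MetaboliteMatrix,
    Panel,
    ParentLine,
    SyntheticStudySpec,
    enumerate_diallel,
    generate_study,
)

logging.getLogger("hybridmet").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study: 6 parents (3+3), 30 analytes."""
    return generate_study(SyntheticStudySpec(n_parents=6, n_analytes=30,
                                             n_causal=4, random_seed=11))


@pytest.fixture(scope="session")
def full_study():
    """Default-scale study: 18 parents, 525 analytes, 306 hybrids."""
    return generate_study(SyntheticStudySpec(random_seed=42))


@pytest.fixture
def toy_panel():
    return Panel([
        ParentLine("A", "indica", f_i=0.9),
        ParentLine("B", "indica", f_i=0.7),
        ParentLine("C", "japonica", f_i=0.1),
    ])


@pytest.fixture
def toy_cross(toy_panel):
    return enumerate_diallel(toy_panel)


@pytest.fixture
def raw_matrix():
    """2 parents x 2 replicates x 3 analytes with known areas."""
    idx = pd.MultiIndex.from_tuples(
        [("A", 1), ("A", 2), ("B", 1), ("B", 2)], names=["parent_id", "replicate"]
    )
    values = pd.DataFrame(
        [[500.0, 250.0, 1000.0],
         [600.0, 300.0, 1200.0],
         [125.0, 250.0, 500.0],
         [250.0, 500.0, 1000.0]],
        index=idx, columns=["m1", "m2", "m3"],
    )
    std = pd.Series([250.0, 300.0, 250.0, 500.0], index=idx)
    return MetaboliteMatrix(values=values, stage="raw", internal_standard=std)


def rng_design(seed, n, p):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, p))
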