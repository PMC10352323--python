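import numpy as np
import pytest

from docnet.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A miniature three-group cohort: fast, but exercises every stage."""
    spec = CohortSpec(
        n_regions=20,
        n_timepoints=120,
        group_sizes={"NC": 6, "MCS": 5, "VS": 7},
        effect_map={"NC": [], "MCS": [((0, 1, 2), 0.8)], "VS": [((0, 1, 2), 0.7)]},
        seed=7,
    )
    return spec, generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
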