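import numpy as np
import pytest

from templex.synthetic import demo_cohort
from templex.te import combination_significance
import templex as tx


@pytest.fixture(scope="session")
def demo_cohort_subjects():
    """The standard planted demonstration cohort (both groups pooled)."""
    g1, g2, _ = tx.gen_cohort(demo_cohort(seed=300))
    return g1 + g2


@pytest.fixture(scope="session")
def demo_significance(demo_cohort_subjects):
    """Combination significance on the demo cohort (shared across tests)."""
    return combination_significance(
        demo_cohort_subjects, n_perm=100, alpha=0.05, seed=400
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
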