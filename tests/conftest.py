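import warnings

import pytest

from immunosubtype import ImmuneSubtypeModel
from immunosubtype.synth import make_reference_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    """Small reference panel shared across tests."""
    return make_reference_panel(n_genes=900, n_markers_per_pop=50, fold=8.0, seed=1)


@pytest.fixture(scope="session")
def cohort(panel):
    """Default-condition synthetic cohort on the small panel."""
    return simulate_cohort(panel, seed=1)


@pytest.fixture(scope="session")
def fitted(cohort):
    """Full pipeline fit of the shared cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ImmuneSubtypeModel.from_cohort(cohort).fit(seed=1)
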