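import pytest

from captopbpk import get_spec, load_captopril_parameters, load_tissue_composition
from captopbpk.virtual_population import Variability

#: seed used by the seeded study-condition tests (fixed a priori)
STUDY_SEED = 20210421


@pytest.fixture(scope="session")
def drug():
    return load_captopril_parameters()


@pytest.fixture(scope="session")
def tissues():
    return load_tissue_composition()


@pytest.fixture
def no_variability_healthy():
    """Healthy spec with all inter-individual variability switched off and
    a fixed 70-kg body weight: every subject is the typical subject."""
    return get_spec("healthy").with_(
        variability=Variability(0.0, 0.0, 0.0, 0.0, 0.0),
        weight_range=(70.0, 70.0),
    )
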