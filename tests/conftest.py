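import numpy as np
import pytest

from gatekit.models import GateModel
from gatekit.synthetic import ArchitectureConfig, simulate_study


@pytest.fixture(scope="session")
def study_small():
    """A mid-size synthetic study shared across modules (read-only)."""
    cfg = ArchitectureConfig(seed=11)
    return simulate_study(cfg, n_cases=1500, n_controls=1500, n_ref=5000)


@pytest.fixture(scope="session")
def fitted_small(study_small):
    """A fitted GateModel on the shared study (read-only)."""
    model = GateModel(study_small.summary_stats, study_small.cc_genotypes,
                      study_small.phenotypes,
                      ld_genotypes=study_small.ref_genotypes,
                      study=study_small)
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
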