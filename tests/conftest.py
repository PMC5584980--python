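import pytest

import hlamotifs as hm
from hlamotifs.mixture import DeconvConfig
from hlamotifs.pipeline import run_annotation


@pytest.fixture(scope="session")
def cohort7():
    """The standard standard cohort, one fixed seed, shared read-only."""
    return hm.standard_cohort(seed=7)


@pytest.fixture(scope="session")
def pipeline7(cohort7):
    """Full deconvolution + annotation of the standard cohort."""
    catalog, state, pools = run_annotation(
        cohort7.samples, 9, deconv=DeconvConfig(seed=7, n_restarts=3))
    return catalog, state, pools
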