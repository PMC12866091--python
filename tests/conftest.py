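import numpy as np
import pytest
from hypothesis import settings

from triovar import SimConfig, simulate_cohort, write_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_patients=6,
        n_genes=80,
        n_germline_per_patient=60,
        n_tumor_private=12,
        n_normal_private=6,
        n_shared_somatic=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, outdir)
    return outdir


@pytest.fixture(scope="session")
def classified(small_cohort):
    from triovar import classify_origin

    return {p.patient_id: classify_origin(p) for p in small_cohort.patients}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
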