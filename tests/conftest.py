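import numpy as np
import pytest

from fwdmri.synthetic import (
    CohortSpec,
    PhantomRegion,
    PhantomSpec,
    build_phantom,
    make_acquisition_scheme,
    simulate_cohort_table,
)

F_GRID = (0.0, 0.2, 0.4, 0.6)
TISSUE_EIGS = (1.5, 0.3, 0.3)


@pytest.fixture(scope="session")
def scheme64():
    """The study's acquisition layout: 5 b=0 + 64 b=1000 s/mm^2 volumes."""
    return make_acquisition_scheme(n_b0=5, n_dirs=64, b=1000.0, seed=1)


@pytest.fixture(scope="session")
def four_region_phantom(scheme64):
    """Small noiseless phantom with f_true in {0, 0.2, 0.4, 0.6}."""
    regions = tuple(
        PhantomRegion(name=f"f{f:.1f}", f=f, eigenvalues=TISSUE_EIGS) for f in F_GRID
    )
    spec = PhantomSpec(grid_shape=(10, 10, 4), regions=regions, snr=None, seed=0)
    return build_phantom(spec, scheme64)


@pytest.fixture(scope="session")
def cohort_table():
    """Default synthetic cohort: 43 per group, NT age slopes, 7-tract offset."""
    return simulate_cohort_table(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def null_cohort_table():
    """Cohort with no group offset and no age slopes anywhere."""
    spec = CohortSpec(
        nt_fw_slope=0.0,
        nt_fwcfa_slope=0.0,
        nt_fa_slope=0.0,
        nt_md_slope=0.0,
        asd_fw_offset=0.0,
        seed=100,
    )
    return simulate_cohort_table(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
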