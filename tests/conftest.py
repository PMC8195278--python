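import numpy as np
import pytest

from neoharm.phantom import PhantomParams, SubjectMeta


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    """A 28^3 phantom for fast structural tests (not measurement-accurate)."""
    return PhantomParams(
        grid_shape=(28, 28, 28), spacing_mm=(1.4, 1.4, 1.4),
        radii_mm=(14.5, 13.5, 12.5), radius_growth_mm_per_week=0.2,
        radius_jitter_sd_mm=0.3, csf_rim_mm=2.2,
        dgm_radii_mm=(4.0, 3.5, 3.0), cerebellum_radius_mm=2.0,
        brainstem_radius_mm=2.0,
    )


@pytest.fixture(scope="session")
def ref_meta() -> SubjectMeta:
    """A subject at the thickness-model reference ages."""
    return SubjectMeta(id="ref", cohort="target", ga_weeks=30.5,
                       pma_weeks=41.3, sex="F")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
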