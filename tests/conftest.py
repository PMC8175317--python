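import numpy as np
import pytest

from tauroi import (
    CohortConfig,
    GroupSpec,
    TracerModel,
    cohort_config,
    default_atlas,
    generate_cohort,
)


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def preset_cohorts():
    """The three calibrated tracer cohorts at their published sizes."""
    return {
        tracer: generate_cohort(cohort_config(tracer, seed=7))
        for tracer in ("flortaucipir", "ro948", "mk6240")
    }


@pytest.fixture()
def simple_tracer():
    return TracerModel(name="toy", offset=1.0, gain=1.0, noise_sd=0.05)


@pytest.fixture()
def small_config(atlas, simple_tracer):
    """A small three-group cohort with clear AD/CU separation."""
    groups = (
        GroupSpec(diagnosis="CU", n=60, latent_mean=-2.0, latent_sd=0.5,
                  abeta_pos_fraction=0.3, latent_mean_pos=-1.0),
        GroupSpec(diagnosis="nonAD", subtype="PSP", n=40,
                  latent_mean=-1.5, latent_sd=0.6),
        GroupSpec(diagnosis="AD", n=50, latent_mean=2.0, latent_sd=0.8,
                  abeta_pos_fraction=1.0),
    )
    return CohortConfig(tracer=simple_tracer, groups=groups, atlas=atlas, seed=11)


@pytest.fixture()
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
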