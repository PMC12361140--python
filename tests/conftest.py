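import numpy as np
import pytest
from hypothesis import settings

from lacsite import synthetic as syn

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_config():
    return syn.study_mimic_config(seed=1)


@pytest.fixture(scope="session")
def genome_objects(study_config):
    return syn.build_genome_objects(study_config)


@pytest.fixture(scope="session")
def truth_by_strain(study_config):
    return {s.strain_id: s for s in study_config.strains}


def make_curve(sl=2.4e-4, m=1.0, t_off=10.0, d=5.0, sigma=0.0, seed=0,
               t_max=240.0, step=5.0):
    """Synthetic ONPG curve straight from the model, optional Gaussian noise."""
    cfg = syn.SynthConfig(seed=1, strains=(), sigma_od=sigma, kin_m=m,
                          kin_t_off=t_off, kin_d=d, t_max=t_max, t_step=step)
    rng = np.random.default_rng(seed)
    return syn.gen_kinetic_curve(sl, cfg, rng)
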