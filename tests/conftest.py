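import pytest

from qmtcest.phantom import (CESTPool, PhantomSpec, Protocol, RegionSpec,
                             default_phantom_spec, make_phantom,
                             simulate_study)


def flat_regions(with_pools: bool = True):
    """Zero-variance regions: every voxel carries its region mean exactly."""
    pools_t = (CESTPool(3.5, 1.2, 1.2), CESTPool(2.0, 1.5, 1.5),
               CESTPool(-3.3, 0.9, 3.0)) if with_pools else ()
    pools_n = (CESTPool(3.5, 0.5, 1.2), CESTPool(2.0, 0.6, 1.5),
               CESTPool(-3.3, 0.5, 3.0)) if with_pools else ()
    return (
        RegionSpec(label="tumour", t1_obs_ms=(2200, 0), t2_obs_ms=(55, 0),
                   t2_f_ms=(47, 0), mt_effect_hz=(1.8, 0),
                   t2_mt_us=(7.8, 0), cest_pools=pools_t),
        RegionSpec(label="necrosis", t1_obs_ms=(2000, 0), t2_obs_ms=(44, 0),
                   t2_f_ms=(39, 0), mt_effect_hz=(2.3, 0),
                   t2_mt_us=(7.4, 0), cest_pools=pools_n),
        RegionSpec(label="muscle", t1_obs_ms=(1800, 0), t2_obs_ms=(35, 0),
                   t2_f_ms=(30, 0), mt_effect_hz=(3.5, 0),
                   t2_mt_us=(8.0, 0)),
        RegionSpec(label="muscle_connective", t1_obs_ms=(1900, 0),
                   t2_obs_ms=(42, 0), t2_f_ms=(36, 0),
                   mt_effect_hz=(2.9, 0), t2_mt_us=(8.6, 0)),
        RegionSpec(label="blood_edema", t1_obs_ms=(3000, 0),
                   t2_obs_ms=(180, 0), t2_f_ms=(180, 0),
                   mt_effect_hz=(0.3, 0), t2_mt_us=(8.0, 0)),
    )


@pytest.fixture(scope="session")
def flat_spec():
    return PhantomSpec(regions=flat_regions(), grid_shape=(32, 32),
                       b0_amplitude_ppm=0.0, n_blood_specks=0, seed=1)


@pytest.fixture(scope="session")
def noiseless_protocol():
    return Protocol(noise_sd=0.0, drift_slope=0.0)


@pytest.fixture(scope="session")
def study_noiseless(flat_spec, noiseless_protocol):
    """Zero-noise, zero-drift, flat-region, no-B0 study: exact round trips."""
    return simulate_study(make_phantom(flat_spec), noiseless_protocol, seed=1)


@pytest.fixture(scope="session")
def study_default_small():
    """A small realistic study: noise, drift and B0 field all on."""
    spec = default_phantom_spec("22Rv1", grid_shape=(32, 32), seed=3,
                                b0_amplitude_ppm=0.08)
    return simulate_study(make_phantom(spec),
                          Protocol(noise_sd=0.005, drift_slope=1e-4), seed=3)
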