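import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mkrbe import (
    MKParameters,
    make_synthetic_experiment,
    make_synthetic_field,
)

#: Dose grid (Gy) shared by the synthetic experiments: spans both RBE branches.
DOSES = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0])


@pytest.fixture(scope="session")
def params():
    return MKParameters()  # y0=100 keV/um, D_t=7 Gy, (a/b)_c=10 Gy


@pytest.fixture(scope="session")
def photon_spectrum():
    return make_synthetic_field("photon-like", {"median": 1.0}, seed=1)


@pytest.fixture(scope="session")
def neutron_spectrum():
    return make_synthetic_field("neutron-like", {"admixture": 0.2}, seed=2)


@pytest.fixture(scope="session")
def clinical_spectrum():
    return make_synthetic_field("photon-like", {"median": 0.5}, seed=3)


@pytest.fixture(scope="session")
def noiseless_experiment(params, photon_spectrum, neutron_spectrum, clinical_spectrum):
    return make_synthetic_experiment(
        "noiseless",
        true_r_d=0.231,
        doses=DOSES,
        test_spectrum=neutron_spectrum,
        ref_spectrum=photon_spectrum,
        clin_spectrum=clinical_spectrum,
        params_base=params,
    )


@pytest.fixture(scope="session")
def noisy_experiments(params, photon_spectrum, neutron_spectrum, clinical_spectrum):
    """Five noisy synthetic experiments emulating one disease group."""
    radii = [0.18, 0.21, 0.23, 0.25, 0.28]
    return [
        make_synthetic_experiment(
            f"synth-{i}",
            true_r_d=r,
            doses=DOSES,
            test_spectrum=make_synthetic_field(
                "neutron-like", {"admixture": 0.2}, seed=100 + i
            ),
            ref_spectrum=photon_spectrum,
            clin_spectrum=clinical_spectrum,
            params_base=params,
            noise_sigma=0.05,
            seed=200 + i,
        )
        for i, r in enumerate(radii)
    ]
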