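import numpy as np
import pytest

from tetrodose.parameters import load_drug_params, load_physiology
from tetrodose.synthetic import SyntheticSpec, generate_dataset

ALL_TISSUES = ("blood", "heart", "kidney", "liver", "lung", "thyroid", "gi", "urine")


@pytest.fixture(scope="session")
def adult_phys():
    return load_physiology("adult")


@pytest.fixture(scope="session")
def drug():
    return load_drug_params()


@pytest.fixture(scope="session")
def truth_params(drug):
    return {
        "kp_lung": drug.kp["lung"], "kp_heart": drug.kp["heart"],
        "ps_heart": drug.ps_heart, "kp_kidney": drug.kp["kidney"],
        "ps_kidney": drug.ps_kidney, "kp_liver": drug.kp["liver"],
        "kp_thyroid": drug.kp["thyroid"], "kp_other": drug.kp["other"],
        "cl_renal": drug.cl_renal, "cl_liver": drug.cl_liver,
        "k_gb": drug.k_gb,
    }


@pytest.fixture(scope="session")
def noise_free_dataset(adult_phys, drug):
    spec = SyntheticSpec(sigmas={t: 0.0 for t in ALL_TISSUES}, seed=0)
    return generate_dataset(spec, adult_phys, drug)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
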