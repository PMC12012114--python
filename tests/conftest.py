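import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dtwdemux as dx

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kmer_model():
    return dx.synthetic_kmer_model()


@pytest.fixture(scope="session")
def barcodes4():
    rng = np.random.default_rng(42)
    return {f"BC{i:02d}": "".join(rng.choice(list("ACGT"), size=18)) for i in range(1, 5)}


@pytest.fixture(scope="session")
def train4(kmer_model, barcodes4):
    return dx.simulate_fingerprints(barcodes4, 60, sim_cfg=dx.SimConfig(seed=10), kmer_model=kmer_model)


@pytest.fixture(scope="session")
def test4(kmer_model, barcodes4):
    return dx.simulate_fingerprints(barcodes4, 40, sim_cfg=dx.SimConfig(seed=20), kmer_model=kmer_model)


@pytest.fixture(scope="session")
def clf4(train4):
    return dx.DtwKernelSvmClassifier(random_state=0).fit(train4.fingerprints, train4.labels)
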