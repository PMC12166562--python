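import numpy as np
import pytest

from nutrimr import BootstrapConfig, datasets
from nutrimr.summary_data import HarmonizedInstrument


@pytest.fixture(scope="session", params=datasets.NUTRIENTS)
def nutrient(request):
    return request.param


@pytest.fixture(scope="session")
def b6_instruments():
    return datasets.instruments("vitamin_b6")


@pytest.fixture
def fast_boot():
    return BootstrapConfig(n_boot=500, seed=7)


def random_instruments(rng: np.random.Generator, k: int = 5) -> list[HarmonizedInstrument]:
    """Random but well-conditioned instrument sets for oracle comparisons."""
    bx = rng.uniform(0.02, 0.1, size=k) * rng.choice([-1.0, 1.0], size=k)
    sx = rng.uniform(0.003, 0.02, size=k)
    by = rng.normal(0.0, 0.2, size=k)
    sy = rng.uniform(0.05, 0.4, size=k)
    return [
        HarmonizedInstrument(snp_id=f"rs{i}", bx=bx[i], sx=sx[i], by=by[i], sy=sy[i])
        for i in range(k)
    ]
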