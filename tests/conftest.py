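import numpy as np
import pytest

from vegclim.preprocess import filter_valid_pixels, mvc_composite, regrid_mean
from vegclim.scenarios import noise_free
from vegclim.synthetic import generate_climate, generate_ndvi


@pytest.fixture(scope="session")
def noise_free_small():
    """A 2x2 noise-free grid: climate, fine NDVI, and filtered pixel datasets."""
    scn = noise_free(2, 2)
    climate = generate_climate(scn.spec, scn.params, seed=1)
    fine, truth = generate_ndvi(climate, scn.spec, scn.params, seed=1)
    monthly = regrid_mean(mvc_composite(fine), scn.spec.fine_factor)
    datasets = filter_valid_pixels(monthly, climate)
    return {
        "scenario": scn,
        "climate": climate,
        "fine": fine,
        "monthly": monthly,
        "datasets": datasets,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
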