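import numpy as np
import pytest
from hypothesis import settings

from bmatquant import synthetic as syn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """One 100k-voxel marrow phantom at 70% adiposity, default distributions."""
    config = syn.PhantomConfig(
        grid_shape=(50, 50, 48),
        bm_regions=(syn.BMRegionSpec("bm", 100_000, 0.70),),
        seed=11,
    )
    return syn.generate_human_phantom(config)


@pytest.fixture(scope="session")
def tem_phantom():
    """Five-rod calibration phantom, HU = 1000*rho - 800, noise SD 10."""
    densities = list(np.linspace(1.08, 1.57, 5))
    ct, masks, truth = syn.generate_tem_phantom(
        densities, slope=1000.0, intercept=-800.0, noise_sd=10.0, voxels_per_rod=500, seed=7
    )
    return ct, masks, truth, densities
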