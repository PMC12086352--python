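import numpy as np
import pytest

from xemrsi.config import AcquisitionConfig, HeterogeneityConfig
from xemrsi.fitting import PriorKnowledge, fit_volume
from xemrsi.recon import reconstruct
from xemrsi.sampling import SamplingPattern, build_spherical_pattern
from xemrsi.synthetic import generate_phantom, simulate_acquisition


@pytest.fixture(scope="session")
def acq():
    """Protocol configuration without spatial zero-fill (fits on the
    acquisition grid)."""
    return AcquisitionConfig(spatial_zf=1)


@pytest.fixture(scope="session")
def acq_small():
    return AcquisitionConfig(matrix=(16, 16, 6), spatial_zf=1)


@pytest.fixture(scope="session")
def pattern(acq):
    return build_spherical_pattern(acq.matrix)


@pytest.fixture(scope="session")
def pattern_small(acq_small):
    return build_spherical_pattern(acq_small.matrix)


def full_pattern(matrix):
    axes = [np.arange(-(m // 2), (m + 1) // 2) for m in matrix]
    locs = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    return SamplingPattern(locs, tuple(matrix))


@pytest.fixture(scope="session")
def uniform_phantom_small(acq_small):
    """Zero-heterogeneity 40%-FiO2 phantom on the small grid."""
    return generate_phantom(acq_small.matrix, 0.40, HeterogeneityConfig.none(),
                            seed=0)


@pytest.fixture(scope="session")
def noiseless_fits_small(acq_small, pattern_small, uniform_phantom_small):
    """Noiseless end-to-end: acquire, reconstruct, fit the small phantom."""
    ksp = simulate_acquisition(uniform_phantom_small, acq_small, pattern_small,
                               0.0, seed=0)
    img = reconstruct(ksp)
    fits = fit_volume(img, PriorKnowledge.default(0.40), acq_small)
    return img, fits
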