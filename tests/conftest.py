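import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import kneemorph as km

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom() -> km.PhantomSet:
    """One default phantom shared by the slower geometry tests."""
    return km.generate_phantom(km.PhantomConfig(noise_seed=0))


@pytest.fixture(scope="session")
def phantom_extraction(default_phantom):
    """Registration + morphometry + thickness run on the default phantom."""
    return km.extract_phantom(default_phantom)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-size synthetic cohort (23 D / 16 T / 8 C, seed 0)."""
    return km.generate_cohort(km.CohortConfig(seed=0))


@pytest.fixture(scope="session")
def schema():
    return km.build_default_schema()


def voxel_sphere(radius_mm: float, spacing_mm: float) -> km.Mask:
    """Voxelized solid sphere centered in its lattice."""
    n = int(np.ceil(2 * radius_mm / spacing_mm)) + 5
    coords = (np.arange(n) - (n - 1) / 2) * spacing_mm
    X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)
    sel = X**2 + Y**2 + Z**2 <= radius_mm**2
    return km.Mask(sel, np.full(3, spacing_mm))
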