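import numpy as np
import pytest

from ipet import phantom
from ipet.core import DensityMap


@pytest.fixture(scope="session")
def equilateral_conf():
    dist = phantom.ConformationDistribution.equilateral(82.0)
    return phantom.sample_conformation(dist, np.random.default_rng(0))


@pytest.fixture(scope="session")
def default_particle(equilateral_conf):
    """Equilateral phantom at the full default grid (164 px, 2 A)."""
    return phantom.build_phantom(equilateral_conf)


@pytest.fixture(scope="session")
def small_particle(equilateral_conf):
    """Same phantom on a coarser grid (110 px, 3 A) for fast pipeline tests."""
    return phantom.build_phantom(equilateral_conf, pixel_size=3.0, box=110)


@pytest.fixture(scope="session")
def small_noisy_series(small_particle):
    return phantom.project_tilt_series(
        small_particle.density, jitter_max=5.0, target_snr=0.2,
        rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def template_maps():
    return {t.name: phantom.rasterize_template(t, 2.0)
            for t in phantom.default_templates()}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sphere_map(box=64, voxel=2.0, radius_A=40.0, value=1.0):
    ax = (np.arange(box) - (box - 1) / 2.0) * voxel
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    return DensityMap((r <= radius_A).astype(np.float32) * value, voxel)
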