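import numpy as np
import pytest

from petquant.grid import VoxelGrid
from petquant.phantom import CompartmentSpec, Cylinder, LesionSpec, PhantomSpec, build_phantom
from petquant.projector import Projector, forward_project, psf_blur, sample_counts


@pytest.fixture(scope="session")
def small_grid():
    return VoxelGrid.centered((32, 32, 8))


@pytest.fixture(scope="session")
def uniform_cylinder(small_grid):
    """1.8 kBq/mL cylinder filling most of the small grid."""
    spec = PhantomSpec(
        grid=small_grid,
        compartments=[
            CompartmentSpec(
                "body",
                Cylinder(center=(0, 0, 0), radii=(45, 45), height=small_grid.extent[2]),
                1.8,
            )
        ],
    )
    return build_phantom(spec)


@pytest.fixture(scope="session")
def small_projector(small_grid):
    return Projector(small_grid, n_angles=96)


def make_blurred_ball(diameter, center=(0.8, -0.6, 0.4), contrast=57.6, bkg=1.8,
                      shape=(40, 40, 20), fwhm=4.7):
    """Noiseless PSF-blurred sphere-in-cylinder test image."""
    grid = VoxelGrid.centered(shape)
    spec = PhantomSpec(
        grid=grid,
        compartments=[
            CompartmentSpec("body", Cylinder((0, 0, 0), (65, 65), grid.extent[2]), bkg)
        ],
        lesions=[LesionSpec("l", center, diameter, contrast)],
    )
    img = build_phantom(spec)
    return psf_blur(img, fwhm) if fwhm > 0 else img
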