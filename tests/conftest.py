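import numpy as np
import pytest

from vdmkit.core import CenterlineCurve, ImageGrid
from vdmkit.phantom import (
    IntensityModel,
    PhantomSpec,
    apply_radial_bulge,
    grid_around,
    make_centerline,
    make_tube_mesh,
    rasterize,
    straight_centerline,
)


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Straight cylinder r=15, length 100, moderate density (fast tests)."""
    return make_tube_mesh(straight_centerline(100.0), 15.0, n_circ=96,
                          axial_step=1.0)


@pytest.fixture(scope="session")
def candycane():
    """Default candy-cane centerline and tube mesh at test density."""
    spec = PhantomSpec()
    cl = make_centerline(spec)
    mesh = make_tube_mesh(cl, 12.0, n_circ=96, axial_step=0.8)
    return spec, cl, mesh


@pytest.fixture(scope="session")
def cylinder_volume(cylinder_mesh):
    grid = grid_around(cylinder_mesh.bounds(), (1.25, 1.25, 1.0), 10.0)
    img, mask = rasterize(cylinder_mesh, grid, IntensityModel())
    return img, mask


@pytest.fixture(scope="session")
def default_phantom_pair():
    """The reference phantom: dense candy-cane tube + 2.5 mm ascending bulge."""
    spec = PhantomSpec()
    cl = make_centerline(spec)
    fixed = make_tube_mesh(cl, 12.0)
    deformed = apply_radial_bulge(fixed, 25.0, 30.0, 2.5)
    return fixed, deformed


@pytest.fixture(scope="session")
def default_phantom_images(default_phantom_pair):
    fixed, deformed = default_phantom_pair
    bounds = np.stack([
        np.minimum(fixed.bounds()[0], deformed.bounds()[0]),
        np.maximum(fixed.bounds()[1], deformed.bounds()[1]),
    ])
    grid = grid_around(bounds, (1.25, 1.25, 1.0), 12.0)
    img, mask = rasterize(fixed, grid, IntensityModel(texture_hu=30.0,
                                                      texture_seed=11))
    return img, mask


@pytest.fixture(scope="session")
def default_ground_truth(default_phantom_pair, default_phantom_images):
    from vdmkit.ground_truth import make_ground_truth

    fixed, deformed = default_phantom_pair
    img, mask = default_phantom_images
    return make_ground_truth(fixed, deformed, img, mask)
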