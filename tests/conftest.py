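import numpy as np
import pytest

from mechprop import synth, tfm
from mechprop.boussinesq import SubstrateParams, forward_displacement


@pytest.fixture(scope="session")
def substrate():
    return SubstrateParams()  # 20 kPa, ν = 0.5


@pytest.fixture(scope="session")
def doublet_geometry():
    # 0.3 µm working pixel keeps the imaging chain fast at full fidelity
    return synth.PatternGeometry(pixel_size_um=0.3, corner_patch_radius_um=4.0)


@pytest.fixture(scope="session")
def corner_traction(doublet_geometry):
    """Balanced inward-pointing 100 nN corner forces on the H pattern."""
    F = 100e-9
    forces = [-c / np.hypot(*c) * F for c in doublet_geometry.corners()]
    return synth.make_pattern_traction(doublet_geometry, forces,
                                       grid_spacing_um=0.3)


@pytest.fixture(scope="session")
def corner_displacement(corner_traction, substrate):
    return forward_displacement(corner_traction, substrate)


@pytest.fixture(scope="session")
def true_displacement_interp(corner_displacement):
    from scipy.interpolate import RegularGridInterpolator
    d = corner_displacement
    X, Y = d.coords()
    ix = RegularGridInterpolator((Y[:, 0], X[0]), d.vx, bounds_error=False,
                                 fill_value=0.0)
    iy = RegularGridInterpolator((Y[:, 0], X[0]), d.vy, bounds_error=False,
                                 fill_value=0.0)

    def interp(x, y):
        pts = np.column_stack([np.atleast_1d(y), np.atleast_1d(x)])
        return np.column_stack([ix(pts), iy(pts)])

    return interp


@pytest.fixture
def piv_config():
    return tfm.PivConfig()
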