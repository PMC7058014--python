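import numpy as np
import pytest

import samcascade as sc
from samcascade.model import SimulationConfig

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


#: Geometry of the reduced dome used throughout the tests: same cell size
#: as the standard template, smaller footprint.
SMALL_GEO = sc.DomeGeometry(radius_of_curvature=8.0, height=4.0, n_shells=3, shell_spacing=2.0)
MID_GEO = sc.DomeGeometry(radius_of_curvature=10.0, height=5.0, n_shells=4, shell_spacing=2.0)

#: Loose-tolerance integrator settings for tests where the asymptotic
#: steady state itself is not under scrutiny.
FAST_CONFIG = SimulationConfig(steady_tol=1e-6, t_max=600.0)


@pytest.fixture(scope="session")
def micro_template():
    """12-cell, two-shell dome; every pair can be checked by hand."""
    return sc.build_dome_template(12, geometry=sc.MICRO_DOME, seed=7)


@pytest.fixture(scope="session")
def small_template():
    """~60-cell, three-shell dome (all three layers populated)."""
    return sc.build_dome_template(60, geometry=SMALL_GEO, seed=5)


@pytest.fixture(scope="session")
def mid_template():
    """300-cell, four-shell dome used for the reduced-scale screens."""
    return sc.build_dome_template(300, geometry=MID_GEO, seed=2)


@pytest.fixture(scope="session")
def small_wt_result(small_template):
    wt = sc.make_ml1p_wildtype(small_template)
    return sc.integrate_euler(wt, sc.BASELINE, small_template)


@pytest.fixture(scope="session")
def mid_wt_result(mid_template):
    wt = sc.make_ml1p_wildtype(mid_template)
    return sc.integrate_euler(wt, sc.BASELINE, mid_template)


@pytest.fixture(scope="session")
def mid_ectopic_result(mid_template):
    ect = sc.make_ml1p_ectopic(mid_template, 1.1, 0.4)
    return sc.integrate_euler(ect, sc.BASELINE, mid_template)


def make_pair_template(distance=1.8, radius=1.0):
    """Two overlapping unit-ish spheres — the smallest legal template."""
    centers = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    radii = np.array([radius, radius])
    return sc.CellTemplate(
        centers=centers,
        radii=radii,
        volumes=4 / 3 * np.pi * radii**3,
        shells=np.array([0, 1]),
        layers=np.array(["L1", "L2"], dtype=object),
        edges=np.array([[0, 1]]),
    )
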