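import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    from twinmark.synthetic import make_landmark_template

    return make_landmark_template()


@pytest.fixture(scope="session")
def regions():
    from twinmark.landmark_regions import canonical_regions

    return canonical_regions()


@pytest.fixture(scope="session")
def region_polygons(template, regions):
    from shapely.geometry import Polygon

    from twinmark.landmark_regions import region_polygon

    return {r.name: Polygon(region_polygon(template, r)) for r in regions}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def unit_square_landmarks():
    """468 landmarks where indices 0-3 trace the unit square and the rest sit
    far away; handy for exact geometry assertions."""
    from twinmark.landmark_regions import FaceLandmarks, Landmark

    corners = {0: (0.0, 0.0), 1: (4.0, 0.0), 2: (4.0, 4.0), 3: (0.0, 4.0)}
    pts = []
    for i in range(468):
        x, y = corners.get(i, (100.0 + (i % 21), 100.0 + (i // 21)))
        pts.append(Landmark(index=i, x=x, y=y, z=None))
    return FaceLandmarks(points=tuple(pts), image_width=128, image_height=128)
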