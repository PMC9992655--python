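"""Shared fixtures: synthetic eyes and their (expensive) pipeline runs.

Pipeline runs are session-scoped so several test modules can interrogate
the same run without repeating the heavy stages.
"""

import pytest

from ommatidia.oda3d import EyePointCloud, run_pipeline
from ommatidia.synth import SyntheticEyeSpec, make_synthetic_eye3d


@pytest.fixture(scope="session")
def hex_image():
    """Clean hexagonal lattice image with ground-truth centres."""
    from ommatidia.synth import make_hex_lattice_image

    img, centers = make_hex_lattice_image(512, 20)
    return img, centers


@pytest.fixture(scope="session")
def spherical_eye():
    """Spherical eye, zero skew: D = 20 µm, R = 1000 µm, 45 x 45 degrees."""
    spec = SyntheticEyeSpec(
        lens_diameter=20.0, radius_h=1000.0, radius_v=1000.0,
        extent_deg=(45.0, 45.0), seed=0,
    )
    return make_synthetic_eye3d(spec)


@pytest.fixture(scope="session")
def spherical_run(spherical_eye):
    """Full pipeline output on the spherical eye."""
    cloud = EyePointCloud(coords=spherical_eye.points)
    records, pairs, section, clusters = run_pipeline(cloud)
    return {
        "eye": spherical_eye,
        "records": records,
        "pairs": pairs,
        "section": section,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def small_spherical_run():
    """Second spherical condition: D = 15 µm, R = 500 µm."""
    spec = SyntheticEyeSpec(
        lens_diameter=15.0, radius_h=500.0, radius_v=500.0,
        extent_deg=(55.0, 55.0), seed=1,
    )
    eye = make_synthetic_eye3d(spec)
    cloud = EyePointCloud(coords=eye.points)
    records, pairs, section, clusters = run_pipeline(cloud)
    return {
        "eye": eye,
        "records": records,
        "pairs": pairs,
        "section": section,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def oval_run():
    """Oval eye with R_v = 3 R_h and a regular hexagonal lattice."""
    spec = SyntheticEyeSpec(
        lens_diameter=20.0, radius_h=500.0, radius_v=1500.0,
        extent_deg=(60.0, 20.0), seed=2,
    )
    eye = make_synthetic_eye3d(spec)
    cloud = EyePointCloud(coords=eye.points)
    records, pairs, section, clusters = run_pipeline(cloud)
    return {
        "eye": eye,
        "records": records,
        "pairs": pairs,
        "section": section,
        "clusters": clusters,
    }
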