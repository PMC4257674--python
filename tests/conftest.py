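import numpy as np
import pytest

from clemdock.geometry import (
    FeatureClass,
    Landmark,
    LandmarkPairing,
    LandmarkSet,
    Point3,
    VolumeGeometry,
    pair_by_id,
)


@pytest.fixture
def geometry():
    return VolumeGeometry((1.0, 1.0, 1.0), (500, 500, 200))


def make_set(points, geometry, ids=None, feature_class=FeatureClass.OTHER, name=""):
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if ids is None:
        ids = [f"L{i}" for i in range(len(points))]
    return LandmarkSet(
        [Landmark(i, Point3.from_array(p), feature_class) for i, p in zip(ids, points)],
        geometry,
        name=name,
        min_separation=0.0,
    )


def make_pairing(src_points, tgt_points, geometry, ids=None) -> LandmarkPairing:
    src = make_set(src_points, geometry, ids)
    tgt = make_set(tgt_points, geometry, ids)
    return pair_by_id(src, tgt)


def random_cloud(rng, n, extent=(400.0, 400.0, 150.0)):
    return rng.uniform([0, 0, 0], list(extent), size=(n, 3))


def rotation_about_z(deg):
    a = np.deg2rad(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


@pytest.fixture(scope="session")
def default_scenarios():
    """The standard simulated study for seeds 1..20, computed once."""
    from clemdock.simulate import default_scenario

    return {seed: default_scenario(seed) for seed in range(1, 21)}
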