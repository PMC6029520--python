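import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hpvmleaf.hpvm import FeatureLevel, FeaturePointSet
from hpvmleaf.pipeline import fit_leaf, remesh
from hpvmleaf.sampling import SamplingConfig
from hpvmleaf.synthetic import LeafParams, generate_leaf

settings.register_profile(
    "fast", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def default_leaf():
    return generate_leaf(LeafParams())


@pytest.fixture(scope="session")
def fitted_default(default_leaf):
    return fit_leaf(default_leaf.truth_sets)


@pytest.fixture(scope="session")
def planar_leaf():
    return generate_leaf(LeafParams(wrinkle_amplitude=0.0, vein_groove_depth=0.0,
                                    bend=0.0, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def planar_fitted(planar_leaf):
    return fit_leaf(planar_leaf.truth_sets)


@pytest.fixture(scope="session")
def remesh20(default_leaf, fitted_default):
    model, sfit = fitted_default
    return remesh(model, sfit, default_leaf.cloud, SamplingConfig(l=20.0, seed=1))


def square_margin_sets(side: float = 100.0, pts_per_side: int = 6):
    """Four margin parts tracing a planar square, sharp corners."""
    c = np.array([[0, 0], [side, 0], [side, side], [0, side]], dtype=float)
    sets = []
    for k in range(4):
        a, b = c[k], c[(k + 1) % 4]
        t = np.linspace(0, 1, pts_per_side)[:, None]
        pts = a + t * (b - a)
        pts3 = np.column_stack([pts, np.zeros(len(pts))])
        roles = ["sharp"] + ["none"] * (len(pts3) - 2) + ["sharp"]
        sets.append(FeaturePointSet(level=FeatureLevel.MARGIN, points=pts3, roles=roles))
    return sets


@pytest.fixture()
def square_sets():
    return square_margin_sets()
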