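import numpy as np
import pytest

from spinemorph.synthetic_spines import SpineSpec, make_spine


@pytest.fixture(scope="session")
def spine_a():
    """Canonical group-A spine: sphere head r=0.5, neck l=0.6, r=0.15."""
    return make_spine(SpineSpec(seed=1))


@pytest.fixture(scope="session")
def spine_b():
    return make_spine(SpineSpec(target_group="B", seed=2))


@pytest.fixture(scope="session")
def spine_c():
    return make_spine(SpineSpec(target_group="C", seed=3))


@pytest.fixture(scope="session")
def spine_d():
    return make_spine(SpineSpec(target_group="D", seed=4))


@pytest.fixture(scope="session")
def spine_e():
    return make_spine(SpineSpec(target_group="E", seed=5))


def random_group_a_spec(rng: np.random.Generator, seed: int,
                        resolution: int = 1) -> SpineSpec:
    """Group-A spec sampler shared by tests and the acceptance suite.

    Head radii 0.3-0.8 um, neck radii 0.08-0.25 um capped at 0.45x the head
    radius (a neck about as wide as its head is a sessile/group-B shape, not
    a group-A spine), neck lengths 0.4-1.2 um.
    """
    hr = rng.uniform(0.3, 0.8)
    nr = rng.uniform(0.08, min(0.25, 0.45 * hr))
    nl = rng.uniform(0.4, 1.2)
    return SpineSpec(head_radii=(hr, hr, hr), neck_radius=nr, neck_length=nl,
                     mesh_resolution=resolution, seed=seed)
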