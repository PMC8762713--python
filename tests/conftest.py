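"""Shared fixtures: phantoms and pipeline products are session-scoped
because rendering and enhancing the standard phantom dominates runtime."""

from __future__ import annotations

import numpy as np
import pytest

from chorovol import (
    PhantomSpec,
    ShadowStripe,
    Vessel,
    enhance_pipeline,
    make_phantom,
    segment_vessels,
)


@pytest.fixture(scope="session")
def standard_truth():
    """The standard study phantom: L=4 speckle, two shadow stripes,
    attenuation 0.5 /mm, six vessels with radii 0.05-0.2 mm."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noiseless_truth():
    """Same geometry with speckle, shadows and attenuation disabled."""
    return make_phantom(PhantomSpec(seed=0).without_noise())


@pytest.fixture(scope="session")
def standard_enhanced(standard_truth):
    return enhance_pipeline(standard_truth.volume)


@pytest.fixture(scope="session")
def standard_mask(standard_truth, standard_enhanced):
    return segment_vessels(standard_enhanced, standard_truth.surfaces)


def small_spec(**overrides) -> PhantomSpec:
    """A fast-to-render phantom for I/O, pipeline and CLI tests."""
    defaults = dict(
        shape=(56, 160, 120),
        spacing=(0.03, 0.03, 0.01),
        vessels=(
            Vessel((0.20, 0.30, 0.50), (0.50, 4.50, 0.50), 0.08),
            Vessel((0.55, 0.30, 0.62), (0.25, 4.50, 0.62), 0.06),
        ),
        shadows=(ShadowStripe(2.2, 0.1, 0.4),),
        seed=3,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    return make_phantom(small_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
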