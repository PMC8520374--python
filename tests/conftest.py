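"""Shared fixtures: small phantoms and convolution systems built once."""

import numpy as np
import pytest

from ctperf import (
    AIFParams,
    PhantomSpec,
    TimeGrid,
    build_conv_matrix,
    build_phantom,
)


@pytest.fixture(scope="session")
def grid20():
    return TimeGrid(n_frames=20, dt=2.0)


@pytest.fixture(scope="session")
def random_system():
    """T=8 system with a random strictly-positive AIF (invertible matrix)."""
    rng = np.random.default_rng(7)
    B = rng.uniform(0.5, 2.0, size=8)
    return build_conv_matrix(B, dt=0.7)


@pytest.fixture(scope="session")
def default_phantom():
    """The package's default 64x64x1x20 two-lesion phantom (built once)."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_spec():
    """A 32x32 single-lesion-pair phantom that builds in well under a second."""
    from ctperf import LesionSpec

    return PhantomSpec(
        shape=(32, 32, 1),
        lesions=(
            LesionSpec(kind="core", center=(22.0, 19.0, 0.0), radii=(3.0, 3.0, 1.0),
                       rcbf=43.17, rmtt=124.83, rttp=122.57),
            LesionSpec(kind="penumbra", center=(21.0, 11.0, 0.0), radii=(3.0, 3.5, 1.0),
                       rcbf=18.37, rmtt=183.17, rttp=150.74),
        ),
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)
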