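"""Shared fixtures: small synthetic scenes generated programmatically."""

import numpy as np
import pytest

from panicle3d.synth import (
    PlotSpec,
    finalize_cloud,
    place_plants,
    sample_scene_rng,
)


@pytest.fixture(scope="session")
def tiny_scene():
    """A short-row scene with a handful of plants (session-cached)."""
    spec = PlotSpec(row_length=0.5, gap_probability=0.0)
    return place_plants(spec, np.random.default_rng(5))


@pytest.fixture(scope="session")
def tiny_cloud(tiny_scene):
    """Finalized annotated cloud of the tiny scene (~3k points)."""
    raw = sample_scene_rng(tiny_scene, 9000, np.random.default_rng(6))
    return finalize_cloud(raw, 3000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
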