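"""Shared fixtures: deterministic random morphs and the synthetic chain pairs."""

from __future__ import annotations

import numpy as np
import pytest

from morphcheck import make_crossing_change_pair, make_loop_fixtures
from morphcheck.morphgeo import Morph


def random_morph(rng, n_vertices=12, step=3.0, noise=2.5) -> Morph:
    """A random-walk backbone and a perturbed copy; dense enough to produce
    self-intersections in roughly half of the draws at the default scales."""
    steps = rng.normal(size=(n_vertices - 1, 3))
    steps = step * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    curve0 = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    curve1 = curve0 + rng.normal(scale=noise, size=curve0.shape)
    return Morph(curve0=curve0, curve1=curve1)


@pytest.fixture(scope="session")
def crossing_pair():
    return make_crossing_change_pair(100)


@pytest.fixture(scope="session")
def loop_pairs():
    return {
        kind: make_loop_fixtures(kind)
        for kind in ("removable_loop", "threaded_loop", "slide_pair")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
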