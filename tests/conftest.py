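"""Shared fixtures: small synthetic scenes and hand-drawn skeleton shapes."""

import numpy as np
import pytest

from actinet import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene_params():
    """A reduced 100x100 px scene for fast tests (same physics, smaller field)."""
    return SceneParams(shape=(100, 100), n_filaments=4)


@pytest.fixture(scope="session")
def clean_scene(small_scene_params):
    """A noiseless multi-filament scene with ground truth."""
    return generate_scene(small_scene_params, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def draw_line(shape, r0, c0, r1, c1):
    """Rasterise a straight 1-px line onto a boolean grid (inclusive ends)."""
    from skimage.draw import line

    grid = np.zeros(shape, dtype=bool)
    rr, cc = line(r0, c0, r1, c1)
    grid[rr, cc] = True
    return grid


@pytest.fixture()
def t_skeleton():
    """A 'T': horizontal bar through (10, 5..25) with stem down from (10, 15)."""
    grid = draw_line((30, 30), 10, 5, 10, 25)
    grid |= draw_line((30, 30), 10, 15, 24, 15)
    return grid


@pytest.fixture()
def x_skeleton():
    """An 'X' of two diagonals crossing at (15, 15)."""
    grid = draw_line((31, 31), 5, 5, 25, 25)
    grid |= draw_line((31, 31), 25, 5, 5, 25)
    return grid
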