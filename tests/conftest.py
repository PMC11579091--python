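"""Shared fixtures: all test data is generated by the phantom module."""

import numpy as np
import pytest

from brainslide.phantom import make_brain, make_slide, make_stack


@pytest.fixture(scope="session")
def brain():
    """One deterministic phantom brain (128 px, light background)."""
    return make_brain(seed=1)


@pytest.fixture(scope="session")
def textured():
    """Inverted brain image: tissue bright on ~zero background, the
    polarity the registration stages operate on."""
    return 1.0 - make_brain(seed=1).image.pixels


@pytest.fixture(scope="session")
def stack_and_brains():
    return make_stack(n_layers=6, seed=12)


@pytest.fixture(scope="session")
def slide_3x5():
    return make_slide(3, 5, set(), 2, seed=7)
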