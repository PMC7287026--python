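import dataclasses

import numpy as np
import pytest

from ommaquant import EyeSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_eye_spec():
    """A reduced-geometry eye for fast rendering in unit tests."""
    return EyeSpec(image_size=(360, 480), eye_center=(180.0, 240.0),
                   eye_axes=(110.0, 150.0), lattice_spacing=24.0)


@pytest.fixture
def small_eye_spec_offcenter(small_eye_spec):
    return dataclasses.replace(small_eye_spec, eye_center=(150.0, 200.0))
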