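import numpy as np
import pytest

import knobkit as kk


@pytest.fixture(scope="session")
def default_scene():
    """One default single-nucleus scene with one planted knob."""
    stacks, truth = kk.generate_nucleus_scene(kk.SceneParams(), seed=11)
    return stacks, truth


@pytest.fixture(scope="session")
def default_nucleus(default_scene):
    stacks, truth = default_scene
    nuclei = kk.segment_nuclei(stacks["DAPI"])
    assert len(nuclei) == 1
    return stacks, truth, nuclei[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
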