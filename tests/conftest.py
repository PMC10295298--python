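import numpy as np
import pytest

import excitescan as ex


@pytest.fixture(scope="session")
def tiny_render():
    """Small noiseless scene (5 bands, 16x16, 4 frames) plus ground truth."""
    scene = ex.tiny_scene(seed=7)
    stacks, truth = ex.render_scene(scene)
    return scene, stacks, truth


@pytest.fixture(scope="session")
def control_tsa():
    """Rendered control acquisition (no Ca2+ label) with the measured-style
    analysis library and the default injection ROI — shared by the
    sensitivity tests because the LU sweep is the slow part."""
    scene = ex.control_scene(seed=0)
    stacks, truth = ex.render_scene(scene)
    library = ex.analysis_library(scene)
    roi = ex.tsa_roi(scene)
    return scene, stacks[0], truth, library, roi


@pytest.fixture
def rng():
    return np.random.default_rng(20230642)
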