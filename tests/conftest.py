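import numpy as np
import pytest

from cusdvt import synth


@pytest.fixture(scope="session")
def healthy_knee_sequence():
    scene = synth.make_scene("LM8", pathology=False, seed=3)
    return synth.render_sequence(scene, synth.ramp_profile(), seed=3, speckle=False)


@pytest.fixture(scope="session")
def thrombosed_knee_sequence():
    scene = synth.make_scene("LM8", pathology=True, seed=4)
    return synth.render_sequence(scene, synth.ramp_profile(), seed=4, speckle=False)


@pytest.fixture(scope="session")
def tiny_manifest():
    """A very small training manifest for smoke tests."""
    return synth.make_dataset({
        "landmarks": {"LM8": 6, "LM9": 4},
        "n_subjects": 5,
        "pathology_fraction": 0.0,
        "val_fraction": 0.2,
        "n_frames": 14,
        "speckle": False,
        "seed": 21,
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
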