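import numpy as np
import pytest

from asbestoscreen import PhantomSpec, generate_volume
from asbestoscreen.pipeline import run_desk_experiment

DESK_SEED = 7
DESK_N = 200


@pytest.fixture(scope="session")
def desk():
    """The desk-scale end-to-end experiment shared by the slower tests.

    n = 200 phantoms on the 48 x 48 x 24 grid, VAE on healthy training
    slices, soft- and hard-label classifiers on CT + heatmap, evaluated on
    the held-out test split.  Session-scoped: it runs once.
    """
    return run_desk_experiment(n=DESK_N, seed=DESK_SEED)


@pytest.fixture()
def healthy_phantom():
    spec = PhantomSpec(lesion_kind="none", severity_img=0.0, seed=101)
    volume, lesion = generate_volume(spec)
    return spec, volume, lesion


@pytest.fixture()
def fibrotic_phantom():
    spec = PhantomSpec(lesion_kind="asbestosis_fibrosis", severity_img=0.6, seed=202)
    volume, lesion = generate_volume(spec)
    return spec, volume, lesion


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
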