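import numpy as np
import pytest

from dualseg.models import SegNetConfig
from dualseg.synthetic import generate_dataset, preset_task
from dualseg.types import SoftPrediction


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_seg_config():
    # 16x16-capable toy segmentor: fast enough for per-test training steps
    return SegNetConfig(spatial_rank=2, in_channels=2, num_classes=3,
                        depth=2, base_width=4, dropout=0.0)


@pytest.fixture
def tiny_dataset():
    spec = preset_task("cross_modality")
    spec.size = 16
    spec.radius_range = (2.0, 3.5)
    spec.classes = 3
    spec.class_means = ((0.1, 0.1), (0.55, 0.35), (0.8, 0.65))
    return generate_dataset(spec, 6, 6, 2, 2,
                            rng=np.random.default_rng(99))


@pytest.fixture
def adv_dataset():
    # 32x32 phantoms: large enough for the 5-layer stride-2 discriminator
    spec = preset_task("cross_modality")
    spec.classes = 3
    spec.class_means = ((0.1, 0.1), (0.55, 0.35), (0.8, 0.65))
    return generate_dataset(spec, 4, 4, 2, 2,
                            rng=np.random.default_rng(77))


def random_soft_prediction(rng, num_classes, spatial, batch=None):
    """Dirichlet-ish random probability map wrapped as a SoftPrediction."""
    shape = ((batch,) if batch else ()) + (num_classes,) + tuple(spatial)
    raw = rng.gamma(1.0, 1.0, size=shape)
    axis = 1 if batch else 0
    probs = raw / raw.sum(axis=axis, keepdims=True)
    return SoftPrediction.from_probs(probs)
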