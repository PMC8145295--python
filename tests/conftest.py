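import numpy as np
import pytest

from lesionkit import dss, enhancement, fixtures
from lesionkit.nn import SaliencyNetSpec


@pytest.fixture(scope="session")
def seg_dataset():
    """Small two-class lesion image set with ground-truth masks."""
    return fixtures.generate_segmentation_dataset(60, image_size=64, n_classes=2, seed=3)


@pytest.fixture(scope="session")
def trained_net(seg_dataset):
    """Saliency CNN trained on the enhanced first half of the image set.

    Session-scoped: CNN training is the most expensive step in the suite and
    several segmentation tests share one trained network.
    """
    imgs = [enhancement.enhance(im) for im in seg_dataset.images[:30]]
    net = dss.build_saliency_net(
        SaliencyNetSpec(input_size=64, n_classes=2, epochs=3, seed=0))
    dss.train_saliency_net(net, imgs, seg_dataset.labels[:30])
    return net


@pytest.fixture(scope="session")
def enhanced_test_images(seg_dataset):
    return [enhancement.enhance(im) for im in seg_dataset.images[30:]]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
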