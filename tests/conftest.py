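import numpy as np
import pytest

from lungcad.phantom import default_test_spec, generate_phantom
from lungcad.segmentation import segment_lungs


@pytest.fixture(scope="session")
def easy_phantom():
    """Easy preset at noise_sd=20 with its segmentation, computed once."""
    spec = default_test_spec("easy", seed=1, noise_sd=20.0)
    volume, annotations, gt_mask = generate_phantom(spec)
    mask, parenchyma = segment_lungs(volume)
    return {
        "spec": spec,
        "volume": volume,
        "annotations": annotations,
        "gt_mask": gt_mask,
        "mask": mask,
        "parenchyma": parenchyma,
    }


@pytest.fixture(scope="session")
def vessel_phantom():
    """Vessel-heavy preset, noise-free, with its segmentation."""
    spec = default_test_spec("vessel-heavy", seed=0, noise_sd=0.0)
    volume, annotations, gt_mask = generate_phantom(spec)
    mask, parenchyma = segment_lungs(volume)
    return {
        "spec": spec,
        "volume": volume,
        "annotations": annotations,
        "gt_mask": gt_mask,
        "mask": mask,
        "parenchyma": parenchyma,
    }


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
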