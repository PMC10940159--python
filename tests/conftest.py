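import numpy as np
import pytest
from skimage import draw

from lysomech import synthetic as syn
from lysomech.segmentation import extract_objects


@pytest.fixture(scope="session")
def five_lobe():
    """Mildly lobed organelle shape with mixed-sign exact curvature."""
    spec = syn.ShapeSpec(r0_um=2.5, harmonics=[(5, 0.15, 0.0)])
    return syn.make_shape(spec)


def disk_mask(radius_px: float, pad: int = 10) -> np.ndarray:
    half = int(np.ceil(radius_px)) + pad
    size = 2 * half + 1
    m = np.zeros((size, size), dtype=np.uint8)
    rr, cc = draw.disk((half, half), radius_px + 0.2)
    m[rr, cc] = 1
    return m


def single_object(mask: np.ndarray, intensity=None, frame: int = 0):
    objs = extract_objects(mask, intensity_image=intensity, frame=frame)
    assert len(objs) == 1
    return objs[0]


@pytest.fixture(scope="session")
def disk20():
    return disk_mask(20)
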