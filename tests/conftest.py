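import numpy as np
import pytest
from scipy.ndimage import label

from soilplant import make_scene


def brute_force_area_opening(img: np.ndarray, lam: int,
                             connectivity: int = 4) -> np.ndarray:
    """Independent level-set oracle for area opening.

    Thresholds the image at every gray level, labels the connected
    components of each upper level set, and keeps a pixel at level t only
    if its component has at least ``lam`` pixels; the result at a pixel is
    the highest surviving level.
    """
    img = np.asarray(img, float)
    struct = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
              if connectivity == 4 else np.ones((3, 3), int))
    out = np.full(img.shape, img.min())
    for t in np.unique(img):
        lab, n = label(img >= t, structure=struct)
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, bool)
        keep[1:] = sizes[1:] >= lam
        out[keep[lab]] = t
    return out


@pytest.fixture(scope="session")
def small_scene():
    """30 m x 30 m scene at 10 cm pixels, high contrast, fixed seed."""
    return make_scene(extent_m=(30.0, 30.0), cell_size=0.10, seed=7,
                      plant_density=0.7, green_contrast=70.0, noise_sd=4.0)


@pytest.fixture(scope="session")
def small_profile(small_scene):
    from soilplant import build_profile
    return build_profile(small_scene.rgb, thresholds=(25, 100))
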