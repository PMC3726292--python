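import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from filodetect.records import GrayImage

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_image(arr, pixel_size_um=0.1, bit_depth=8):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return GrayImage(pixels=np.asarray(arr, dtype=dtype), bit_depth=bit_depth,
                     pixel_size_um=pixel_size_um)


@pytest.fixture
def disk_cell_image():
    """Clean synthetic cell: a bright disk (200) on dark background (10)."""
    yy, xx = np.mgrid[0:128, 0:128]
    disk = np.hypot(yy - 64, xx - 64) <= 40
    arr = np.where(disk, 200, 10).astype(np.uint8)
    return make_image(arr), disk
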