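"""Reading and writing grayscale images as PNG/TIFF."""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .imaging_core import ImageGrid


def read_image(path) -> ImageGrid:
    """Read a single-channel image and rescale intensities to [0, 1].

    Multi-channel input is converted to grayscale by averaging channels;
    integer dtypes are divided by their max representable value.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.shape[0] != arr.shape[1]:
        side = min(arr.shape)
        arr = arr[:side, :side]
    return ImageGrid(arr)


def write_image(path, img: ImageGrid) -> None:
    """Write an image as 8-bit grayscale, clipping values to [0, 1]."""
    out = np.clip(img.values, 0.0, 1.0)
    iio.imwrite(path, (out * 255).round().astype(np.uint8))
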