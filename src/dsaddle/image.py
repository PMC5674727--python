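"""Image loading and the grayscale working representation.

All pipeline code operates on 2D float64 arrays with intensities in [0, 1]
("gray images").  Color fundus photographs are reduced to the green channel,
which carries the highest vessel-to-background contrast in fundus
photography; already-gray input is used as-is (rescaled to [0, 1]).
"""

from __future__ import annotations

import numpy as np
from PIL import Image


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a gray image (float64, [0, 1], 2D).

    Raises ``ValueError`` for non-2D input, non-finite values, values outside
    [0, 1], or images smaller than 8 pixels along either axis (below which
    the candidate lattice of the detector is empty by construction).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"gray image must be 2D, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("gray image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("gray image intensities must lie in [0, 1]")
    return img


def to_gray(arr: np.ndarray) -> np.ndarray:
    """Convert an array image (H×W or H×W×C, any dtype) to a [0, 1] gray image.

    RGB(A) input uses the green channel; single-channel input is used
    directly.  Integer dtypes are scaled by their max value.
    """
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 1]  # green channel: best vessel contrast in fundus
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
        if arr.size and arr.max() > 1.0:
            arr = arr / 255.0
    return validate_gray(np.clip(arr, 0.0, 1.0))


def load_image(path) -> np.ndarray:
    """Load PNG/TIFF/JPEG from *path* as a [0, 1] gray image."""
    with Image.open(path) as im:
        return to_gray(np.asarray(im))


def load_working(path, working_resolution: int | None = None) -> np.ndarray:
    """Load an image and, if requested, resize it to the square working
    resolution (e.g. 583) at which the pipeline processes fundus images."""
    from skimage.transform import resize

    img = load_image(path)
    if working_resolution and img.shape != (working_resolution, working_resolution):
        img = resize(img, (working_resolution, working_resolution), order=1,
                     mode="reflect", anti_aliasing=True, preserve_range=True)
        img = np.clip(img, 0.0, 1.0)
    return img


def save_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] gray image as an 8-bit grayscale file."""
    img = validate_gray(img)
    Image.fromarray((np.clip(img, 0, 1) * 255).round().astype(np.uint8)).save(path)
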