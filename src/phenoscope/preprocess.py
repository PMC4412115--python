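"""Flat-field illumination correction and image I/O.

Microscope illumination is never perfectly even across the field of view;
dividing each micrograph by a blank (no-sample) image of the same session
removes the smooth multiplicative irregularity.  The blank is median-smoothed
before division so that its own shot noise is not imprinted onto the
corrected image, and the quotient is rescaled by the blank's per-channel mean
so corrected brightness stays comparable across sessions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["correct_illumination", "smooth_blank", "read_image", "write_image"]


def smooth_blank(blank: np.ndarray, size: int = 5) -> np.ndarray:
    """Median-smooth a blank once so it can be reused across a batch
    (pass the result to :func:`correct_illumination` with smooth_size=1)."""
    blk = _as_rgb(blank, "blank")
    if size <= 1:
        return blk
    return np.stack(
        [
            ndimage.median_filter(blk[:, :, ch], size=size, mode="nearest")
            for ch in range(3)
        ],
        axis=2,
    )


def _as_rgb(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError(f"{name} must be an H x W x 3 array, got shape {a.shape}")
    return a.astype(float)


def correct_illumination(
    image: np.ndarray, blank: np.ndarray, smooth_size: int = 5
) -> np.ndarray:
    """Divide ``image`` by the smoothed ``blank``, rescaled to the blank mean.

    Per channel: ``out = image * mean(blank) / median_filter(blank)``, clipped
    to [0, 255] and rounded half-up to 8 bit.  A constant blank is therefore
    the identity.

    Parameters
    ----------
    image, blank : ndarray, shape (H, W, 3)
        8-bit RGB micrograph and the session's no-sample image.
    smooth_size : int
        Side of the median filter applied to the blank (1 disables smoothing).

    Raises
    ------
    ValueError
        If the shapes differ, or if any smoothed blank pixel is zero (the
        error names the offending channel and pixel).
    """
    img = _as_rgb(image, "image")
    blk = _as_rgb(blank, "blank")
    if img.shape != blk.shape:
        raise ValueError(
            f"image shape {img.shape} does not match blank shape {blk.shape}"
        )
    out = np.empty_like(img)
    for ch, name in enumerate(("red", "green", "blue")):
        b = blk[:, :, ch]
        if smooth_size > 1:
            b = ndimage.median_filter(b, size=smooth_size, mode="nearest")
        if b.min() <= 0:
            r, c = np.argwhere(b <= 0)[0]
            raise ValueError(
                f"blank {name} channel is zero at pixel (row={r}, col={c}) "
                "after smoothing; correction undefined"
            )
        out[:, :, ch] = img[:, :, ch] * (b.mean() / b)
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB TIFF or PNG as an H x W x 3 uint8 array."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got dtype {arr.dtype}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an H x W x 3 uint8 array as TIFF or PNG (by extension)."""
    import imageio.v3 as iio

    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        raise ValueError("image must be uint8")
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), arr, photometric="rgb")
    else:
        iio.imwrite(str(path), arr)
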