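"""Cell segmentation: maximum-entropy thresholding and particle registration.

The red and green channels are thresholded independently with the
Kapur/MaxEntropy criterion (viable cells carry the red chlorophyll signal,
dead cells only the unspecific green one), the two binary masks are combined
by pixelwise union, and connected components are registered as particles.
Particles smaller than 10 px and particles touching the image edge are
excluded as artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "kapur_threshold",
    "channel_histogram",
    "segment_cells",
    "Particle",
    "ExclusionTallies",
]

MIN_AREA_PX = 10  # strict reading: area >= 10 survives


@dataclass(frozen=True)
class Particle:
    """One registered connected component.

    ``bbox`` is half-open ``(row_min, col_min, row_max, col_max)``;
    ``centroid`` is the (row, col) pixel-coordinate mean.
    """

    id: int
    area_px: int
    bbox: tuple[int, int, int, int]
    touches_border: bool
    centroid: tuple[float, float]


@dataclass
class ExclusionTallies:
    n_size: int = 0
    n_border: int = 0

    @property
    def total(self) -> int:
        return self.n_size + self.n_border


def channel_histogram(channel: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram of one 8-bit channel."""
    ch = np.asarray(channel)
    if ch.min() < 0 or ch.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    return np.bincount(ch.astype(np.int64).ravel(), minlength=256)


def kapur_threshold(hist: np.ndarray) -> int:
    """Maximum-entropy (Kapur) threshold of a 256-bin histogram.

    Returns the level ``t`` in [0, 254] maximizing the sum of the Shannon
    entropies of the two class-conditional distributions: background = bins
    <= t, foreground = bins > t.  Candidates with an empty class on either
    side are skipped; ties are broken toward the smallest ``t``.

    Raises
    ------
    ValueError
        If the histogram has mass in fewer than two distinct bins (no valid
        split exists).
    """
    counts = np.asarray(hist, dtype=float)
    if counts.shape != (256,) or (counts < 0).any():
        raise ValueError("hist must be 256 nonnegative counts")
    total = counts.sum()
    if total <= 0 or np.count_nonzero(counts) < 2:
        raise ValueError("histogram needs mass in at least two bins to threshold")

    p = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    w = np.cumsum(p)  # w[t] = P(level <= t)
    s = np.cumsum(plogp)  # s[t] = sum_{i<=t} p_i log p_i
    w0 = w[:-1]  # candidates t = 0..254
    w1 = 1.0 - w0
    s0 = s[:-1]
    s1 = s[-1] - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(w0) - s0 / w0
        h1 = np.log(w1) - s1 / w1
    crit = h0 + h1
    crit[(w0 <= 0) | (w1 <= 0)] = -np.inf
    # np.argmax returns the first maximum -> smallest t on ties
    return int(np.argmax(crit))


def _threshold_channel(channel: np.ndarray, name: str) -> np.ndarray:
    try:
        t = kapur_threshold(channel_histogram(channel))
    except ValueError as exc:
        raise ValueError(f"thresholding failed on {name} channel: {exc}") from exc
    return channel > t


def segment_cells(
    image: np.ndarray,
    min_area: int = MIN_AREA_PX,
    connectivity: int = 2,
) -> tuple[np.ndarray, list[Particle], ExclusionTallies]:
    """Segment cells from an illumination-corrected RGB micrograph.

    Red and green channels are thresholded independently with
    :func:`kapur_threshold` (foreground = levels above the threshold), the
    binary masks are united, and connected components (8-connected by
    default) are registered.  Components with area below ``min_area`` and
    components touching the image edge are excluded; survivors are relabeled
    1..n.  A component failing both rules is tallied once, under the size
    rule.

    Returns
    -------
    labels : ndarray of int32, shape (H, W)
        0 = background, 1..n = surviving particles.
    particles : list of Particle
    tallies : ExclusionTallies
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"image must be H x W x 3, got shape {img.shape}")
    fg = _threshold_channel(img[:, :, 0], "red") | _threshold_channel(
        img[:, :, 1], "green"
    )
    raw_labels = measure.label(fg, connectivity=connectivity)

    h, w = fg.shape
    tallies = ExclusionTallies()
    particles: list[Particle] = []
    relabel = np.zeros(raw_labels.max() + 1, dtype=np.int32)
    next_id = 1
    for region in measure.regionprops(raw_labels):
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if region.area < min_area:
            tallies.n_size += 1
            continue
        if touches:
            tallies.n_border += 1
            continue
        relabel[region.label] = next_id
        particles.append(
            Particle(
                id=next_id,
                area_px=int(region.area),
                bbox=(r0, c0, r1, c1),
                touches_border=False,
                centroid=tuple(float(x) for x in region.centroid),
            )
        )
        next_id += 1
    return relabel[raw_labels], particles, tallies
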