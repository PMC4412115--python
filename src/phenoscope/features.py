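"""Per-particle colour features: normalized hue histogram + mean brightness.

Phenotype classes differ almost purely in colour, so each registered
particle is described by the distribution of hexcone hue over its member
pixels (red ~ 0, yellow ~ 1/6, green ~ 1/3 on the 0-1 scale) plus the mean
HSV value, which separates the dimmer orange producer cells from bright
wild-type cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

__all__ = ["FeatureConfig", "extract_features", "feature_table", "hsv_planes"]

DEFAULT_N_BINS = 32


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction settings; the fingerprint ties a trained model to
    the exact convention used at training time."""

    n_bins: int = DEFAULT_N_BINS
    #: achromatic pixels (max == min) are assigned hue 0 by the hexcone
    #: transform; any fixed convention works as long as it is consistent.
    achromatic_hue: float = 0.0
    #: mean brightness is appended as one extra input after the histogram,
    #: not normalized jointly with it.
    append_brightness: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def n_features(self) -> int:
        return self.n_bins + (1 if self.append_brightness else 0)

    def fingerprint(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "achromatic_hue": self.achromatic_hue,
            "append_brightness": self.append_brightness,
        }


def hsv_planes(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue and value planes of an 8-bit RGB image (both on a 0-1 scale)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"image must be H x W x 3, got shape {img.shape}")
    hsv = rgb2hsv(img.astype(float) / 255.0)
    return hsv[:, :, 0], hsv[:, :, 2]


def _features_from_pixels(
    hue: np.ndarray, value: np.ndarray, config: FeatureConfig
) -> np.ndarray:
    bins = np.minimum((hue * config.n_bins).astype(int), config.n_bins - 1)
    hist = np.bincount(bins, minlength=config.n_bins).astype(float)
    hist /= hue.size
    if config.append_brightness:
        return np.concatenate([hist, [float(value.mean())]])
    return hist


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    particle_id: int,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Feature vector of one particle: hue histogram (sums to 1) followed by
    the mean brightness (mean HSV value of the member pixels).

    ``image`` must be the same illumination-corrected image the mask was
    segmented from.

    Raises
    ------
    ValueError
        If ``particle_id`` is absent from the mask.
    """
    config = config or FeatureConfig()
    member = np.asarray(mask) == particle_id
    if not member.any():
        raise ValueError(f"particle id {particle_id} not present in mask")
    hue, value = hsv_planes(image)
    return _features_from_pixels(hue[member], value[member], config)


def feature_table(
    image: np.ndarray,
    mask: np.ndarray,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature matrix for every particle in the mask (rows indexed by
    particle id, columns ``b0..b{B-1}`` plus ``brightness``)."""
    config = config or FeatureConfig()
    labels = np.asarray(mask)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    hue, value = hsv_planes(image)
    rows = [
        _features_from_pixels(hue[labels == pid], value[labels == pid], config)
        for pid in ids
    ]
    cols = [f"b{i}" for i in range(config.n_bins)]
    if config.append_brightness:
        cols.append("brightness")
    return pd.DataFrame(
        np.array(rows).reshape(len(ids), config.n_features),
        index=pd.Index(ids.astype(int), name="particle_id"),
        columns=cols,
    )
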