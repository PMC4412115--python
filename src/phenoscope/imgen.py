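"""Synthetic fluorescence-micrograph generator with ground truth.

Emulates 40x epifluorescence images of cyanobacterial monolayers in which
three pigmentation phenotypes are distinguishable by colour: viable cells
with wild-type pigmentation fluoresce red (chlorophyll + phycocyanin),
ethanol-producing cells with down-regulated phycocyanin fluoresce orange
(red and green signal of comparable intensity), and dead cells without
photopigments fluoresce green.  Every rendered scene carries a full ground
truth (per-cell class, position, shape and pixel membership) so that the
segmentation, feature-extraction and classification stages can be validated
without real microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WT_RED",
    "PRODUCER_ORANGE",
    "DEAD_GREEN",
    "CLASS_LABELS",
    "PhenotypeSpec",
    "SceneConfig",
    "CellTruth",
    "SceneTruth",
    "PlacementError",
    "default_phenotypes",
    "render_scene",
    "render_blank",
]

WT_RED = "WT_RED"
PRODUCER_ORANGE = "PRODUCER_ORANGE"
DEAD_GREEN = "DEAD_GREEN"

#: Fixed class ordering used everywhere (one-hot encoding, report columns).
CLASS_LABELS = (WT_RED, PRODUCER_ORANGE, DEAD_GREEN)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Rendering recipe for one pigmentation phenotype.

    Parameters
    ----------
    class_label : str
        One of :data:`CLASS_LABELS`.
    red_mean, green_mean, blue_mean : float
        Mean 8-bit channel intensities of a cell of this phenotype.
    channel_sd : float
        Per-pixel Gaussian spread of the channel intensities inside a cell
        (applied only when the scene's ``noise_sd`` is nonzero; see
        :func:`render_scene`).
    radius_range : tuple of float
        Inclusive interval from which the two ellipse semi-axes are drawn
        uniformly, in pixels.
    """

    class_label: str
    red_mean: float
    green_mean: float
    blue_mean: float
    channel_sd: float = 15.0
    radius_range: tuple[float, float] = (3.0, 8.0)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for name in ("red_mean", "green_mean", "blue_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"radius_range {self.radius_range} must be positive")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.red_mean, self.green_mean, self.blue_mean], float)


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """Default colour recipes for the three phenotypes.

    Chosen so that the hexcone hue separates the classes the way the
    phenotypes separate under the 388 nm excitation / 510 nm long-pass
    filter set: wild type strongly red-dominant, producer with red ~ green
    ("orange" and less bright), dead cells green-dominant.
    """
    return {
        WT_RED: PhenotypeSpec(WT_RED, 200, 40, 10),
        PRODUCER_ORANGE: PhenotypeSpec(PRODUCER_ORANGE, 150, 130, 10),
        DEAD_GREEN: PhenotypeSpec(DEAD_GREEN, 30, 180, 20),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, mixture and noise settings for one synthetic scene.

    ``class_fractions`` follows the :data:`CLASS_LABELS` order
    (wt, producer, dead).  ``vignette_strength`` is the relative drop of the
    multiplicative illumination field at the image corners (0 = flat field).
    Fixing ``seed`` fixes every byte of the rendered scene and its truth.
    """

    image_height: int = 768
    image_width: int = 1024
    n_cells: int = 50
    class_fractions: tuple[float, float, float] = (1.0, 0.0, 0.0)
    vignette_strength: float = 0.25
    noise_sd: float = 15.0
    background_level: float = 10.0
    seed: int = 0
    allow_border_cells: bool = False
    min_center_distance: float = 18.0
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        f = np.asarray(self.class_fractions, float)
        if f.shape != (3,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must be 3 nonnegative values summing to 1")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must lie in [0, 1)")

    def with_(self, **kw) -> "SceneConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one rendered cell; ``pixels`` are (rows, cols) of the
    pre-noise interior."""

    id: int
    class_label: str
    center: tuple[float, float]  # (row, col)
    radii: tuple[float, float]  # (semi-axis rows, semi-axis cols)
    pixels: tuple[np.ndarray, np.ndarray]

    @property
    def area_px(self) -> int:
        return int(self.pixels[0].size)


@dataclass
class SceneTruth:
    cells: list[CellTruth]
    image: np.ndarray  # H x W x 3 uint8
    blank_reference: np.ndarray  # H x W x 3 uint8
    config: SceneConfig = field(repr=False, default=None)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_LABELS}
        for cell in self.cells:
            counts[cell.class_label] += 1
        return counts


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested density."""


def scene_config_from_yaml(path) -> tuple[SceneConfig, dict[str, PhenotypeSpec]]:
    """Load a scene configuration (and optional phenotype overrides) from YAML.

    Top-level keys mirror :class:`SceneConfig` fields; an optional
    ``phenotypes`` mapping overrides :func:`default_phenotypes` entries,
    each with ``red_mean``/``green_mean``/``blue_mean`` and optionally
    ``channel_sd`` and ``radius_range``.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    pheno_doc = doc.pop("phenotypes", {}) or {}
    config = SceneConfig(**{k: tuple(v) if k == "class_fractions" else v
                            for k, v in doc.items()})
    specs = default_phenotypes()
    for label, fields in pheno_doc.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown phenotype {label!r} in {path}")
        fields = dict(fields)
        if "radius_range" in fields:
            fields["radius_range"] = tuple(fields["radius_range"])
        specs[label] = PhenotypeSpec(class_label=label, **fields)
    return config, specs


def _illumination_field(config: SceneConfig) -> np.ndarray:
    """Radial quadratic vignette, normalized to unit mean.

    The relative corner-to-centre drop equals ``vignette_strength``; the
    unit-mean scaling makes the field exactly invertible by a flat-field
    correction that rescales by the blank's mean.
    """
    h, w = config.image_height, config.image_width
    rows = np.arange(h, dtype=float)[:, None] - (h - 1) / 2.0
    cols = np.arange(w, dtype=float)[None, :] - (w - 1) / 2.0
    d2 = rows**2 + cols**2
    d2max = ((h - 1) / 2.0) ** 2 + ((w - 1) / 2.0) ** 2
    if d2max == 0:
        return np.ones((h, w))
    field_ = 1.0 - config.vignette_strength * d2 / d2max
    return field_ / field_.mean()


def _to_uint8(img: np.ndarray) -> np.ndarray:
    # round half up, matching the 8-bit conversion used throughout
    return np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)


def _place_centers(
    config: SceneConfig, radii: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample cell centres at pairwise distance >= min_center_distance."""
    h, w = config.image_height, config.image_width
    centers = np.empty((len(radii), 2))
    for i, (ra, rc) in enumerate(radii):
        if config.allow_border_cells:
            lo_r, hi_r, lo_c, hi_c = 0.0, h - 1.0, 0.0, w - 1.0
        else:
            # keep the full ellipse strictly inside the frame (one-pixel margin
            # so no member pixel lies on the border rows/cols)
            lo_r, hi_r = ra + 1.0, h - 2.0 - ra
            lo_c, hi_c = rc + 1.0, w - 2.0 - rc
            if lo_r > hi_r or lo_c > hi_c:
                raise PlacementError("cell radius too large for the image frame")
        for _ in range(config.max_placement_tries):
            cand = np.array(
                [rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)]
            )
            if i == 0:
                centers[0] = cand
                break
            d2 = np.sum((centers[:i] - cand) ** 2, axis=1)
            if d2.min() >= config.min_center_distance**2:
                centers[i] = cand
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{len(radii)} after "
                f"{config.max_placement_tries} tries; reduce n_cells or "
                f"min_center_distance"
            )
    return centers


def _ellipse_pixels(
    center: np.ndarray, radii: np.ndarray, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    cr, cc = center
    ra, rc = radii
    r0, r1 = int(np.floor(cr - ra)), int(np.ceil(cr + ra))
    c0, c1 = int(np.floor(cc - rc)), int(np.ceil(cc + rc))
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0] - 1), min(c1, shape[1] - 1)
    rr = np.arange(r0, r1 + 1)[:, None]
    cc_ = np.arange(c0, c1 + 1)[None, :]
    inside = ((rr - cr) / ra) ** 2 + ((cc_ - cc) / rc) ** 2 <= 1.0
    rows, cols = np.nonzero(inside)
    return rows + r0, cols + c0


def render_scene(
    config: SceneConfig, specs: dict[str, PhenotypeSpec] | None = None
) -> SceneTruth:
    """Render a synthetic micrograph with known ground truth.

    Cells are axis-aligned ellipses with semi-axes drawn uniformly from each
    phenotype's ``radius_range``, class labels drawn independently from
    ``class_fractions``, placed by rejection sampling so that no two centres
    come closer than ``min_center_distance``.  The pre-noise image (cells at
    their exact phenotype means on a flat background) is multiplied by the
    smooth illumination field; when ``noise_sd`` > 0 Gaussian noise is then
    added (sd ``noise_sd`` on background pixels, the phenotype's
    ``channel_sd`` inside cells) and the result clipped to 8 bit.

    Returns a :class:`SceneTruth` whose ``blank_reference`` is the matching
    no-sample image from :func:`render_blank`.
    """
    specs = default_phenotypes() if specs is None else specs
    missing = [c for c in CLASS_LABELS if c not in specs]
    if missing:
        raise ValueError(f"specs missing phenotypes: {missing}")
    rng = np.random.default_rng([int(config.seed), 0])
    h, w = config.image_height, config.image_width

    labels = [
        CLASS_LABELS[k]
        for k in rng.choice(3, size=config.n_cells, p=np.asarray(config.class_fractions))
    ]
    radii = np.array(
        [
            rng.uniform(*specs[lab].radius_range, size=2)
            for lab in labels
        ]
    ).reshape(config.n_cells, 2)
    centers = (
        _place_centers(config, radii, rng) if config.n_cells else np.empty((0, 2))
    )

    clean = np.full((h, w, 3), config.background_level, dtype=float)
    cell_mask = np.zeros((h, w), dtype=bool)
    cell_sd = np.zeros((h, w), dtype=float)
    cells: list[CellTruth] = []
    for i, lab in enumerate(labels):
        rows, cols = _ellipse_pixels(centers[i], radii[i], (h, w))
        clean[rows, cols] = specs[lab].means
        cell_mask[rows, cols] = True
        cell_sd[rows, cols] = specs[lab].channel_sd
        cells.append(
            CellTruth(
                id=i + 1,
                class_label=lab,
                center=tuple(centers[i]),
                radii=tuple(radii[i]),
                pixels=(rows, cols),
            )
        )

    field_ = _illumination_field(config)
    img = clean * field_[:, :, None]
    if config.noise_sd > 0:
        sd = np.where(cell_mask, cell_sd, config.noise_sd)
        img = img + rng.standard_normal((h, w, 3)) * sd[:, :, None]
    image = _to_uint8(img)

    blank = render_blank(config)
    return SceneTruth(cells=cells, image=image, blank_reference=blank, config=config)


def render_blank(config: SceneConfig) -> np.ndarray:
    """Render the no-sample (blank) image of the same imaging session.

    The illumination field is identical to the one applied in
    :func:`render_scene` for the same config, scaled to a mean of mid-gray
    (128); because the flat-field correction rescales by the blank's mean,
    a ``noise_sd`` = 0 blank then inverts the field exactly up to 8-bit
    rounding.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    field_ = _illumination_field(config)
    img = np.repeat((field_ * 128.0)[:, :, None], 3, axis=2)
    if config.noise_sd > 0:
        img = img + rng.standard_normal(img.shape) * config.noise_sd
    return _to_uint8(img)
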