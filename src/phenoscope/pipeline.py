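"""Batch orchestration: correct, segment, featurize and classify micrographs.

A *sample* is a set of micrographs of one culture (20 stage positions per
sample in the reference protocol, totalling 500-1000 cells) plus one blank
image of the session.  ``analyze_sample`` runs every stage per image and
aggregates the per-class counts into a :class:`SampleReport`;
``mixing_experiment`` reproduces the wt/producer mixing validation entirely
in silico on generated scenes with known mixing ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import imgen
from .classify import PhenotypeNetClassifier, train
from .features import FeatureConfig, feature_table
from .imgen import CLASS_LABELS, DEAD_GREEN, SceneConfig, render_blank, render_scene
from .preprocess import correct_illumination, smooth_blank
from .segment import segment_cells

__all__ = [
    "SampleReport",
    "analyze_sample",
    "make_training_set",
    "train_default_model",
    "mixing_experiment",
]

logger = logging.getLogger("phenoscope")

#: Reference protocol: 20 stage positions per sample, >= 500 cells monitored.
DEFAULT_IMAGES_PER_SAMPLE = 20
MIN_RECOMMENDED_CELLS = 500


@dataclass
class SampleReport:
    """Aggregated phenotype counts for one sample.

    ``class_fractions`` are over all classified particles;
    ``viable_fractions`` restrict the denominator to non-dead particles
    (wt + producer), the quantity of interest when tracking revertants.
    The accounting identity ``sum(class_counts) + n_excluded_size +
    n_excluded_border == n_particles_total`` always holds.
    """

    n_images: int
    n_particles_total: int
    n_excluded_size: int
    n_excluded_border: int
    class_counts: dict[str, int]
    class_fractions: dict[str, float]
    viable_fractions: dict[str, float]
    per_image: pd.DataFrame
    particles: pd.DataFrame = field(repr=False)
    failed_images: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_classified(self) -> int:
        return sum(self.class_counts.values())


def _fractions(counts: dict[str, int], labels) -> dict[str, float]:
    total = sum(counts[c] for c in labels)
    if total == 0:
        return {c: float("nan") for c in labels}
    return {c: counts[c] / total for c in labels}


def analyze_sample(
    images: list[np.ndarray],
    blank: np.ndarray,
    model: PhenotypeNetClassifier,
    feature_config: FeatureConfig | None = None,
    min_area: int = 10,
) -> SampleReport:
    """Run the full per-image pipeline and aggregate a sample report.

    Each image is illumination-corrected with ``blank``, segmented, its
    particles featurized and classified.  A failing image is logged and
    skipped; the sample fails only if every image fails.
    """
    if len(images) == 0:
        raise ValueError("analyze_sample needs at least one image")
    feature_config = feature_config or FeatureConfig()
    model.check_fingerprint(feature_config)
    blank_smooth = smooth_blank(blank)  # smooth once, reuse for every image

    counts = {c: 0 for c in CLASS_LABELS}
    n_total = n_size = n_border = 0
    per_image_rows = []
    particle_rows = []
    failed: list[tuple[int, str]] = []
    for idx, img in enumerate(images):
        try:
            corrected = correct_illumination(img, blank_smooth, smooth_size=1)
            mask, particles, tallies = segment_cells(corrected, min_area=min_area)
            feats = feature_table(corrected, mask, feature_config)
            if len(feats):
                act = model.predict_proba(feats.to_numpy())
                pred = model.classes_[np.argmax(act, axis=1)]
            else:
                act = np.zeros((0, len(model.classes_)))
                pred = np.array([], dtype=object)
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            logger.error("image %d failed: %s", idx, exc)
            failed.append((idx, str(exc)))
            continue
        registered = len(particles) + tallies.total
        n_total += registered
        n_size += tallies.n_size
        n_border += tallies.n_border
        img_counts = {c: 0 for c in CLASS_LABELS}
        for pid, cls, a in zip(feats.index, pred, act):
            img_counts[cls] += 1
            particle_rows.append(
                {
                    "image": idx,
                    "particle_id": int(pid),
                    "class": cls,
                    **{f"act_{c}": float(v) for c, v in zip(model.classes_, a)},
                }
            )
        for c in CLASS_LABELS:
            counts[c] += img_counts[c]
        per_image_rows.append(
            {
                "image": idx,
                "n_registered": registered,
                "n_excluded_size": tallies.n_size,
                "n_excluded_border": tallies.n_border,
                **{f"n_{c}": img_counts[c] for c in CLASS_LABELS},
            }
        )
    if not per_image_rows:
        raise RuntimeError("every image in the sample failed to process")

    n_classified = sum(counts.values())
    if n_classified < MIN_RECOMMENDED_CELLS:
        logger.warning(
            "only %d cells classified; the protocol recommends monitoring "
            "at least %d cells per sample",
            n_classified,
            MIN_RECOMMENDED_CELLS,
        )
    viable = [c for c in CLASS_LABELS if c != DEAD_GREEN]
    return SampleReport(
        n_images=len(per_image_rows),
        n_particles_total=n_total,
        n_excluded_size=n_size,
        n_excluded_border=n_border,
        class_counts=counts,
        class_fractions=_fractions(counts, CLASS_LABELS),
        viable_fractions=_fractions(counts, viable),
        per_image=pd.DataFrame(per_image_rows),
        particles=pd.DataFrame(particle_rows),
        failed_images=failed,
    )


# -------------------------------------------------------------- training data

#: Frame geometry used for generated training/mixing scenes: 640x480 frames
#: with ~50 cells keep a 20-frame sample at the protocol's ~1000 cells.
TRAIN_SCENE_SHAPE = (480, 640)


def make_training_set(
    n_per_class: int = 100,
    seed: int = 0,
    specs: dict | None = None,
    feature_config: FeatureConfig | None = None,
    scene_shape: tuple[int, int] = TRAIN_SCENE_SHAPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled feature vectors from single-class synthetic scenes.

    Renders one pure scene per phenotype under the default imaging
    conditions, runs the correction/segmentation/feature stages, and keeps
    the first ``n_per_class`` particles of each class.
    """
    feature_config = feature_config or FeatureConfig()
    rows, labels = [], []
    for k, label in enumerate(CLASS_LABELS):
        fractions = tuple(1.0 if i == k else 0.0 for i in range(3))
        n_cells = int(np.ceil(n_per_class * 1.25))
        config = SceneConfig(
            image_height=scene_shape[0],
            image_width=scene_shape[1],
            n_cells=n_cells,
            class_fractions=fractions,
            seed=int(seed) * 8 + k,
        )
        scene = render_scene(config, specs)
        corrected = correct_illumination(scene.image, scene.blank_reference)
        mask, particles, _ = segment_cells(corrected)
        feats = feature_table(corrected, mask, feature_config)
        if len(feats) < n_per_class:
            raise RuntimeError(
                f"scene produced only {len(feats)} {label} particles; "
                f"needed {n_per_class}"
            )
        rows.append(feats.to_numpy()[:n_per_class])
        labels.extend([label] * n_per_class)
    return np.vstack(rows), np.array(labels, dtype=object)


def train_default_model(
    n_per_class: int = 100,
    seed: int = 0,
    specs: dict | None = None,
    feature_config: FeatureConfig | None = None,
    **train_kwargs,
) -> PhenotypeNetClassifier:
    """Train a phenotype network on a freshly generated synthetic set."""
    feature_config = feature_config or FeatureConfig()
    X, y = make_training_set(n_per_class, seed, specs, feature_config)
    model = PhenotypeNetClassifier(
        random_state=int(seed), feature_config=feature_config, **train_kwargs
    )
    model.fit(X, y)
    return model


# ----------------------------------------------------------- mixing harness


def mixing_experiment(
    ratios,
    n_cells_per_sample: int = 1000,
    n_replicates: int = 3,
    seed: int = 0,
    model: PhenotypeNetClassifier | None = None,
    n_images: int = DEFAULT_IMAGES_PER_SAMPLE,
    specs: dict | None = None,
    feature_config: FeatureConfig | None = None,
    scene_shape: tuple[int, int] = TRAIN_SCENE_SHAPE,
) -> pd.DataFrame:
    """In-silico analogue of the wt/producer mixing validation.

    For every wt fraction in ``ratios`` and every replicate, renders
    ``n_images`` scenes totalling ~``n_cells_per_sample`` cells with class
    fractions (ratio, 1 - ratio, 0), analyzes the sample with ``model``
    (trained fresh from synthetic data when not supplied), and tabulates the
    estimated against the true phenotype fractions.

    Returns one row per (ratio, replicate) with the estimated wt, producer
    and dead fractions and the realized ground-truth wt fraction.
    """
    ratios = [float(r) for r in ratios]
    if any(not 0 <= r <= 1 for r in ratios):
        raise ValueError("ratios must lie in [0, 1]")
    if n_cells_per_sample < 100:
        raise ValueError("n_cells_per_sample must be >= 100")
    feature_config = feature_config or FeatureConfig()
    if model is None:
        model = train_default_model(
            seed=int(seed) + 1_000_003, specs=specs, feature_config=feature_config
        )

    cells_per_image = max(1, round(n_cells_per_sample / n_images))
    root = np.random.SeedSequence([int(seed), 77])
    rows = []
    for ratio in ratios:
        for rep in range(n_replicates):
            sample_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            images = []
            true_wt = true_total = 0
            config = None
            for i in range(n_images):
                config = SceneConfig(
                    image_height=scene_shape[0],
                    image_width=scene_shape[1],
                    n_cells=cells_per_image,
                    class_fractions=(ratio, 1.0 - ratio, 0.0),
                    seed=(sample_seed + i) % (2**31),
                )
                scene = render_scene(config, specs)
                images.append(scene.image)
                counts = scene.class_counts()
                true_wt += counts[imgen.WT_RED]
                true_total += sum(counts.values())
            blank = render_blank(config)
            report = analyze_sample(images, blank, model, feature_config)
            rows.append(
                {
                    "true_ratio": ratio,
                    "replicate": rep,
                    "n_cells_true": true_total,
                    "n_classified": report.n_classified,
                    "true_wt_fraction": true_wt / true_total if true_total else np.nan,
                    "wt_fraction": report.class_fractions[imgen.WT_RED],
                    "producer_fraction": report.class_fractions[imgen.PRODUCER_ORANGE],
                    "dead_fraction": report.class_fractions[imgen.DEAD_GREEN],
                }
            )
    return pd.DataFrame(rows)
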