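"""Maximum-entropy thresholding (against a brute-force oracle) and particle
registration with the size/border exclusion rules."""

import numpy as np
import pytest
from skimage import measure

from phenoscope import (
    DEAD_GREEN,
    SceneConfig,
    kapur_threshold,
    render_scene,
    segment_cells,
)
from phenoscope.segment import channel_histogram

from conftest import draw_block, noiseless_config


def kapur_oracle(counts, tie_tol=1e-10):
    """Exhaustive search: score both class entropies directly from their
    definitions for every candidate threshold.

    Thresholds separated only by empty bins give mathematically identical
    partitions, so criterion values within ``tie_tol`` are treated as ties
    and resolved toward the smallest threshold (the stated convention).
    """
    counts = np.asarray(counts, float)
    p = counts / counts.sum()
    best_t, best_h = None, -np.inf
    for t in range(255):
        lo, hi = p[: t + 1], p[t + 1 :]
        w0, w1 = lo.sum(), hi.sum()
        if w0 <= 0 or w1 <= 0:
            continue
        q0 = lo[lo > 0] / w0
        q1 = hi[hi > 0] / w1
        h = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if h > best_h + tie_tol:
            best_h, best_t = h, t
    return best_t


class TestKapurThreshold:
    def test_two_spike_tie_breaks_to_smallest(self):
        hist = np.zeros(256, int)
        hist[50] = hist[200] = 10
        assert kapur_threshold(hist) == 50

    def test_matches_oracle_on_random_histograms(self):
        rng = np.random.default_rng(2024)
        for i in range(1000):
            if i % 3 == 0:  # dense
                hist = rng.integers(0, 100, size=256)
            elif i % 3 == 1:  # sparse
                hist = np.zeros(256, int)
                idx = rng.choice(256, size=rng.integers(2, 20), replace=False)
                hist[idx] = rng.integers(1, 1000, size=idx.size)
            else:  # smooth bimodal with random modes
                x = np.arange(256)
                m1, m2 = sorted(rng.integers(5, 250, size=2))
                hist = (
                    1000 * np.exp(-((x - m1) ** 2) / (2 * 15**2))
                    + 800 * np.exp(-((x - m2) ** 2) / (2 * 20**2))
                ).astype(int)
            if np.count_nonzero(hist) < 2:
                continue
            assert kapur_threshold(hist) == kapur_oracle(hist), f"histogram {i}"

    def test_separated_gaussian_modes(self):
        x = np.arange(256)
        hist = (
            1000 * np.exp(-((x - 60) ** 2) / 200)
            + 1000 * np.exp(-((x - 180) ** 2) / 200)
        ).astype(int)
        t = kapur_threshold(hist)
        assert 80 < t < 160
        assert t == kapur_oracle(hist)

    def test_single_bin_raises(self):
        hist = np.zeros(256, int)
        hist[100] = 50
        with pytest.raises(ValueError, match="at least two bins"):
            kapur_threshold(hist)

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError):
            kapur_threshold(np.zeros(256, int))

    def test_histogram_of_channel(self):
        channel = np.array([[0, 0, 5], [255, 5, 5]])
        hist = channel_histogram(channel)
        assert hist[0] == 2 and hist[5] == 3 and hist[255] == 1
        assert hist.sum() == channel.size


def blank_canvas(h=64, w=64):
    return np.zeros((h, w, 3), dtype=np.uint8)


class TestSegmentCells:
    def test_recovers_ground_truth_count_per_mix(self, noiseless_scene):
        mask, particles, tallies = segment_cells(noiseless_scene.image)
        assert len(particles) == len(noiseless_scene.cells)
        assert tallies.total == 0
        areas = sorted(p.area_px for p in particles)
        true_areas = sorted(c.area_px for c in noiseless_scene.cells)
        assert areas == true_areas

    @pytest.mark.parametrize(
        "fractions", [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.4, 0.4, 0.2)]
    )
    def test_count_exact_for_every_class_mix(self, fractions):
        scene = render_scene(
            noiseless_config(n_cells=15, class_fractions=fractions, seed=21)
        )
        _, particles, tallies = segment_cells(scene.image)
        assert len(particles) == 15
        assert tallies.total == 0

    def test_pure_dead_green_registered_via_union(self):
        """A cell visible only in the green channel is still registered."""
        scene = render_scene(
            noiseless_config(n_cells=12, class_fractions=(0, 0, 1), seed=2)
        )
        _, particles, _ = segment_cells(scene.image)
        assert len(particles) == 12

    def test_size_filter_strictly_below_ten(self):
        img = blank_canvas()
        draw_block(img, 10, 10, (3, 3), (200, 200, 0))  # 9 px -> excluded
        draw_block(img, 30, 30, (3, 4), (200, 200, 0))  # 12 px -> kept
        mask, particles, tallies = segment_cells(img)
        assert len(particles) == 1
        assert particles[0].area_px == 12
        assert tallies.n_size == 1
        assert tallies.n_border == 0

    def test_exactly_ten_pixels_survives(self):
        img = blank_canvas()
        draw_block(img, 10, 10, (2, 5), (200, 200, 0))  # area 10 survives
        _, particles, tallies = segment_cells(img)
        assert len(particles) == 1 and tallies.n_size == 0

    def test_border_touching_excluded(self):
        img = blank_canvas()
        draw_block(img, 0, 20, (4, 4), (200, 200, 0))  # touches row 0
        draw_block(img, 30, 30, (4, 4), (200, 200, 0))  # interior
        mask, particles, tallies = segment_cells(img)
        assert len(particles) == 1
        assert tallies.n_border == 1
        assert particles[0].bbox == (30, 30, 34, 34)

    @pytest.mark.parametrize(
        "row,col", [(0, 20), (60, 20), (20, 0), (20, 60)]
    )
    def test_all_four_borders_excluded(self, row, col):
        img = blank_canvas()
        draw_block(img, row, col, (4, 4), (200, 200, 0))
        draw_block(img, 28, 28, (4, 4), (200, 200, 0))
        _, particles, tallies = segment_cells(img)
        assert len(particles) == 1 and tallies.n_border == 1

    def test_filters_order_independent(self):
        """Survivors equal the raw components minus (small OR border) sets,
        whichever order the two rules are applied in."""
        img = blank_canvas()
        draw_block(img, 0, 5, (2, 3), (200, 200, 0))  # small AND border
        draw_block(img, 0, 30, (5, 5), (200, 200, 0))  # border only
        draw_block(img, 20, 20, (2, 3), (200, 200, 0))  # small only
        draw_block(img, 40, 40, (5, 5), (200, 200, 0))  # survivor
        fg = (img[:, :, 0] > 0) | (img[:, :, 1] > 0)
        raw = measure.label(fg, connectivity=2)
        survivors = set()
        for region in measure.regionprops(raw):
            r0, c0, r1, c1 = region.bbox
            border = r0 == 0 or c0 == 0 or r1 == raw.shape[0] or c1 == raw.shape[1]
            if region.area >= 10 and not border:
                survivors.add((region.bbox, region.area))
        _, particles, tallies = segment_cells(img)
        assert {(p.bbox, p.area_px) for p in particles} == survivors
        assert tallies.total == 3

    def test_relabeling_consecutive(self, noiseless_scene):
        mask, particles, _ = segment_cells(noiseless_scene.image)
        labels = np.unique(mask)
        assert labels[0] == 0
        assert list(labels[1:]) == [p.id for p in particles]
        assert [p.id for p in particles] == list(range(1, len(particles) + 1))

    def test_uniform_image_raises_naming_channel(self):
        img = np.full((32, 32, 3), 7, dtype=np.uint8)
        with pytest.raises(ValueError, match="red channel"):
            segment_cells(img)

    def test_touching_cells_merge_one_particle(self):
        img = blank_canvas()
        draw_block(img, 10, 10, (4, 4), (200, 200, 0))
        draw_block(img, 14, 14, (4, 4), (0, 200, 0))  # 8-connected via corner
        _, particles, _ = segment_cells(img)
        assert len(particles) == 1
        assert particles[0].area_px == 32
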