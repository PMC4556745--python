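"""Thresholding criteria vs brute-force scans; mask refinement behavior."""

import math

import numpy as np
import pytest
from scipy import ndimage

from fiberdiam import (
    DegenerateHistogramError,
    auto_local_window,
    smooth_mask,
    threshold_global,
    threshold_local,
    threshold_value,
)
from fiberdiam.segmentation import (
    huang_threshold,
    min_error_threshold,
    otsu_threshold,
)

LEVELS = np.arange(256)


# -- independent brute-force criterion scans (plain loops) -------------------
#
# Each criterion is re-derived here with direct summation; the scans return
# both the optimizing threshold and the optimal criterion value so that the
# implementation can be checked on *attained value* (empty histogram runs
# make the arg-optimum tie-degenerate).

def otsu_criterion(counts, t):
    """Between-class variance of the <=t / >t split (to maximize)."""
    total = counts.sum()
    w0 = counts[: t + 1].sum()
    w1 = total - w0
    if w0 == 0 or w1 == 0:
        return -math.inf
    m0 = (counts[: t + 1] * LEVELS[: t + 1]).sum() / w0
    m1 = (counts[t + 1 :] * LEVELS[t + 1 :]).sum() / w1
    return (w0 / total) * (w1 / total) * (m0 - m1) ** 2


def huang_criterion(counts, t):
    """Fuzzy Shannon entropy of the split (to minimize)."""
    nz = np.flatnonzero(counts)
    c = int(nz[-1]) - int(nz[0])
    w0 = counts[: t + 1].sum()
    w1 = counts.sum() - w0
    m0 = (counts[: t + 1] * LEVELS[: t + 1]).sum() / max(w0, 1e-12)
    m1 = (counts[t + 1 :] * LEVELS[t + 1 :]).sum() / max(w1, 1e-12)
    e = 0.0
    for g in range(256):
        if counts[g] == 0:
            continue
        mu = m0 if g <= t else m1
        u = 1.0 / (1.0 + abs(g - mu) / c)
        if 0.0 < u < 1.0:
            e += counts[g] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
    return e


def min_error_criterion(counts, t):
    """Kittler-Illingworth classification-error criterion (to minimize)."""
    total = counts.sum()
    w0 = counts[: t + 1].sum()
    w1 = total - w0
    if w0 < 1e-12 or w1 < 1e-12:
        return math.inf
    p0, p1 = w0 / total, w1 / total
    m0 = (counts[: t + 1] * LEVELS[: t + 1]).sum() / w0
    m1 = (counts[t + 1 :] * LEVELS[t + 1 :]).sum() / w1
    v0 = max((counts[: t + 1] * (LEVELS[: t + 1] - m0) ** 2).sum() / w0, 1e-8)
    v1 = max((counts[t + 1 :] * (LEVELS[t + 1 :] - m1) ** 2).sum() / w1, 1e-8)
    return (1.0 + 2.0 * (p0 * math.log(math.sqrt(v0)) + p1 * math.log(math.sqrt(v1)))
            - 2.0 * (p0 * math.log(p0) + p1 * math.log(p1)))


def brute_optimum(criterion, counts, maximize=False):
    values = [criterion(counts, t) for t in range(255)]
    best = max(values) if maximize else min(values)
    return values.index(best), best


def assert_attains_optimum(fast_threshold, criterion, counts, maximize=False):
    _, best = brute_optimum(criterion, counts, maximize=maximize)
    attained = criterion(counts, fast_threshold)
    tol = 1e-9 * max(1.0, abs(best))
    if maximize:
        assert attained >= best - tol
    else:
        assert attained <= best + tol


def random_bimodal_counts(rng):
    a = rng.normal(rng.integers(40, 100), rng.uniform(5, 20), 4000)
    b = rng.normal(rng.integers(140, 220), rng.uniform(5, 25), 6000)
    vals = np.clip(np.round(np.concatenate([a, b])), 0, 255).astype(int)
    return np.bincount(vals, minlength=256).astype(float)


class TestGlobalThresholds:
    @pytest.mark.parametrize("fast,criterion,maximize", [
        (otsu_threshold, otsu_criterion, True),
        (huang_threshold, huang_criterion, False),
        (min_error_threshold, min_error_criterion, False),
    ])
    def test_matches_exhaustive_scan(self, fast, criterion, maximize):
        rng = np.random.default_rng(12)
        for _ in range(10):
            counts = random_bimodal_counts(rng)
            assert_attains_optimum(fast(counts), criterion, counts, maximize)

    def test_two_level_image_separates_classes(self):
        img = np.full((50, 50), 30, np.uint8)
        img[:, 30:] = 200
        t = threshold_value(img, "otsu")
        assert 30 <= t < 200
        mask = threshold_global(img, "otsu")
        assert mask[:, 30:].all() and not mask[:, :30].any()

    def test_constant_image_errors(self):
        with pytest.raises(DegenerateHistogramError):
            threshold_global(np.full((20, 20), 77, np.uint8), "otsu")


class TestLocalThreshold:
    def test_gradient_phantom_local_beats_global(self):
        """Local Otsu recovers a two-level phantom under a strong
        illumination gradient that defeats the global threshold."""
        h, w = 200, 300
        phantom = np.zeros((h, w), bool)
        for x0 in range(0, w, 24):
            phantom[:, x0 : x0 + 10] = True
        gray = np.where(phantom, 150, 70).astype(float)
        gray += np.linspace(-70, 70, w)[None, :]
        gray = np.clip(np.round(gray), 0, 255)
        global_agree = (threshold_global(gray, "otsu") == phantom).mean()
        local_agree = (threshold_local(gray, "otsu", window=49) == phantom).mean()
        assert local_agree >= 0.99
        assert global_agree < 0.95

    @pytest.mark.parametrize("method", ["otsu", "huang", "min_error"])
    def test_window_as_large_as_image_equals_global(self, method):
        rng = np.random.default_rng(1)
        img = np.clip(np.round(rng.normal(120, 40, (60, 80))), 0, 255)
        assert np.array_equal(
            threshold_local(img, method, window=80), threshold_global(img, method)
        )

    def test_uniform_window_pixels_go_background(self):
        img = np.full((40, 40), 128, np.uint8)
        img[35:, 35:] = 250  # one bright corner; most windows are constant
        mask = threshold_local(img, "otsu", window=9)
        assert not mask[:20, :20].any()

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            threshold_local(np.zeros((50, 50)), "otsu", window=200)

    def test_auto_window_mfd_plus_ten_percent(self):
        assert auto_local_window(20) == 23  # round(22) -> odd
        assert auto_local_window(9.5) == 11
        assert auto_local_window(1) == 3


class TestSmoothMask:
    def test_isolated_pixel_removed(self):
        m = np.zeros((30, 30), bool)
        m[15, 15] = True
        assert not smooth_mask(m).any()

    def test_despeckle_reaches_a_fixed_point(self):
        from fiberdiam.segmentation import despeckle

        rng = np.random.default_rng(3)
        for _ in range(5):
            m = rng.random((80, 80)) < 0.5
            once = despeckle(m)
            assert np.array_equal(despeckle(once), once)

    def test_wide_bar_survives_with_bounded_thinning(self):
        bar = np.zeros((60, 200), bool)
        bar[18:43, :] = True  # 25 px wide
        out = smooth_mask(bar)
        widths = out.sum(axis=0)[5:-5]
        assert widths.min() >= 23
        assert widths.max() <= 25

    def test_component_count_never_increases_on_phantoms(self, disordered9_small):
        rng = np.random.default_rng(8)
        noisy = disordered9_small | (rng.random(disordered9_small.shape) < 0.02)
        s8 = ndimage.generate_binary_structure(2, 2)
        _, before = ndimage.label(noisy, structure=s8)
        _, after = ndimage.label(smooth_mask(noisy), structure=s8)
        assert after <= before
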