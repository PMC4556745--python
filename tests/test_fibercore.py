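"""Skeletonization and diameter estimators against geometric oracles."""

import numpy as np
import pytest
from scipy import ndimage

from fiberdiam import (
    EmptyMaskError,
    build_calibration_spec,
    diameter_histogram,
    diameter_samples,
    fiber_summary,
    local_thickness,
    render,
    skeletonize,
    superpixel_mean,
)
from conftest import horizontal_bar


def brute_local_thickness(mask):
    """Exhaustive inscribed-circle oracle: for every candidate center the
    largest circle fitting in the foreground is painted onto the pixels it
    contains; each pixel keeps the largest covering diameter."""
    h, w = mask.shape
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros((h, w))
    for cy, cx in fg:
        if len(bg):
            r = np.sqrt(((bg - [cy, cx]) ** 2).sum(axis=1)).min()
        else:
            r = float(max(h, w))
        val = 2.0 * r - 1.0
        rc = max(r - 1.0, 0.0)
        ri = int(rc)
        for py in range(max(0, cy - ri), min(h, cy + ri + 1)):
            for px in range(max(0, cx - ri), min(w, cx + ri + 1)):
                if mask[py, px] and (py - cy) ** 2 + (px - cx) ** 2 <= rc * rc + 1e-9:
                    out[py, px] = max(out[py, px], val)
    return out


def random_blob_mask(rng, size):
    m = rng.random((size, size)) < 0.45
    return ndimage.binary_closing(m)


class TestSkeletonize:
    def test_bar_skeleton_is_single_midline(self):
        bar = horizontal_bar(25, (60, 400))
        skel = skeletonize(bar)
        ys, xs = np.nonzero(skel.pixels)
        assert skel.n_intersections == 0
        # away from the ends the centerline sits at mid-height
        mid = ys[(xs > 30) & (xs < 370)]
        assert np.all(np.abs(mid - 29.5) <= 1.0)

    def test_plus_sign_has_one_intersection_cluster(self):
        plus = np.zeros((101, 101), bool)
        plus[45:56, :] = True
        plus[:, 45:56] = True
        skel = skeletonize(plus)
        assert skel.n_intersections == 1
        assert skel.n_segments == 4

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyMaskError):
            skeletonize(np.zeros((20, 20), bool))

    def test_skeleton_subset_of_foreground_and_thin(self, disordered9_small):
        skel = skeletonize(disordered9_small)
        assert not (skel.pixels & ~disordered9_small).any()
        # no solid 2x2 block anywhere on the centerline
        s = skel.pixels
        blocks = s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]
        assert not blocks.any()


class TestDiameterHistogram:
    def test_bar_reads_its_width(self):
        bar = horizontal_bar(25, (60, 600))
        skel = skeletonize(bar)
        h = diameter_histogram(bar, skel)
        assert h.mode() == pytest.approx(25, abs=1)
        assert h.mean() == pytest.approx(25, abs=1)

    def test_disc_samples_bounded_by_diameter(self):
        yy, xx = np.mgrid[0:101, 0:101]
        r = 30
        disc = (yy - 50) ** 2 + (xx - 50) ** 2 < r * r
        skel = skeletonize(disc)
        d = diameter_samples(disc, skel, exclude_ends=False)
        assert d.max() <= 2 * r + 1
        assert d.max() >= 2 * r - 2

    def test_histogram_mean_agrees_with_local_thickness(self):
        spec = build_calibration_spec("Ordered-1D", seed=2, diameter=25,
                                      canvas=(480, 360))
        mask = render(spec) > 0
        skel = skeletonize(mask)
        hist_mean = diameter_histogram(mask, skel).mean()
        # same 2xEDT convention and the same retained centerline pixels
        # (crossing-inflated pixels are outside both estimators' remit)
        _, coords = diameter_samples(mask, skel, return_coords=True)
        lt = local_thickness(mask, edge_correction=False)
        lt_mean = lt[coords[:, 0], coords[:, 1]].mean()
        assert abs(hist_mean - lt_mean) / hist_mean <= 0.05

    def test_scale_converts_bin_centers(self):
        bar = horizontal_bar(9, (40, 300))
        skel = skeletonize(bar)
        h_px = diameter_histogram(bar, skel)
        h_um = diameter_histogram(bar, skel, scale=0.5)
        assert np.allclose(h_um.bin_centers, h_px.bin_centers * 0.5)
        assert np.array_equal(h_um.counts, h_px.counts)

    def test_dilation_monotonicity(self):
        spec = build_calibration_spec("Ordered-1D", seed=2, diameter=15,
                                      canvas=(400, 300))
        mask = render(spec) > 0
        grown = ndimage.binary_dilation(mask, ndimage.generate_binary_structure(2, 2))
        m0 = diameter_histogram(mask, skeletonize(mask)).mean()
        m1 = diameter_histogram(grown, skeletonize(grown)).mean()
        assert m1 >= m0 - 0.25
        # one dilation widens an oblique stroke by up to 2*sqrt(2) px
        assert m1 <= m0 + 2.0 * np.sqrt(2.0) + 0.25


class TestSuperpixelMean:
    def test_long_bar_within_five_percent(self):
        bar = horizontal_bar(9, (60, 800))
        est = superpixel_mean(bar, skeletonize(bar))
        assert 0.95 * 9 <= est <= 1.05 * 9

    def test_two_parallel_bars_match_single_bar(self):
        one = horizontal_bar(9, (80, 800))
        two = np.zeros((80, 800), bool)
        two[10:19, :] = True
        two[60:69, :] = True
        e1 = superpixel_mean(one, skeletonize(one))
        e2 = superpixel_mean(two, skeletonize(two))
        assert e2 == pytest.approx(e1, rel=0.02)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyMaskError):
            superpixel_mean(np.zeros((10, 10), bool), None)


class TestLocalThickness:
    def test_bar_interior_reads_bar_width(self):
        bar = horizontal_bar(25, (60, 200))
        lt = local_thickness(bar)
        interior = lt[18 + 2 : 43 - 2, 30:170]
        assert np.all(interior == 25)

    def test_disc_interior_reads_two_r(self):
        yy, xx = np.mgrid[0:81, 0:81]
        disc = (yy - 40) ** 2 + (xx - 40) ** 2 < 25 * 25
        lt = local_thickness(disc)
        inner = lt[(yy - 40) ** 2 + (xx - 40) ** 2 < 15 * 15]
        assert np.all(np.abs(inner - 50) <= 1.5)

    def test_matches_exhaustive_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(12):
            m = random_blob_mask(rng, 28)
            if not m.any():
                continue
            assert np.allclose(local_thickness(m), brute_local_thickness(m))

    def test_dilation_never_decreases_thickness(self):
        rng = np.random.default_rng(5)
        m = random_blob_mask(rng, 40)
        grown = ndimage.binary_dilation(m, ndimage.generate_binary_structure(2, 2))
        lt0 = local_thickness(m)
        lt1 = local_thickness(grown)
        assert np.all(lt1[m] >= lt0[m] - 1e-9)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyMaskError):
            local_thickness(np.zeros((10, 10), bool))


class TestFiberSummary:
    def test_scale_equivariance(self):
        bar = horizontal_bar(9, (60, 800))
        skel = skeletonize(bar)
        fs_px = fiber_summary(bar, skel)
        fs_um = fiber_summary(bar, skel, scale=0.31)
        assert fs_um.mean_diameter_histogram == pytest.approx(
            fs_px.mean_diameter_histogram * 0.31)
        assert fs_um.mean_diameter_superpixel == pytest.approx(
            fs_px.mean_diameter_superpixel * 0.31)
        assert fs_um.sd == pytest.approx(fs_px.sd * 0.31)
        assert fs_um.n_samples == fs_px.n_samples
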