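"""Grayscale micrograph segmentation and binary-mask refinement.

Three histogram-shape thresholding families are provided, each in a
global and a local-adaptive flavour:

* ``otsu`` — maximize between-class variance (Otsu 1979);
* ``huang`` — minimize fuzzy Shannon entropy (Huang & Wang 1995);
* ``min_error`` — minimize the Kittler & Illingworth (1986) minimum-error
  criterion, modelling both classes as Gaussians.

The convention throughout is that fibers are brighter than background
and a pixel is foreground iff its intensity is *strictly greater* than
the threshold (ties go to background).  Local mode evaluates the chosen
criterion on window-sized neighbourhoods centred on a half-window grid
(reflected at the borders) and classifies each pixel against the
bilinearly interpolated threshold surface; a window at least as large as
the image reproduces the global result exactly.  The window size is
conventionally set to the mean fiber diameter plus 10 %.

``smooth_mask`` applies the standard post-segmentation cleanup: 3x3
median despeckling iterated to a fixed point, then an
erosion-dilation-erosion round with a 3x3 square element to sharpen
fiber edges and drop isolated pixels.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

METHODS = ("otsu", "huang", "min_error")

_LEVELS = np.arange(256, dtype=float)


class DegenerateHistogramError(ValueError):
    """Raised when an image has a single intensity level."""


def _hist256(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return np.bincount(np.round(img).astype(np.int64).ravel(), minlength=256).astype(float)


def otsu_threshold(counts: np.ndarray) -> int:
    """Threshold maximizing between-class variance; classes are <=t / >t."""
    p = counts / counts.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * _LEVELS)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b[:-1]))


def huang_threshold(counts: np.ndarray) -> int:
    """Threshold minimizing Huang & Wang's fuzzy Shannon entropy."""
    nz = np.flatnonzero(counts)
    gmin, gmax = int(nz[0]), int(nz[-1])
    if gmax == gmin:
        return gmin
    c = float(gmax - gmin)
    w = counts * _LEVELS
    cw = np.cumsum(counts)
    cwg = np.cumsum(w)
    total, total_g = cw[-1], cwg[-1]
    ts = np.arange(gmin, gmax)  # split points with both classes non-empty
    mu0 = cwg[ts] / np.maximum(cw[ts], 1e-12)
    mu1 = (total_g - cwg[ts]) / np.maximum(total - cw[ts], 1e-12)
    g = _LEVELS[None, :]
    mu = np.where(g <= ts[:, None], mu0[:, None], mu1[:, None])
    u = 1.0 / (1.0 + np.abs(g - mu) / c)  # membership in [0.5, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
    s[~np.isfinite(s)] = 0.0
    entropy = (s * counts[None, :]).sum(axis=1)
    return int(ts[np.argmin(entropy)])


def min_error_threshold(counts: np.ndarray) -> int:
    """Kittler-Illingworth minimum-error Gaussian-mixture threshold."""
    p = counts / counts.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * _LEVELS)
    mu2 = np.cumsum(p * _LEVELS**2)
    p1 = omega
    p2 = 1.0 - omega
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = mu / p1
        m2 = (mu[-1] - mu) / p2
        v1 = mu2 / p1 - m1**2
        v2 = (mu2[-1] - mu2) / p2 - m2**2
        v1 = np.maximum(v1, 1e-8)
        v2 = np.maximum(v2, 1e-8)
        j = 1.0 + 2.0 * (p1 * np.log(np.sqrt(v1)) + p2 * np.log(np.sqrt(v2))) - 2.0 * (
            p1 * np.log(p1) + p2 * np.log(p2)
        )
    valid = (p1 > 1e-12) & (p2 > 1e-12)
    j[~valid] = np.inf
    j[~np.isfinite(j)] = np.inf
    return int(np.argmin(j[:-1]))


_THRESH = {
    "otsu": otsu_threshold,
    "huang": huang_threshold,
    "min_error": min_error_threshold,
}


def _threshold_from_counts(counts: np.ndarray, method: str, allow_degenerate: bool = False) -> float:
    if method not in _THRESH:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    nz = np.flatnonzero(counts)
    if len(nz) < 2:
        if allow_degenerate:
            return float(nz[0]) if len(nz) else 0.0
        raise DegenerateHistogramError("image has fewer than two distinct intensities")
    return float(_THRESH[method](counts))


def threshold_value(image: np.ndarray, method: str = "otsu") -> float:
    """Global threshold value for ``image`` (foreground is > value)."""
    return _threshold_from_counts(_hist256(image), method)


def threshold_global(image: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Global threshold; returns a boolean mask (True = fiber)."""
    return np.asarray(image) > threshold_value(image, method)


def auto_local_window(mean_fiber_diameter: float) -> int:
    """Local window size: mean fiber diameter plus 10 %, odd, >= 3 px."""
    w = int(round(1.10 * float(mean_fiber_diameter)))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def threshold_local(image: np.ndarray, method: str = "otsu", window: int = 15) -> np.ndarray:
    """Locally adaptive threshold with the same criterion families.

    Windows are centred on a grid spaced half a window apart; pixels are
    classified against the bilinearly interpolated per-window thresholds.
    Degenerate (constant) windows threshold at their single value, which
    the strict-> rule sends to background.
    """
    img = np.asarray(image, float)
    h, w = img.shape
    if window > max(h, w):
        raise ValueError("window larger than the image")
    if window < 3:
        window = 3
    if window % 2 == 0:
        window += 1  # rounded up to odd
    if window >= max(h, w):
        counts = _hist256(img)
        t = _threshold_from_counts(counts, method, allow_degenerate=True)
        return img > t
    half = window // 2
    padded = np.pad(np.round(img).astype(np.int64), half, mode="reflect")
    spacing = max(1, window // 2)

    def _nodes(extent):
        n = max(2, int(np.ceil(extent / spacing)) + 1)
        return np.linspace(0, extent - 1, n)

    ys, xs = _nodes(h), _nodes(w)
    tmap = np.empty((len(ys), len(xs)))
    for i, yc in enumerate(np.round(ys).astype(int)):
        for j, xc in enumerate(np.round(xs).astype(int)):
            win = padded[yc : yc + window, xc : xc + window]
            counts = np.bincount(win.ravel(), minlength=256).astype(float)
            tmap[i, j] = _threshold_from_counts(counts, method, allow_degenerate=True)
    interp = RegularGridInterpolator((ys, xs), tmap, method="linear",
                                     bounds_error=False, fill_value=None)
    gy, gx = np.mgrid[0:h, 0:w]
    surface = interp(np.column_stack([gy.ravel(), gx.ravel()])).reshape(h, w)
    # epsilon guards the ties-to-background rule against interpolation noise
    return img > surface + 1e-6


_SQUARE3 = np.ones((3, 3), bool)


def despeckle(mask: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """3x3 median filter iterated to a fixed point (capped at ``max_iter``)."""
    m = np.asarray(mask) > 0
    for _ in range(max_iter):
        nm = ndimage.median_filter(m.astype(np.uint8), size=3, mode="reflect").astype(bool)
        if np.array_equal(nm, m):
            return nm
        m = nm
    warnings.warn("despeckle did not reach a fixed point within the iteration cap")
    return m


def smooth_mask(mask: np.ndarray, max_despeckle_iter: int = 100) -> np.ndarray:
    """Despeckle to a fixed point, then erode-dilate-erode (3x3 square).

    The median stage removes salt-and-pepper noise and is iterated until
    the image stops changing (hard cap ``max_despeckle_iter``); the
    morphology round trims ragged fiber edges by at most two pixels per
    side and eliminates isolated pixel areas.  Erosion treats the region
    beyond the border as foreground so strokes crossing the image edge
    are not eaten from the outside.
    """
    m = despeckle(mask, max_iter=max_despeckle_iter)
    m = ndimage.binary_erosion(m, structure=_SQUARE3, border_value=1)
    m = ndimage.binary_dilation(m, structure=_SQUARE3, border_value=0)
    m = ndimage.binary_erosion(m, structure=_SQUARE3, border_value=1)
    return m


def segment(
    image: np.ndarray,
    method: str = "otsu",
    mode: str = "global",
    window: int | None = None,
    invert: bool = False,
    smooth: bool = True,
) -> np.ndarray:
    """Threshold + refine in one call; returns a boolean fiber mask."""
    img = np.asarray(image)
    if invert:
        img = 255 - img
    if mode == "global":
        mask = threshold_global(img, method)
    elif mode == "local":
        if window is None:
            raise ValueError("local mode needs a window size")
        mask = threshold_local(img, method, window)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return smooth_mask(mask) if smooth else mask
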