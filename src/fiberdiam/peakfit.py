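"""Gaussian multi-peak fitting of diameter histograms and error metrics.

A diameter histogram from an image with k distinct fiber diameters shows
k modes; each is fit with a Gaussian (plus an optional constant
baseline) by ordinary least squares, and the fitted centers are the
per-diameter estimates D_calc.  Accuracy against ground truth uses

    %error    = (1/N) * sum |D_real - D_calc| / D_real
    abs error = (1/N) * sum |D_real - D_calc|

with N the number of distinct line diameters, peaks and truths matched
by ascending center.  Peak width is reported as FWHM with
sigma = FWHM / (2 sqrt(2 ln 2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit.models import ConstantModel, GaussianModel
from scipy.signal import find_peaks

#: FWHM = FWHM_FACTOR * sigma for a Gaussian
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class FitError(RuntimeError):
    """Raised when the least-squares peak fit fails to converge."""


@dataclass(frozen=True)
class GaussianPeak:
    center: float
    amplitude: float  # peak height, in counts
    fwhm: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_FACTOR

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ErrorReport:
    percent_error: float  # fraction, not percent points
    abs_error: float
    n_diameters: int
    pooled_sd: float = float("nan")


def _as_xy(hist) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(hist, "bin_centers"):
        return np.asarray(hist.bin_centers, float), np.asarray(hist.counts, float)
    x, y = hist
    return np.asarray(x, float), np.asarray(y, float)


def _initial_centers(x: np.ndarray, y: np.ndarray, n_peaks: int) -> np.ndarray:
    """Seed centers from the strongest local maxima, well separated."""
    distance = max(1, len(x) // (3 * n_peaks))
    idx, props = find_peaks(y, height=0, distance=distance)
    if len(idx):
        order = np.argsort(props["peak_heights"])[::-1]
        idx = idx[order][:n_peaks]
    if len(idx) < n_peaks:
        extra = np.argsort(y)[::-1]
        for i in extra:
            if len(idx) >= n_peaks:
                break
            if all(abs(i - j) > distance for j in idx):
                idx = np.append(idx, i)
    return np.sort(x[np.asarray(idx[:n_peaks], int)])


def fit_gaussians(hist, n_peaks: int = 1, baseline: bool = True) -> list[GaussianPeak]:
    """Least-squares fit of a sum of Gaussians to a histogram.

    ``hist`` is anything with ``bin_centers``/``counts`` attributes or an
    ``(x, y)`` pair.  Peaks are initialized from the ``n_peaks`` highest
    local maxima and returned sorted by center.  The loss is plain least
    squares on counts; a constant baseline is included by default.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    x, y = _as_xy(hist)
    if np.count_nonzero(y) < 3 * n_peaks:
        raise ValueError("histogram has too few non-empty bins for this many peaks")
    bw = float(np.median(np.diff(x))) if len(x) > 1 else 1.0
    span = float(x.max() - x.min()) or 1.0
    centers0 = _initial_centers(x, y, n_peaks)
    model = ConstantModel(prefix="bg_") if baseline else None
    params = None
    for i, c0 in enumerate(centers0):
        g = GaussianModel(prefix=f"g{i}_")
        model = g if model is None else model + g
    params = model.make_params()
    if baseline:
        params["bg_c"].set(value=0.0, min=0.0, max=max(y.max(), 1.0))
    for i, c0 in enumerate(centers0):
        h0 = max(float(np.interp(c0, x, y)), 1e-3)
        s0 = max(bw, span / (10.0 * n_peaks))
        params[f"g{i}_center"].set(value=float(c0), min=float(x.min()) - bw,
                                   max=float(x.max()) + bw)
        params[f"g{i}_sigma"].set(value=s0, min=bw / 4.0, max=span)
        params[f"g{i}_amplitude"].set(value=h0 * s0 * math.sqrt(2 * math.pi), min=1e-9)
    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitError(f"peak fit did not converge: {result.message}")
    peaks = []
    for i in range(n_peaks):
        sigma = float(result.params[f"g{i}_sigma"].value)
        amp = float(result.params[f"g{i}_amplitude"].value)
        height = amp / (sigma * math.sqrt(2 * math.pi))
        peaks.append(GaussianPeak(
            center=float(result.params[f"g{i}_center"].value),
            amplitude=max(height, 1e-12),
            fwhm=max(FWHM_FACTOR * sigma, 1e-12),
        ))
    return sorted(peaks, key=lambda p: p.center)


def percent_error_single(d_real: float, d_calc: float) -> float:
    """|D_real - D_calc| / D_real for a single-diameter image."""
    if d_real <= 0:
        raise ValueError("d_real must be positive")
    return abs(d_real - d_calc) / d_real


def error_multi(d_real: Sequence[float], d_calc: Sequence[float]) -> ErrorReport:
    """Mean percent and absolute error over matched diameter sets.

    Both lists are matched in the given order; callers pairing fitted
    peaks to known diameters should sort both ascending first (which is
    how :func:`fit_gaussians` returns peaks).
    """
    real = np.asarray(d_real, float)
    calc = np.asarray(d_calc, float)
    if real.shape != calc.shape or real.ndim != 1 or len(real) < 1:
        raise ValueError("d_real and d_calc must be equal-length non-empty sequences")
    if np.any(real <= 0):
        raise ValueError("d_real values must be positive")
    diff = np.abs(real - calc)
    return ErrorReport(
        percent_error=float(np.mean(diff / real)),
        abs_error=float(np.mean(diff)),
        n_diameters=len(real),
    )


def pooled_sd(
    fwhms: Sequence[float],
    n_peaks: int,
    n_images: int,
    strategy: str = "rss_scaled",
) -> float:
    """Pool per-peak Gaussian widths into one diameter standard deviation.

    Each FWHM W converts to sigma = W / (2 sqrt(2 ln 2)); the default
    ``rss_scaled`` strategy takes the root-sum-of-squares of the sigmas
    scaled by ``n_peaks / n_images``.  The printed source formula is
    typographically ambiguous, so the reading is swappable: ``rss``
    (plain root-sum-of-squares) and ``mean`` (mean sigma) are also
    available.
    """
    w = np.asarray(fwhms, float)
    if w.size == 0:
        raise ValueError("need at least one FWHM")
    if np.any(w <= 0):
        raise ValueError("FWHM values must be positive")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    sigmas = w / FWHM_FACTOR
    rss = float(np.sqrt(np.sum(sigmas**2)))
    if strategy == "rss_scaled":
        return rss * n_peaks / n_images
    if strategy == "rss":
        return rss
    if strategy == "mean":
        return float(np.mean(sigmas))
    raise ValueError(f"unknown strategy {strategy!r}")
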