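"""Fiber diameter measurement from a binary mask.

The measurement chain is: thin the mask to a one-pixel centerline
(axial thinning), read the Euclidean distance transform (EDT) of the
mask at every retained centerline pixel, and convert radius to diameter.
Centerline pixels near fiber crossings are excluded because the EDT
there reflects the merged blob, not either fiber.

Diameter convention.  The local diameter is reported as ``2*EDT`` with
no pixel-width correction: the EDT measures to the nearest background
pixel *center*, which over-reads the continuous fiber boundary by
exactly half a pixel on axis-aligned strokes but by a vanishing amount
on oblique ones, so the uncorrected value is the less biased choice at
mixed stroke angles and the +-1 px rasterization jitter dominates
either way.  ``edge_correction=True`` subtracts the full pixel
(``2*EDT - 1``), which is exact for axis-aligned strokes.

Three estimators are provided:

* ``diameter_histogram`` — per-centerline-pixel diameters binned at a
  fixed width; its mean is the "histogram" estimate.
* ``superpixel_mean`` — one whole-image figure: foreground area divided
  by total centerline length, with the double-counted area at each
  crossing subtracted.
* ``local_thickness`` — for every foreground pixel, the diameter of the
  largest inscribed circle containing it (the classic local-thickness
  definition used as an independent comparison estimate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_thin

SQRT2 = math.sqrt(2.0)
_NBR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_EIGHT = ndimage.generate_binary_structure(2, 2)


class EmptyMaskError(ValueError):
    """Raised when a mask with no foreground is analyzed."""


@dataclass
class Skeleton:
    """One-pixel centerline of a fiber mask plus derived bookkeeping.

    ``radii`` is the EDT of the *source mask* (not of the skeleton);
    ``intersections`` marks skeleton pixels with three or more skeleton
    neighbours, clustered 8-connectedly into ``n_intersections`` crossing
    sites.  ``segment_labels`` labels the centerline runs between
    crossings/endpoints and ``segment_lengths`` holds their 8-connected
    path lengths (diagonal steps weighted by sqrt(2)).
    """

    pixels: np.ndarray
    radii: np.ndarray
    intersections: np.ndarray
    n_intersections: int
    segment_labels: np.ndarray
    segment_lengths: np.ndarray
    total_length: float

    @property
    def n_segments(self) -> int:
        return len(self.segment_lengths)

    @property
    def coords(self) -> np.ndarray:
        return np.argwhere(self.pixels)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NBR_KERNEL, mode="constant")


def _path_length(component: np.ndarray) -> float:
    """8-connected polyline length: axial links + sqrt(2) diagonal links.

    A diagonal link is only counted when the path does not already pass
    through one of the pair's common 4-neighbours (otherwise an L-corner
    would be billed twice).
    """
    c = component.astype(bool)
    axial = (c[:, :-1] & c[:, 1:]).sum() + (c[:-1, :] & c[1:, :]).sum()
    d1 = c[:-1, :-1] & c[1:, 1:] & ~(c[1:, :-1] | c[:-1, 1:])
    d2 = c[:-1, 1:] & c[1:, :-1] & ~(c[:-1, :-1] | c[1:, 1:])
    length = float(axial) + SQRT2 * float(d1.sum() + d2.sum())
    if length == 0.0 and c.any():
        length = 1.0  # isolated pixel
    return length


def _prune_spurs(skel: np.ndarray, edt: np.ndarray, factor: float = 1.5,
                 max_rounds: int = 5) -> np.ndarray:
    """Remove endpoint branches shorter than ``factor`` x the local radius.

    Thinning grows short spurs at stroke ends and crossings; a branch
    running from an endpoint into a junction is an artifact when it is
    shorter than the fiber radius there.
    """
    skel = skel.copy()
    cap = int(math.ceil(factor * max(1.0, edt.max()))) + 2
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    h, w = skel.shape
    for _ in range(max_rounds):
        ncount = _neighbor_count(skel) * skel
        endpoints = np.argwhere(ncount == 1)
        removed_any = False
        for ey, ex in endpoints:
            if not skel[ey, ex]:
                continue
            path = [(ey, ex)]
            prev = None
            cur = (ey, ex)
            junction = None
            while len(path) <= cap:
                nbrs = []
                for dy, dx in offsets:
                    y, x = cur[0] + dy, cur[1] + dx
                    if 0 <= y < h and 0 <= x < w and skel[y, x] and (y, x) != prev:
                        nbrs.append((y, x))
                nbrs = [n for n in nbrs if n not in path]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if ncount[nxt] >= 3:
                    junction = nxt
                    break
                prev, cur = cur, nxt
                path.append(cur)
            if junction is not None and len(path) < factor * edt[junction]:
                for y, x in path:
                    skel[y, x] = False
                removed_any = True
        if not removed_any:
            break
    return skel


def skeletonize(mask: np.ndarray, prune: bool = True) -> Skeleton:
    """Axial-thinning centerline with spur pruning and crossing detection."""
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyMaskError("mask has no foreground pixels")
    edt = ndimage.distance_transform_edt(m)
    skel = _sk_thin(m)
    if prune:
        skel = _prune_spurs(skel, edt)
    if not skel.any():  # pruning ate a tiny blob; keep the raw thinning
        skel = _sk_thin(m)
    ncount = _neighbor_count(skel) * skel
    inter = skel & (ncount >= 3)
    _, n_inter = ndimage.label(inter, structure=_EIGHT)
    seg_labels, n_seg = ndimage.label(skel & ~inter, structure=_EIGHT)
    lengths = np.empty(n_seg)
    slices = ndimage.find_objects(seg_labels)
    for i, sl in enumerate(slices):
        lengths[i] = _path_length(seg_labels[sl] == i + 1)
    total = _path_length(skel)
    return Skeleton(skel, edt, inter, int(n_inter), seg_labels, lengths, total)


# ---------------------------------------------------------------------------
# diameter estimators
# ---------------------------------------------------------------------------

def _refined_radii(mask: np.ndarray, coords: np.ndarray, supersample: int) -> np.ndarray:
    """Subpixel EDT radii at centerline pixels.

    The EDT is evaluated on an s-fold replicated grid, which measures
    distance to the background *region* rather than to background pixel
    centers and so removes the angle-dependent lattice quantization that
    dominates at small diameters.  Per coarse pixel the maximum over its
    s x s block is taken (the best-centred subpixel position) plus half
    a fine pixel to reach the region boundary.
    """
    s = supersample
    fine = np.repeat(np.repeat(mask, s, axis=0), s, axis=1)
    edtf = ndimage.distance_transform_edt(fine)
    h, w = mask.shape
    bmax = edtf.reshape(h, s, w, s).max(axis=(1, 3))
    return (bmax[coords[:, 0], coords[:, 1]] + 0.5) / s


def diameter_samples(
    mask: np.ndarray,
    skel: Skeleton,
    edge_correction: bool = False,
    exclude_intersections: bool = True,
    exclude_ends: bool = True,
    exclude_border: bool = True,
    supersample: int = 4,
    return_coords: bool = False,
) -> np.ndarray:
    """Local diameters at retained centerline pixels.

    Pixels within one local radius of a crossing are dropped (the
    exclusion radius is the EDT value at the crossing pixel itself), as
    are pixels near centerline endpoints, where stroke caps and
    image-border clipping taper the distance transform below the true
    radius, and pixels closer to the image border than their own radius
    (fibers partially clipped by the field of view read thin).
    ``supersample`` > 1 evaluates the EDT on a finer grid for subpixel
    boundary localization (set to 1 for the plain pixel EDT).
    """
    m = np.asarray(mask) > 0
    coords = skel.coords
    keep = np.ones(len(coords), bool)
    if exclude_border:
        h, w = m.shape
        border_dist = np.minimum(
            np.minimum(coords[:, 0], h - 1 - coords[:, 0]),
            np.minimum(coords[:, 1], w - 1 - coords[:, 1]),
        )
        keep &= border_dist >= skel.radii[coords[:, 0], coords[:, 1]] - 0.5
    tree = cKDTree(coords) if (exclude_intersections or exclude_ends) else None
    if exclude_intersections and skel.intersections.any():
        icoords = np.argwhere(skel.intersections)
        radii = skel.radii[icoords[:, 0], icoords[:, 1]]
        hit = tree.query_ball_point(icoords.astype(float), radii + 1e-9)
        for lst in hit:
            keep[lst] = False
    if exclude_ends:
        ncount = _neighbor_count(skel.pixels) * skel.pixels
        ends = np.argwhere(skel.pixels & (ncount <= 1))
        if len(ends):
            labels = skel.segment_labels[ends[:, 0], ends[:, 1]]
            n_seg = skel.n_segments
            if n_seg:
                segmax = ndimage.maximum(
                    skel.radii, labels=skel.segment_labels, index=np.arange(1, n_seg + 1)
                )
                segmax = np.atleast_1d(segmax)
            radii = np.where(
                labels > 0,
                1.5 * segmax[np.maximum(labels - 1, 0)] if n_seg else 0.0,
                1.5 * skel.radii[ends[:, 0], ends[:, 1]],
            )
            hit = tree.query_ball_point(ends.astype(float), np.asarray(radii) + 1e-9)
            for lst in hit:
                keep[lst] = False
    kept = coords[keep]
    if len(kept) == 0:  # crossing/end-dominated mask: fall back to all pixels
        kept = coords
    if supersample > 1:
        r = _refined_radii(m, kept, supersample)
    else:
        r = skel.radii[kept[:, 0], kept[:, 1]]
    d = 2.0 * r - (1.0 if edge_correction else 0.0)
    return (d, kept) if return_coords else d


@dataclass
class DiameterHistogram:
    """Frequency of local fiber diameters sampled along the centerline."""

    bin_centers: np.ndarray  # px, or um when scale is set
    counts: np.ndarray
    bin_width: float = 1.0
    scale: float | None = None  # um per px; centers already converted when set
    samples: np.ndarray | None = field(default=None, repr=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mode(self) -> float:
        """Center of the most populated bin (first on ties)."""
        return float(self.bin_centers[int(np.argmax(self.counts))])

    def mean(self) -> float:
        return float(np.average(self.bin_centers, weights=self.counts))

    def sd(self) -> float:
        mu = self.mean()
        return float(math.sqrt(np.average((self.bin_centers - mu) ** 2, weights=self.counts)))


def diameter_histogram(
    mask: np.ndarray,
    skel: Skeleton,
    bin_width: float = 1.0,
    scale: float | None = None,
    edge_correction: bool = False,
) -> DiameterHistogram:
    """Bin centerline diameters at ``bin_width`` (default 1 px).

    Bins are centred on integer multiples of the bin width; the optional
    ``scale`` (um/px) converts the bin centers only — counting is always
    done in pixel units.
    """
    d = diameter_samples(mask, skel, edge_correction=edge_correction)
    if len(d) == 0:
        raise EmptyMaskError("no centerline samples")
    nbins = int(math.floor(d.max() / bin_width + 0.5)) + 1
    edges = (np.arange(nbins + 1) - 0.5) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    centers = np.arange(nbins) * bin_width
    if scale is not None:
        if scale <= 0:
            raise ValueError("scale must be positive")
        centers = centers * scale
    return DiameterHistogram(centers, counts, bin_width, scale, samples=d)


def superpixel_mean(mask: np.ndarray, skel: Skeleton, edge_correction: bool = False) -> float:
    """Whole-image mean diameter: foreground area / centerline length.

    Where fibers cross, the overlap area is counted once but traversed
    by two centerlines; per crossing cluster, the square of the typical
    fiber diameter (2x the median centerline EDT, which is robust to the
    crossing-blob inflation) is subtracted from the area to compensate.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyMaskError("mask has no foreground pixels")
    if skel.total_length <= 0:
        raise EmptyMaskError("zero centerline length")
    area = raw_area = float(m.sum())
    if skel.intersections.any():
        clean = skel.pixels & ~skel.intersections
        if clean.any():
            r_med = float(np.median(skel.radii[clean]))
        else:
            r_med = float(np.median(skel.radii[skel.pixels]))
        d_est = 2.0 * r_med - (1.0 if edge_correction else 0.0)
        area -= skel.n_intersections * d_est**2
    # dense crossing fields: never write off more than half the area
    area = max(area, 0.5 * raw_area)
    return area / skel.total_length


def local_thickness(mask: np.ndarray, edge_correction: bool = True) -> np.ndarray:
    """Largest-inscribed-circle diameter at every foreground pixel.

    For each foreground pixel ``c`` the maximal inscribed circle centred
    there has radius ``EDT(c)`` (to the half-pixel boundary when
    ``edge_correction``); a pixel's thickness is the diameter of the
    largest such circle that contains it (containment: ``|p-c| <=
    EDT(c) - 1`` in pixel-center distance).  Centers whose circle is
    wholly contained in a neighbour's circle are pruned before painting,
    which is exact and leaves roughly the distance ridge.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise EmptyMaskError("mask has no foreground pixels")
    edt = ndimage.distance_transform_edt(m)
    h, w = m.shape
    redundant = np.zeros_like(m)
    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = np.where(m, edt, -np.inf)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            dist = math.hypot(dy, dx)
            shifted = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
            redundant |= shifted >= edt + dist - 1e-9
    centers = np.argwhere(m & ~redundant)
    order = np.argsort(edt[centers[:, 0], centers[:, 1]])[::-1]
    out = np.zeros((h, w))
    corr = 1.0 if edge_correction else 0.0
    for cy, cx in centers[order]:
        r = edt[cy, cx]
        rc = r - 1.0  # containment radius in pixel-center distance
        val = 2.0 * r - corr
        if rc < 0:
            rc = 0.0
        ri = int(math.floor(rc))
        y0, y1 = max(0, cy - ri), min(h - 1, cy + ri)
        x0, x1 = max(0, cx - ri), min(w - 1, cx + ri)
        box = out[y0 : y1 + 1, x0 : x1 + 1]
        yy, xx = np.ogrid[y0 - cy : y1 - cy + 1, x0 - cx : x1 - cx + 1]
        disc = yy * yy + xx * xx <= rc * rc + 1e-9
        np.maximum(box, np.where(disc, val, 0.0), out=box)
    out[~m] = 0.0
    # every fg pixel is at least covered by its own circle
    own = np.where(m, 2.0 * edt - corr, 0.0)
    return np.maximum(out, own)


@dataclass
class FiberSummary:
    mean_diameter_superpixel: float
    mean_diameter_histogram: float
    sd: float
    n_samples: int
    scale: float | None = None


def fiber_summary(mask: np.ndarray, skel: Skeleton, scale: float | None = None) -> FiberSummary:
    """Histogram and super-pixel mean diameters for one image."""
    hist = diameter_histogram(mask, skel)
    sp = superpixel_mean(mask, skel)
    factor = scale if scale is not None else 1.0
    return FiberSummary(
        mean_diameter_superpixel=sp * factor,
        mean_diameter_histogram=hist.mean() * factor,
        sd=hist.sd() * factor,
        n_samples=hist.total,
        scale=scale,
    )
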