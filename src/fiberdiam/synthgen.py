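"""Synthetic calibration images with exactly known line diameters.

The validation strategy for fiber-diameter software is to draw white
strokes of a stated pixel width on a black canvas and check that the
measurement pipeline recovers that width.  This module generates five
image families that emulate hand-drawn calibration sets:

* ``Ordered-1D`` / ``Disordered-1D`` — straight or gently curved lines,
  one diameter per image;
* ``Ordered-3D`` / ``Disordered-3D`` — three distinct diameters per
  image, drawn with randomly chosen frequencies;
* ``Multi-Dia`` — disordered lines with 2, 3, 4 or 6 distinct diameters.

Stroke geometry.  A stroke of nominal diameter ``d`` is a continuous
capsule of half-width ``d / 2`` around the center path, sampled at pixel
centers (strictly inside — no anti-aliasing).  Axis-aligned strokes are
exactly ``d`` pixels wide: odd diameters are centered on a whole pixel
row/column and even diameters on a half-pixel line.  Twice the Euclidean
distance transform at the centerline then reads the nominal diameter to
within a pixel at any stroke angle.

Every generated image carries a manifest (diameters, line frequencies,
number-average mean diameter, seed) so estimators can be scored against
ground truth without reference to the renderer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

DEFAULT_CANVAS = (1280, 960)  # (width, height), px

ORDERED_FAMILIES = {"Ordered-1D", "Ordered-3D"}
DISORDERED_FAMILIES = {"Disordered-1D", "Disordered-3D", "Multi-Dia"}
FAMILIES = ORDERED_FAMILIES | DISORDERED_FAMILIES

#: number of distinct diameters each family allows
FAMILY_NDIA = {
    "Ordered-1D": (1,),
    "Disordered-1D": (1,),
    "Ordered-3D": (3,),
    "Disordered-3D": (3,),
    "Multi-Dia": (1, 2, 3, 4, 6),
}


class EmptyImageError(ValueError):
    """Raised when an operation needs foreground pixels and finds none."""


@dataclass(frozen=True)
class LineSpec:
    """One stroke: a diameter plus a center path.

    ``control_points`` are ``(x, y)`` pixel coordinates; straight lines
    store their two endpoints, curved lines store dense waypoints that
    are cubic-spline resampled at render time.
    """

    diameter: int
    orientation_class: str  # "ordered-straight" | "disordered-curved"
    angle: float | None = None  # degrees in [-90, 90), ordered lines only
    control_points: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.diameter < 1:
            raise ValueError("line diameter must be >= 1 px")
        if self.orientation_class not in ("ordered-straight", "disordered-curved"):
            raise ValueError(f"unknown orientation class {self.orientation_class!r}")


@dataclass(frozen=True)
class DiameterPlan:
    """Diameters and how many lines of each to draw."""

    entries: tuple[tuple[int, int], ...]  # (diameter px, frequency)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("plan needs at least one diameter")
        for d, f in self.entries:
            if d < 1:
                raise ValueError("diameters must be >= 1 px")
            if f < 1:
                raise ValueError("frequencies must be >= 1")

    @property
    def diameters(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.entries)

    @property
    def frequencies(self) -> tuple[int, ...]:
        return tuple(f for _, f in self.entries)

    @property
    def target_mean(self) -> float:
        """Number-average diameter, weighted by line frequency."""
        num = sum(d * f for d, f in self.entries)
        den = sum(f for _, f in self.entries)
        return num / den


@dataclass(frozen=True)
class CalibrationImageSpec:
    width: int
    height: int
    lines: tuple[LineSpec, ...]
    family: str
    seed: int

    @property
    def mean_diameter(self) -> float:
        if not self.lines:
            return float("nan")
        return float(np.mean([ln.diameter for ln in self.lines]))

    @property
    def distinct_diameters(self) -> tuple[int, ...]:
        return tuple(sorted({ln.diameter for ln in self.lines}))


def make_diameter_plan(
    n_diameters: int,
    seed: int,
    freq_max: int = 25,
    diameter_range: tuple[int, int] = (5, 60),
    min_gap: int = 8,
) -> DiameterPlan:
    """Randomly pick ``n_diameters`` distinct diameters and line counts.

    Frequencies are drawn uniformly on ``[0, freq_max]`` with zeros
    promoted to 1, mirroring the spreadsheet-style random plan the
    calibration sets were built from.  Diameters are drawn without
    replacement from ``diameter_range`` keeping at least ``min_gap`` px
    between neighbours so that multi-peak histograms stay resolvable.
    Deterministic for a fixed seed.
    """
    if n_diameters < 1:
        raise ValueError("n_diameters must be >= 1")
    if freq_max < 1:
        raise ValueError("freq_max must be >= 1")
    lo, hi = diameter_range
    if hi - lo < (n_diameters - 1) * min_gap:
        raise ValueError("diameter_range too narrow for n_diameters at min_gap")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        diams = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_diameters, replace=False))
        if n_diameters == 1 or np.min(np.diff(diams)) >= min_gap:
            break
    else:  # pragma: no cover - bounded by the range check above
        raise RuntimeError("could not draw a spaced diameter set")
    freqs = rng.integers(0, freq_max + 1, size=n_diameters)
    freqs[freqs == 0] = 1  # zero frequencies promoted to 1
    return DiameterPlan(tuple((int(d), int(f)) for d, f in zip(diams, freqs)))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _axis_snap(center: np.ndarray, angle: float, diameter: int) -> np.ndarray:
    """Snap the perpendicular coordinate of an axis-aligned stroke.

    Odd diameters center on a whole pixel row/column, even diameters on
    a half-pixel line; either way the rasterized width is exactly the
    nominal diameter.
    """
    c = center.astype(float).copy()
    half = 0.5 if diameter % 2 == 0 else 0.0
    a = ((angle + 90.0) % 180.0) - 90.0
    if abs(a) < 1e-9:  # horizontal: snap y
        c[1] = math.floor(c[1]) + half
    elif abs(abs(a) - 90.0) < 1e-9:  # vertical: snap x
        c[0] = math.floor(c[0]) + half
    return c


def _stamp_segment(mask: np.ndarray, p0, p1, diameter: int) -> None:
    """OR a straight capsule stroke into ``mask`` (exact distances)."""
    h, w = mask.shape
    r = diameter / 2.0
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    x0 = max(0, int(math.floor(min(p0[0], p1[0]) - r - 1)))
    x1 = min(w - 1, int(math.ceil(max(p0[0], p1[0]) + r + 1)))
    y0 = max(0, int(math.floor(min(p0[1], p1[1]) - r - 1)))
    y1 = min(h - 1, int(math.ceil(max(p0[1], p1[1]) + r + 1)))
    if x1 < x0 or y1 < y0:
        raise ValueError("line lies entirely outside the canvas")
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    v = p1 - p0
    vv = float(v @ v)
    px = xs - p0[0]
    py = ys - p0[1]
    if vv < 1e-12:
        d2 = px * px + py * py
    else:
        t = np.clip((px * v[0] + py * v[1]) / vv, 0.0, 1.0)
        dx = px - t * v[0]
        dy = py - t * v[1]
        d2 = dx * dx + dy * dy
    hit = d2 < r * r - 1e-9
    if not hit.any():
        raise ValueError("line lies entirely outside the canvas")
    mask[y0 : y1 + 1, x0 : x1 + 1] |= hit


def _resample_path(points: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Cubic-spline resample a waypoint polyline at ``step`` px spacing."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate(([True], seg > 1e-9))
    pts = pts[keep]
    if len(pts) < 2:
        return pts
    s = np.concatenate(([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))))
    if len(pts) < 4:
        # too few waypoints for a cubic spline; linear resample
        t = np.arange(0.0, s[-1] + step, step)
        return np.column_stack(
            [np.interp(t, s, pts[:, 0]), np.interp(t, s, pts[:, 1])]
        )
    cs = CubicSpline(s, pts, axis=0)
    t = np.arange(0.0, s[-1] + step, step)
    return cs(t)


def _stamp_path(mask: np.ndarray, points: np.ndarray, diameter: int) -> None:
    """OR a curved capsule stroke into ``mask`` via a dense-sample KD-tree."""
    h, w = mask.shape
    r = diameter / 2.0
    samples = _resample_path(points, step=0.25)
    if len(samples) == 0:
        raise ValueError("empty path")
    # candidate pixels: within r+1.5 of the rasterized path (cheap EDT prefilter)
    path_px = np.unique(
        np.round(samples[:, ::-1]).astype(int), axis=0
    )  # (y, x)
    inside = (
        (path_px[:, 0] >= 0)
        & (path_px[:, 0] < h)
        & (path_px[:, 1] >= 0)
        & (path_px[:, 1] < w)
    )
    path_px = path_px[inside]
    if len(path_px) == 0:
        raise ValueError("line lies entirely outside the canvas")
    raster = np.zeros((h, w), bool)
    raster[path_px[:, 0], path_px[:, 1]] = True
    dist = ndimage.distance_transform_edt(~raster)
    cand = np.argwhere(dist <= r + 1.5)
    tree = cKDTree(samples)
    d, _ = tree.query(cand[:, ::-1].astype(float), workers=-1)
    # sampled distance >= true distance, so "< r" never over-includes
    hit = cand[d < r - 1e-9]
    mask[hit[:, 0], hit[:, 1]] = True


def _bounded_walk(
    rng: np.random.Generator,
    length: float,
    diameter: int,
    width: int,
    height: int,
    step: float = 2.0,
) -> np.ndarray:
    """Random heading walk with minimum bend radius 2x the line diameter."""
    kappa = step / (2.0 * max(diameter, 2))  # max |heading change| per step, rad
    margin = 0.08 * min(width, height)
    x = rng.uniform(0.15 * width, 0.85 * width)
    y = rng.uniform(0.15 * height, 0.85 * height)
    heading = rng.uniform(-math.pi, math.pi)
    n = max(3, int(math.ceil(length / step)))
    pts = np.empty((n + 1, 2))
    pts[0] = (x, y)
    for i in range(1, n + 1):
        if x < margin or x > width - margin or y < margin or y > height - margin:
            # steer back toward the canvas center, bend radius permitting
            want = math.atan2(height / 2 - y, width / 2 - x)
            delta = (want - heading + math.pi) % (2 * math.pi) - math.pi
            heading += float(np.clip(delta, -kappa, kappa))
        else:
            heading += rng.uniform(-kappa, kappa)
        x += step * math.cos(heading)
        y += step * math.sin(heading)
        pts[i] = (x, y)
    return pts


# ---------------------------------------------------------------------------
# spec construction
# ---------------------------------------------------------------------------

def _ordered_conflict(center, direction, a, d, length, placed, width, height) -> bool:
    """True when a straight-line placement merges with an earlier stroke.

    Two strokes crossing at angle alpha share an overlap patch of area
    ~ d1*d2/sin(alpha); the placement is rejected when that patch would
    exceed 8 % of the candidate's own area, or when the strokes are
    near-parallel and closer than their summed radii.
    """
    for c2, dir2, a2, d2, len2 in placed:
        alpha = abs(a - a2) % 180.0
        alpha = min(alpha, 180.0 - alpha)
        sin_a = math.sin(math.radians(alpha))
        normal2 = np.array([-dir2[1], dir2[0]])
        if sin_a < 0.05:  # near-parallel: demand clear lateral separation
            gap = abs(float((center - c2) @ normal2))
            if gap < (d + d2) / 2.0 + 2.0:
                return True
            continue
        # intersection point of the two infinite lines
        rel = c2 - center
        denom = direction[0] * (-dir2[1]) - direction[1] * (-dir2[0])
        if abs(denom) < 1e-12:
            continue
        t = (rel[0] * (-dir2[1]) - rel[1] * (-dir2[0])) / denom
        u = (direction[0] * rel[1] - direction[1] * rel[0]) / (-denom)
        if abs(t) > length / 2.0 or abs(u) > len2 / 2.0:
            continue  # segments do not actually cross
        p = center + t * direction
        if not (-50 <= p[0] <= width + 50 and -50 <= p[1] <= height + 50):
            continue
        overlap = d * d2 / sin_a
        if overlap > 0.08 * d * length:
            return True
    return False

def _line_budget(plan: DiameterPlan, width: int, height: int, coverage: float):
    """Per-diameter stroke length so the canvas is ~``coverage`` foreground.

    The area budget is split evenly across diameter classes and then
    across that class's lines; lengths are floored at max(120 px, 2.5 d)
    so every line remains individually measurable.
    """
    area = coverage * width * height
    n_classes = len(plan.entries)
    out = []
    for d, f in plan.entries:
        per_line = area / n_classes / (f * d)
        out.append((d, f, float(np.clip(per_line, max(120.0, 2.5 * d), 2.2 * math.hypot(width, height)))))
    return out


def build_calibration_spec(
    family: str,
    seed: int,
    *,
    diameter: int | None = None,
    n_diameters: int | None = None,
    plan: DiameterPlan | None = None,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    coverage: float = 0.30,
    angle: float | None = None,
) -> CalibrationImageSpec:
    """Lay out the lines of one calibration image (deterministic per seed).

    ``coverage`` targets the approximate foreground fraction; the source
    image sets do not state a line density, so ~20-40 % coverage is used
    to match typical fibrous-scaffold micrographs.  ``angle`` pins every
    ordered line to one orientation (for orientation-analysis phantoms);
    by default angles are drawn uniformly on [-90, 90).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    width, height = canvas
    rng = np.random.default_rng(seed)
    ordered = family in ORDERED_FAMILIES

    if plan is None:
        allowed = FAMILY_NDIA[family]
        if allowed == (1,):
            if diameter is None:
                raise ValueError(f"{family} needs an explicit diameter")
            # single-diameter: line count set by the coverage budget
            chord = 0.80 * math.hypot(width, height)
            n_lines = int(np.clip(round(coverage * width * height / (diameter * chord)), 1, 40))
            plan = DiameterPlan(((int(diameter), n_lines),))
        else:
            n = n_diameters if n_diameters is not None else allowed[-1] if family == "Multi-Dia" else 3
            if n not in allowed:
                raise ValueError(f"{family} allows n_diameters in {allowed}, got {n}")
            plan = make_diameter_plan(n, int(rng.integers(0, 2**31 - 1)))
    if len(plan.entries) not in FAMILY_NDIA[family]:
        raise ValueError(f"{family} allows {FAMILY_NDIA[family]} diameters, got {len(plan.entries)}")

    single = len(plan.entries) == 1
    lines: list[LineSpec] = []
    if ordered:
        diag = math.hypot(width, height)
        placed: list[tuple[np.ndarray, np.ndarray, float, int, float]] = []
        for d, f, length in _line_budget(plan, width, height, coverage):
            for _ in range(f):
                half = (diag if single else length / 2.0)
                # redraw placements that would overlap an earlier stroke at a
                # shallow angle (merged strokes are unmeasurable and have no
                # hand-drawn counterpart)
                for _try in range(80):
                    a = float(angle) if angle is not None else float(rng.uniform(-90.0, 90.0))
                    center = np.array([rng.uniform(0.1 * width, 0.9 * width),
                                       rng.uniform(0.1 * height, 0.9 * height)])
                    center = _axis_snap(center, a, d)
                    direction = np.array([math.cos(math.radians(a)),
                                          -math.sin(math.radians(a))])
                    if angle is not None or not _ordered_conflict(
                        center, direction, a, d, 2 * half, placed, width, height
                    ):
                        break
                placed.append((center, direction, a, d, 2 * half))
                p0 = tuple(center - half * direction)
                p1 = tuple(center + half * direction)
                lines.append(LineSpec(int(d), "ordered-straight", angle=a,
                                      control_points=(p0, p1)))
    else:
        for d, f, length in _line_budget(plan, width, height, coverage):
            for _ in range(f):
                pts = _bounded_walk(rng, length, d, width, height)
                lines.append(LineSpec(int(d), "disordered-curved",
                                      control_points=tuple(map(tuple, pts))))
    return CalibrationImageSpec(width, height, tuple(lines), family, seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(spec: CalibrationImageSpec) -> np.ndarray:
    """Render a spec to an 8-bit binary image (foreground = 255)."""
    mask = np.zeros((spec.height, spec.width), bool)
    for ln in spec.lines:
        if ln.orientation_class == "ordered-straight":
            _stamp_segment(mask, ln.control_points[0], ln.control_points[1], ln.diameter)
        else:
            _stamp_path(mask, np.asarray(ln.control_points, float), ln.diameter)
    return mask.astype(np.uint8) * 255


def render_ordered(spec: CalibrationImageSpec) -> np.ndarray:
    if any(ln.orientation_class != "ordered-straight" for ln in spec.lines):
        raise ValueError("render_ordered expects only ordered-straight lines")
    return render(spec)


def render_disordered(spec: CalibrationImageSpec, seed: int | None = None) -> np.ndarray:
    """Render a disordered spec; ``seed`` regenerates missing control points."""
    if any(ln.orientation_class != "disordered-curved" for ln in spec.lines):
        raise ValueError("render_disordered expects only disordered-curved lines")
    if any(len(ln.control_points) < 2 for ln in spec.lines):
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        lines = tuple(
            LineSpec(ln.diameter, ln.orientation_class,
                     control_points=tuple(map(tuple, _bounded_walk(
                         rng, 600.0, ln.diameter, spec.width, spec.height))))
            if len(ln.control_points) < 2 else ln
            for ln in spec.lines
        )
        spec = CalibrationImageSpec(spec.width, spec.height, lines, spec.family, spec.seed)
    return render(spec)


def manifest_for(spec: CalibrationImageSpec, plan: DiameterPlan | None = None) -> dict:
    """Ground-truth record for a rendered image."""
    diams = [ln.diameter for ln in spec.lines]
    uniq = sorted(set(diams))
    freqs = [diams.count(d) for d in uniq]
    return {
        "family": spec.family,
        "width": spec.width,
        "height": spec.height,
        "seed": spec.seed,
        "diameters": uniq,
        "frequencies": freqs,
        "mean_diameter": float(np.average(uniq, weights=freqs)),
        "n_lines": len(diams),
    }


def generate_calibration_image(
    family: str, seed: int, **kwargs
) -> tuple[np.ndarray, dict]:
    """Build, render and describe one calibration image."""
    spec = build_calibration_spec(family, seed, **kwargs)
    return render(spec), manifest_for(spec)


# ---------------------------------------------------------------------------
# automated stand-in for the manual 25-site width check
# ---------------------------------------------------------------------------

def verify_manual_width(image: np.ndarray, n_sites: int = 25, seed: int = 0) -> list[int]:
    """Measure perpendicular foreground run lengths at random centerline sites.

    Emulates confirming the drawn line widths by counting pixels on
    screen: pick ``n_sites`` random centerline locations, estimate the
    local tangent from nearby centerline pixels, and count contiguous
    foreground along the perpendicular at quarter-pixel steps.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    mask = np.asarray(image) > 0
    if not mask.any():
        raise EmptyImageError("image has no foreground")
    skel = _sk_skeletonize(mask)
    coords = np.argwhere(skel)  # (y, x)
    if len(coords) == 0:
        raise EmptyImageError("skeleton is empty")
    rng = np.random.default_rng(seed)
    sites = coords[rng.integers(0, len(coords), size=n_sites)]
    tree = cKDTree(coords)
    edt = ndimage.distance_transform_edt(mask)
    h, w = mask.shape
    widths = []
    for y, x in sites:
        nbr_idx = tree.query_ball_point([y, x], r=5.0)
        nbrs = coords[nbr_idx].astype(float)
        nbrs -= nbrs.mean(axis=0)
        cov = nbrs.T @ nbrs
        evals, evecs = np.linalg.eigh(cov)
        tangent = evecs[:, np.argmax(evals)]  # (dy, dx)
        normal = np.array([-tangent[1], tangent[0]])
        rmax = edt[y, x] + 3.0
        ts = np.arange(-rmax, rmax + 0.25, 0.25)
        yy = np.floor(y + ts * normal[0] + 0.5).astype(int)
        xx = np.floor(x + ts * normal[1] + 0.5).astype(int)
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        fg = np.zeros(len(ts), bool)
        fg[ok] = mask[yy[ok], xx[ok]]
        # contiguous run containing t = 0
        i0 = int(np.argmin(np.abs(ts)))
        if not fg[i0]:
            widths.append(0)
            continue
        lo = i0
        while lo > 0 and fg[lo - 1]:
            lo -= 1
        hi = i0
        while hi < len(ts) - 1 and fg[hi + 1]:
            hi += 1
        widths.append(int(math.floor((hi - lo + 1) * 0.25 + 0.5)))
    return widths


# ---------------------------------------------------------------------------
# image sets on disk
# ---------------------------------------------------------------------------

def image_name(family: str, index: int, *, diameter=None, mean=None, n_diameters=None) -> str:
    """Image naming mirroring the published calibration sets."""
    prefix = "Dis_" if family in DISORDERED_FAMILIES else ""
    if family in ("Ordered-1D", "Disordered-1D"):
        return f"{prefix}{int(diameter):03d}-{index}"
    if family in ("Ordered-3D", "Disordered-3D"):
        return f"{prefix}Ave {mean:g}-{index}"
    return f"M{int(n_diameters):02d}D_{index}"


def generate_image_set(
    family: str,
    seed: int,
    n_images: int = 3,
    outdir: str | Path | None = None,
    **kwargs,
) -> list[tuple[str, np.ndarray, dict]]:
    """Generate a set of sibling calibration images.

    Three-diameter families share one diameter plan across the set (same
    number-average diameter, different line arrangements); Multi-Dia sets
    redraw the plan per image so each image has its own average.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=2 * n_images)
    shared_plan = None
    if family in ("Ordered-3D", "Disordered-3D") and "plan" not in kwargs:
        shared_plan = make_diameter_plan(3, int(sub[0]))
    out = []
    for i in range(n_images):
        kw = dict(kwargs)
        if shared_plan is not None:
            kw["plan"] = shared_plan
        spec = build_calibration_spec(family, int(sub[n_images + i]), **kw)
        img = render(spec)
        man = manifest_for(spec)
        name = image_name(
            family,
            i + 1,
            diameter=(man["diameters"][0] if len(man["diameters"]) == 1 else None),
            mean=man["mean_diameter"],
            n_diameters=len(man["diameters"]),
        )
        man["name"] = name
        out.append((name, img, man))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for name, img, man in out:
            tifffile.imwrite(outdir / f"{name}.tif", img)
            (outdir / f"{name}.json").write_text(json.dumps(man, indent=2))
            rows.append(
                {
                    "image": name,
                    "family": family,
                    "diameters": ";".join(map(str, man["diameters"])),
                    "frequencies": ";".join(map(str, man["frequencies"])),
                    "mean_diameter": man["mean_diameter"],
                    "seed": man["seed"],
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "image_index.csv", index=False)
    return out
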