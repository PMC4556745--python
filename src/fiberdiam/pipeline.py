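"""Batch analysis pipeline: segment -> smooth -> skeletonize -> measure.

Each analyzed image yields a fixed ten-file bundle under the output
directory: the segmented mask, a skeleton overlay, an excluded-pixel
check image, histograms (diameter, pore, orientation), per-segment
lengths, a fitted-peak table, a one-row summary CSV and a JSON manifest
echoing the configuration.  All computation is in pixel units; the
optional micrometre scale is applied as extra columns / converted values
at write time only.  Runs are deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .fibercore import diameter_histogram, fiber_summary, skeletonize
from .orientation import centerline_orientation, noi
from .peakfit import FitError, fit_gaussians
from .poremetrics import pore_stats
from .segmentation import auto_local_window, segment, smooth_mask

log = logging.getLogger("fiberdiam")


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    outdir: str = "fiberdiam_out"
    method: str = "otsu"
    mode: str = "global"  # "global" | "local"
    window: int | None = None  # px; None + local mode -> two-pass auto window
    invert: bool = False
    scale: float | None = None  # um per px
    bin_width: float = 1.0
    n_peaks: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class OutputBundle:
    name: str
    files: dict[str, str]
    summary: dict
    error: str | None = None


def _segment_stage(img: np.ndarray, config: RunConfig) -> tuple[np.ndarray, dict]:
    info: dict = {"segmentation": f"{config.mode}/{config.method}"}
    if fio.is_binary(img):
        # already-segmented input: skip thresholding *and* refinement, which
        # would erode clean strokes
        log.info("input already binary; segmentation stage bypassed")
        info["segmentation"] = "bypassed (binary input)"
        mask = img > 0
        if config.invert:
            mask = ~mask
        return mask, info
    window = config.window
    if config.mode == "local" and window is None:
        # two-pass bootstrap: global segment -> measure MFD -> local window
        coarse = segment(img, config.method, "global", invert=config.invert)
        if coarse.any():
            mfd = fiber_summary(coarse, skeletonize(coarse)).mean_diameter_histogram
            window = auto_local_window(mfd)
            info["auto_window"] = window
            log.info("auto local window from bootstrap MFD %.2f px -> %d px", mfd, window)
        else:
            window = 15
    mask = segment(img, config.method, config.mode, window=window, invert=config.invert)
    return mask, info


def analyze_image(img: np.ndarray, name: str, outdir: Path, config: RunConfig) -> OutputBundle:
    """Run the full measurement chain on one image and write its bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def put(key: str, fname: str) -> Path:
        p = outdir / fname
        files[key] = str(p)
        return p

    mask, seginfo = _segment_stage(img, config)
    fio.write_image(put("segmented", f"{name}_BW.tif"), mask)
    summary: dict = {"image": name, **seginfo}
    if not mask.any():
        log.warning("%s: empty segmentation; downstream stages skipped", name)
        summary["empty_segmentation"] = True
        fio.write_csv(put("summary", f"{name}_summary.csv"), pd.DataFrame([summary]))
        put("manifest", f"{name}_manifest.json").write_text(
            json.dumps({"config": asdict(config), "files": files}, indent=2)
        )
        return OutputBundle(name, files, summary, error="empty segmentation")

    skel = skeletonize(mask)
    hist = diameter_histogram(mask, skel, bin_width=config.bin_width)
    fs = fiber_summary(mask, skel, scale=config.scale)
    ps = pore_stats(mask, skel, scale=config.scale)
    ohist = centerline_orientation(skel)
    nres = noi(ohist)

    # 1 segmented mask written above; 2 skeleton overlay; 3 check image
    overlay = mask.astype(np.uint8) * 128
    overlay[skel.pixels] = 255
    fio.write_image(put("skeleton", f"{name}_skeleton.tif"), overlay)
    check = mask.astype(np.uint8) * 128
    check[skel.intersections] = 255
    fio.write_image(put("check", f"{name}_check.tif"), check)

    # 4 diameter histogram (radius + diameter, px, with um conversion column)
    ddf = pd.DataFrame(
        {"diameter_px": hist.bin_centers, "radius_px": hist.bin_centers / 2.0,
         "count": hist.counts}
    )
    if config.scale is not None:
        ddf["diameter_um"] = ddf["diameter_px"] * config.scale
    fio.write_csv(put("diameter_histogram", f"{name}_diam_hist.csv"), ddf)

    # 5 pore areas
    from scipy import ndimage as _ndi

    labels, npores = _ndi.label(~mask, structure=_ndi.generate_binary_structure(2, 1))
    areas = _ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, npores + 1))
    pdf = pd.DataFrame({"pore_area_px2": np.sort(areas)[::-1]})
    if config.scale is not None:
        pdf["pore_area_um2"] = pdf["pore_area_px2"] * config.scale**2
    fio.write_csv(put("pore_histogram", f"{name}_pore_hist.csv"), pdf)

    # 6 orientation histogram
    odf = pd.DataFrame({"angle_deg": ohist.bin_centers, "count": ohist.counts})
    fio.write_csv(put("orientation_histogram", f"{name}_orient_hist.csv"), odf)

    # 7 per-segment lengths
    sdf = pd.DataFrame({"segment_length_px": np.sort(skel.segment_lengths)[::-1]})
    fio.write_csv(put("segments", f"{name}_segments.csv"), sdf)

    # 8 Gaussian peak table
    try:
        peaks = fit_gaussians(hist, n_peaks=config.n_peaks)
        pkdf = pd.DataFrame(
            [{"center_px": p.center, "height": p.amplitude, "area": p.area,
              "fwhm_px": p.fwhm, "sigma_px": p.sigma} for p in peaks]
        )
    except (FitError, ValueError) as exc:
        log.warning("%s: peak fit failed: %s", name, exc)
        pkdf = pd.DataFrame(
            columns=["center_px", "height", "area", "fwhm_px", "sigma_px"])
        summary["peak_fit_error"] = str(exc)
    fio.write_csv(put("peaks", f"{name}_peaks.csv"), pkdf)

    summary.update(
        {
            "mean_diameter_histogram": fs.mean_diameter_histogram,
            "mean_diameter_superpixel": fs.mean_diameter_superpixel,
            "diameter_sd": fs.sd,
            "n_samples": fs.n_samples,
            "porosity": ps.porosity,
            "mean_mesh_hole": ps.mean_mesh_hole,
            "intersection_density": ps.intersection_density,
            "characteristic_fiber_length": ps.characteristic_fiber_length,
            "modal_angle_deg": nres.modal_angle,
            "noi_percent": nres.noi,
            "units": "um" if config.scale is not None else "px",
        }
    )
    # 9 summary row
    fio.write_csv(put("summary", f"{name}_summary.csv"), pd.DataFrame([summary]))
    # 10 manifest with config echo
    put("manifest", f"{name}_manifest.json").write_text(
        json.dumps({"config": asdict(config), "files": files}, indent=2, default=str)
    )
    return OutputBundle(name, files, summary)


def run_pipeline(config: RunConfig) -> list[OutputBundle]:
    """Analyze every input; per-file failures are recorded, not fatal."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for pattern in config.inputs:
        p = Path(pattern)
        if p.exists():
            paths.append(p)
        else:
            paths.extend(sorted(p.parent.glob(p.name)))
    bundles = []
    for p in paths:
        name = p.stem
        try:
            img = fio.read_image(p)
            log.info("analyzing %s (%dx%d)", name, img.shape[1], img.shape[0])
            bundles.append(analyze_image(img, name, outdir, config))
        except Exception as exc:  # noqa: BLE001 - batch must continue
            log.error("%s: %s", name, exc)
            bundles.append(OutputBundle(name, {}, {"image": name}, error=str(exc)))
    rows = [b.summary for b in bundles if b.error is None]
    if rows:
        fio.write_csv(outdir / "summary.csv", pd.DataFrame(rows))
    return bundles
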