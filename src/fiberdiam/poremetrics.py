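"""Scaffold-level pore and network statistics from a segmented mask.

The four summary metrics follow the usual fiber-network reading; the
source summary table names them without formulas, so the definitions
here are the package's documented interpretations:

* porosity — background fraction of the image;
* mean mesh hole size — mean area of 4-connected background components
  that do not touch the image border (border pores have unknown true
  extent and are excluded by default);
* intersection density — number of fiber-crossing sites per unit area;
* characteristic fiber length — total centerline length divided by the
  number of centerline segments, i.e. the mean run between successive
  crossings/endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fibercore import Skeleton, skeletonize

_FOUR = ndimage.generate_binary_structure(2, 1)


@dataclass
class PoreStats:
    porosity: float
    mean_mesh_hole: float  # px^2 (um^2 when scale set)
    intersection_density: float  # per px^2 (per um^2 when scale set)
    characteristic_fiber_length: float  # px (um when scale set)
    n_pores: int
    scale: float | None = None


def pore_stats(
    mask: np.ndarray,
    skel: Skeleton | None = None,
    include_border_pores: bool = False,
    scale: float | None = None,
) -> PoreStats:
    """Compute the pore/network summary for one mask.

    An empty mask reports porosity 1 with the other fields NaN.  Units
    follow ``scale`` (um/px): areas scale quadratically, lengths
    linearly, densities inversely-quadratically.
    """
    m = np.asarray(mask) > 0
    h, w = m.shape
    total = m.size
    porosity = float((~m).sum()) / total
    if not m.any():
        return PoreStats(1.0, float("nan"), float("nan"), float("nan"), 0, scale)
    if skel is None:
        skel = skeletonize(m)

    labels, n = ndimage.label(~m, structure=_FOUR)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    if not include_border_pores and n > 0:
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        border = border[border > 0]
        keep = np.setdiff1d(np.arange(1, n + 1), border)
        areas = areas[keep - 1] if len(keep) else np.array([])
    mean_hole = float(np.mean(areas)) if len(np.atleast_1d(areas)) else float("nan")

    density = skel.n_intersections / float(total)
    char_len = (
        skel.total_length / skel.n_segments if skel.n_segments > 0 else float("nan")
    )
    if scale is not None:
        if scale <= 0:
            raise ValueError("scale must be positive")
        mean_hole *= scale**2
        density /= scale**2
        char_len *= scale
    n_pores = len(np.atleast_1d(areas)) if not np.isnan(mean_hole) else 0
    return PoreStats(porosity, mean_hole, density, char_len, n_pores, scale)
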