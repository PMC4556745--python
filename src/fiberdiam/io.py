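"""Image and CSV I/O helpers for the analysis pipeline."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG micrograph as 8-bit grayscale.

    Multi-channel images are averaged to one channel; 16-bit data is
    rescaled to the 8-bit range.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image")
    if arr.dtype == np.uint16:
        arr = arr.astype(float) / 257.0
    elif np.issubdtype(arr.dtype, np.floating) and arr.max() <= 1.0:
        arr = arr * 255.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def write_image(path: str | Path, arr: np.ndarray) -> None:
    path = Path(path)
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def is_binary(arr: np.ndarray) -> bool:
    vals = np.unique(arr)
    return len(vals) <= 2 and set(vals.tolist()) <= {0, 1, 255}


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_histogram_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a histogram CSV: first column vs its ``count`` column."""
    df = pd.read_csv(path)
    y = df["count"] if "count" in df.columns else df.iloc[:, 1]
    return df.iloc[:, 0].to_numpy(float), y.to_numpy(float)
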