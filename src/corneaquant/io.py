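"""Reading and writing images and tables.

Section images are accepted as JPEG2000 (.jp2/.j2k), TIFF or PNG through
imageio/Pillow.  Tabular outputs are plain CSV; files written by the
pipeline carry a provenance header (version, config hash, seed) as
``#``-prefixed comment lines.
"""

from __future__ import annotations

import io as _io
import os
from typing import Dict, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_section",
    "write_image",
    "write_mask",
    "write_label_image",
    "write_table",
    "read_table",
]

IMAGE_EXTENSIONS = (".jp2", ".j2k", ".tif", ".tiff", ".png")


def read_section(path: str) -> np.ndarray:
    """Read an RGB section image (JPEG2000, TIFF or PNG) as H×W×3 uint8.

    Grayscale inputs are replicated across channels; an alpha channel is
    dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path: str, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image))


def write_mask(path: str, mask: np.ndarray) -> None:
    """Binary mask as a single-channel 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def write_label_image(path: str, labels: np.ndarray) -> None:
    """ROI label image as 16-bit PNG (label = 6*(layer-1) + frame)."""
    iio.imwrite(path, np.asarray(labels).astype(np.uint16))


def write_table(
    path: str,
    frame: pd.DataFrame,
    header: Optional[Dict[str, object]] = None,
) -> None:
    """CSV with optional ``# key: value`` provenance header lines."""
    buf = _io.StringIO()
    if header:
        for k, v in header.items():
            buf.write(f"# {k}: {v}\n")
    frame.to_csv(buf, index=False)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
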