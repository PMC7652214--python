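"""Per-ROI brightness: the mean green intensity as a damage proxy.

For region R_ij (layer i, frame j) with area A_ij the brightness is

    b_ij = (1 / A_ij) * sum_{(r,c) in R_ij} I_g(r, c)

where I_g is the green channel.  High brightness indicates stromal
laxity (bright unstained gaps), low brightness indicates compactness.
Because the statistic is a plain regional average it responds
continuously to partial damage with no detection threshold.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .roi_grid import RoiGrid

logger = logging.getLogger(__name__)

__all__ = [
    "roi_brightness",
    "coefficient_of_variation",
    "summarize_population",
    "aggregate_to_cornea",
]

TABLE_COLUMNS = [
    "cornea_id",
    "population",
    "slide_id",
    "layer",
    "frame",
    "brightness",
    "area",
]


def roi_brightness(
    green: np.ndarray,
    grid: RoiGrid,
    metadata: Optional[Dict[str, object]] = None,
) -> pd.DataFrame:
    """Long-format brightness table: one row per nonempty ROI.

    ``metadata`` supplies the identifying columns (cornea_id, population,
    slide_id); missing keys default to empty strings.  Empty ROIs are
    skipped with a logged notice.
    """
    green = np.asarray(green)
    if green.shape != grid.label_image.shape:
        raise ValueError(
            f"green image shape {green.shape} does not match ROI grid "
            f"shape {grid.label_image.shape}"
        )
    meta = metadata or {}
    labels = grid.label_image.ravel()
    sums = np.bincount(
        labels, weights=green.ravel().astype(float),
        minlength=grid.n_layers * grid.n_frames + 1,
    )
    counts = np.bincount(labels, minlength=grid.n_layers * grid.n_frames + 1)

    rows = []
    for i in range(1, grid.n_layers + 1):
        for j in range(1, grid.n_frames + 1):
            lab = grid.label_of(i, j)
            if counts[lab] == 0:
                logger.info("ROI (layer %d, frame %d) empty; skipped", i, j)
                continue
            rows.append(
                {
                    "cornea_id": meta.get("cornea_id", ""),
                    "population": meta.get("population", ""),
                    "slide_id": meta.get("slide_id", ""),
                    "layer": i,
                    "frame": j,
                    "brightness": sums[lab] / counts[lab],
                    "area": int(counts[lab]),
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def coefficient_of_variation(mean: float, std: float) -> float:
    """CV in percent: 100 * std / mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * std / mean


def summarize_population(table: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean, median, SD, CV (%) and IQR of brightness.

    SD is the sample standard deviation (ddof=1); IQR is the 75th minus
    the 25th percentile.  Requires >= 2 records per population, otherwise
    dispersion is undefined.
    """
    out = []
    for pop, sub in table.groupby("population", sort=True):
        b = sub["brightness"].to_numpy(dtype=float)
        if len(b) < 2:
            raise ValueError(
                f"population {pop!r} has {len(b)} record(s); dispersion "
                "statistics require at least 2"
            )
        mean = float(b.mean())
        sd = float(b.std(ddof=1))
        q25, q75 = np.percentile(b, [25, 75])
        out.append(
            {
                "population": pop,
                "n": len(b),
                "mean": mean,
                "median": float(np.median(b)),
                "std": sd,
                "cv": coefficient_of_variation(mean, sd),
                "iqr": float(q75 - q25),
            }
        )
    return pd.DataFrame(out)


def aggregate_to_cornea(table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate-slide records of one cornea per (layer, frame).

    Serial sections of a cornea are not independent; this collapses them
    to cornea level before statistics when that mode is selected.
    """
    grouped = (
        table.groupby(["cornea_id", "population", "layer", "frame"], sort=True)
        .agg(brightness=("brightness", "mean"), area=("area", "sum"))
        .reset_index()
    )
    grouped["slide_id"] = "pooled"
    return grouped[["cornea_id", "population", "slide_id", "layer", "frame",
                    "brightness", "area"]]
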