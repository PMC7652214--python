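"""Subdivision of the cornea band into depth layers x radial frames.

Each tissue pixel is assigned to the nearest centerline point; the
point's arc length selects one of ``n_frames`` equal radial frames, and
the pixel's perpendicular offset — normalized by the local half-thickness
on its side of the centerline — selects one of ``n_layers`` equal depth
layers.  The default 4 x 6 grid yields 24 regions of interest per
section.  Layer 1 is the anterior (epithelial) side, layer ``n_layers``
the posterior (endothelial) side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .centerline import CenterLine, scan_half_thickness

logger = logging.getLogger(__name__)

__all__ = ["RoiGrid", "build_roi_grid", "layer_index_from_offset"]


def layer_index_from_offset(u: np.ndarray, n_layers: int = 4) -> np.ndarray:
    """Map normalized offset u in [-1, +1] (+1 = anterior boundary) to a
    1-based layer index; layer 1 is anterior-most.

    Boundaries sit at equal intervals of u; a pixel exactly on a boundary
    joins the more anterior layer (deterministic tie-break).
    """
    u = np.asarray(u, dtype=float)
    bins = np.floor((u + 1.0) / 2.0 * n_layers).astype(int)
    bins = np.clip(bins, 0, n_layers - 1)
    return n_layers - bins


@dataclass
class RoiGrid:
    """Label image over the mask: 0 = background, else ``(i-1)*n_frames + j``
    for layer i and frame j."""

    label_image: np.ndarray
    n_layers: int = 4
    n_frames: int = 6
    orientation_verified: bool = True
    areas: Dict[Tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.areas:
            self.areas = self._compute_areas()

    def _compute_areas(self) -> Dict[Tuple[int, int], int]:
        labels, counts = np.unique(self.label_image, return_counts=True)
        out: Dict[Tuple[int, int], int] = {}
        for lab, cnt in zip(labels, counts):
            if lab == 0:
                continue
            i = (lab - 1) // self.n_frames + 1
            j = (lab - 1) % self.n_frames + 1
            out[(int(i), int(j))] = int(cnt)
        return out

    def label_of(self, layer: int, frame: int) -> int:
        return (layer - 1) * self.n_frames + frame

    def region(self, layer: int, frame: int) -> np.ndarray:
        """(n, 2) array of (row, col) pixel coordinates of one ROI."""
        return np.argwhere(self.label_image == self.label_of(layer, frame))

    @property
    def n_nonzero_labels(self) -> int:
        return len(self.areas)

    @property
    def mask_area(self) -> int:
        return int((self.label_image > 0).sum())

    def to_frame(self):
        import pandas as pd

        rows = [
            {"layer": i, "frame": j, "area": a}
            for (i, j), a in sorted(self.areas.items())
        ]
        return pd.DataFrame(rows)


def build_roi_grid(
    mask: np.ndarray,
    line: CenterLine,
    n_layers: int = 4,
    n_frames: int = 6,
    anterior_side: Optional[str] = None,
) -> RoiGrid:
    """Partition the mask into ``n_layers x n_frames`` regions of interest.

    Parameters
    ----------
    anterior_side : "left" | "right" | None
        Which side of the centerline (relative to its travel direction,
        in image coordinates with y down) carries the epithelium.  When
        None the grid is still built — with "left" assumed — but flagged
        ``orientation_verified=False`` and a notice is logged; layer
        indices may then be flipped relative to anatomy.

    Every mask pixel receives exactly one label, so the per-ROI areas sum
    to the mask area.  Empty ROIs (degenerate geometry) produce a logged
    warning but the grid is still returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_layers < 1 or n_frames < 1:
        raise ValueError("n_layers and n_frames must be >= 1")
    if anterior_side is None:
        logger.warning(
            "anterior side not specified: assuming 'left'; layer indices are "
            "orientation-unverified"
        )
        side, verified = "left", False
    elif anterior_side in ("left", "right"):
        side, verified = anterior_side, True
    else:
        raise ValueError("anterior_side must be 'left', 'right' or None")

    pts = line.points
    normals = line.normals_left()
    if side == "right":
        normals = -normals

    # local half-thickness per centerline point, each side, by normal scan
    h_ant = scan_half_thickness(mask, pts, normals)
    h_post = scan_half_thickness(mask, pts, -normals)
    for h in (h_ant, h_post):
        bad = ~np.isfinite(h) | (h <= 0)
        if bad.all():
            raise ValueError("centerline does not lie inside the mask")
        if bad.any():  # ends can fail; fill from neighbors
            good = np.flatnonzero(~bad)
            h[bad] = np.interp(np.flatnonzero(bad), good, h[good])

    rc = np.argwhere(mask)
    pix = rc[:, ::-1].astype(float)  # (x, y)
    _, nearest = cKDTree(pts).query(pix)

    s = line.arclength[nearest]
    f = s / line.total_length * n_frames
    frame = np.floor(f).astype(int)
    exact_boundary = (f == np.rint(f)) & (frame > 0)
    frame[exact_boundary] -= 1  # pixels exactly on a boundary join the lower frame
    frame = np.clip(frame, 0, n_frames - 1) + 1

    delta = pix - pts[nearest]
    d = np.einsum("ij,ij->i", delta, normals[nearest])
    half = np.where(d >= 0, h_ant[nearest], h_post[nearest])
    u = np.clip(d / np.maximum(half, 1e-9), -1.0, 1.0)
    layer = layer_index_from_offset(u, n_layers=n_layers)

    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[rc[:, 0], rc[:, 1]] = (layer - 1) * n_frames + frame

    grid = RoiGrid(
        label_image=labels,
        n_layers=n_layers,
        n_frames=n_frames,
        orientation_verified=verified,
    )
    if grid.n_nonzero_labels < n_layers * n_frames:
        missing = [
            (i, j)
            for i in range(1, n_layers + 1)
            for j in range(1, n_frames + 1)
            if (i, j) not in grid.areas
        ]
        logger.warning(
            "degenerate geometry: %d empty ROI(s) %s; they will be excluded "
            "from statistics",
            len(missing),
            missing,
        )
    return grid
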