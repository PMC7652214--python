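"""Medial-axis estimation for curved tissue bands.

The cornea section appears as a long, gently curved band.  Its center
line is estimated in three stages, mirroring the classic band-tracking
approach: (1) a third-order polynomial fitted to the binary mask (after
PCA pre-rotation so the band is roughly horizontal) as the initial
estimate; (2) refinement of each sampled point to the midpoint of the two
mask-boundary crossings along the local normal; (3) a cubic smoothing
spline, resampled at equal arc-length steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import interpolate
from scipy.ndimage import map_coordinates

__all__ = [
    "CenterLine",
    "InitialAxis",
    "CenterlineError",
    "fit_initial_polynomial",
    "refine_centerline",
    "smooth_centerline",
    "extract_centerline",
    "centerline_from_points",
]


class CenterlineError(RuntimeError):
    """Raised when the medial axis cannot be estimated."""


@dataclass(frozen=True)
class CenterLine:
    """Ordered, equally-sampled polyline with arc-length parameterization.

    ``points`` is an (N, 2) array of sub-pixel (x, y) coordinates;
    ``arclength`` the cumulative arc length per point (pixels), strictly
    increasing and uniformly incremented by construction.
    """

    points: np.ndarray
    arclength: np.ndarray

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])

    def __len__(self) -> int:
        return len(self.points)

    def tangents(self) -> np.ndarray:
        """Unit tangent per point (central differences, ends one-sided)."""
        d = np.gradient(self.points, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def normals_left(self) -> np.ndarray:
        """Unit normal pointing to the *left* of the travel direction.

        Image coordinates have y increasing downward, so for a band
        travelled left-to-right the "left" normal points toward smaller
        row indices (up).
        """
        t = self.tangents()
        return np.column_stack([t[:, 1], -t[:, 0]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.points[:, 0], "y": self.points[:, 1], "s": self.arclength}
        )


@dataclass(frozen=True)
class InitialAxis:
    """Cubic y(x) in a PCA-rotated frame plus the rotation taking the
    rotated frame back to image coordinates."""

    coeffs: np.ndarray  # polynomial coefficients, ascending degree
    angle: float  # rotation angle of the principal axis (radians)
    centroid: np.ndarray  # (x, y) mask centroid in image coordinates
    x_range: Tuple[float, float]  # extent of the mask along the axis

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(x, self.coeffs)

    def to_image(self, xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        x = ca * xr - sa * yr + self.centroid[0]
        y = sa * xr + ca * yr + self.centroid[1]
        return np.column_stack([x, y])


def centerline_from_points(points: np.ndarray, n_out: int = 200) -> CenterLine:
    """Resample an ordered polyline to ``n_out`` equal arc-length steps."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise CenterlineError("degenerate polyline with zero length")
    s_new = np.linspace(0.0, s[-1], n_out)
    x = np.interp(s_new, s, points[:, 0])
    y = np.interp(s_new, s, points[:, 1])
    return CenterLine(points=np.column_stack([x, y]), arclength=s_new)


def fit_initial_polynomial(mask: np.ndarray) -> InitialAxis:
    """Least-squares cubic through all mask pixels in a PCA-rotated frame.

    The pixel-coordinate covariance defines the principal axis; the mask
    is rotated so this axis is horizontal before fitting y(x), which
    makes the fit independent of how the section lies on the slide.
    Raises :class:`CenterlineError` when the mask is empty or nearly
    isotropic (principal-axis eigenvalue ratio <= 1.05).
    """
    rc = np.argwhere(np.asarray(mask, dtype=bool))
    if len(rc) == 0:
        raise CenterlineError("empty mask")
    xy = rc[:, ::-1].astype(float)  # (x, y)
    centroid = xy.mean(axis=0)
    cov = np.cov((xy - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[1] / evals[0] <= 1.05:
        raise CenterlineError(
            "orientation ambiguity: mask is nearly isotropic "
            f"(eigenvalue ratio {evals[1] / max(evals[0], 1e-12):.3f})"
        )
    axis = evecs[:, 1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # deterministic travel direction
    angle = float(np.arctan2(axis[1], axis[0]))
    ca, sa = np.cos(angle), np.sin(angle)
    d = xy - centroid
    xr = ca * d[:, 0] + sa * d[:, 1]
    yr = -sa * d[:, 0] + ca * d[:, 1]
    coeffs = np.polynomial.polynomial.polyfit(xr, yr, 3)
    return InitialAxis(
        coeffs=coeffs,
        angle=angle,
        centroid=centroid,
        x_range=(float(xr.min()), float(xr.max())),
    )


def _mask_interp(mask: np.ndarray):
    m = np.asarray(mask, dtype=float)

    def sample(points_xy: np.ndarray) -> np.ndarray:
        coords = np.stack([points_xy[..., 1], points_xy[..., 0]])  # (row, col)
        return map_coordinates(m, coords, order=1, mode="constant", cval=0.0)

    return sample


def scan_half_thickness(
    mask: np.ndarray,
    points: np.ndarray,
    normals: np.ndarray,
    step: float = 0.25,
    max_dist: Optional[float] = None,
) -> np.ndarray:
    """Distance from each point to the mask boundary along +normal.

    The mask is bilinearly interpolated; the boundary is the first 0.5
    crossing, localized sub-pixel by linear interpolation between the
    bracketing samples.  Returns NaN where the starting point is outside
    the mask or no crossing is found within ``max_dist``.
    """
    mask = np.asarray(mask, dtype=bool)
    if max_dist is None:
        max_dist = float(min(mask.shape))
    sample = _mask_interp(mask)
    ts = np.arange(0.0, max_dist + step, step)
    # (n_points, n_steps, 2)
    probe = points[:, None, :] + ts[None, :, None] * normals[:, None, :]
    vals = sample(probe)
    inside = vals >= 0.5
    out = np.full(len(points), np.nan)
    ok_start = inside[:, 0]
    # first step index that is outside
    any_exit = ~inside.all(axis=1)
    idx = np.argmax(~inside, axis=1)
    valid = ok_start & any_exit & (idx > 0)
    i = idx[valid]
    rows = np.flatnonzero(valid)
    v_prev = vals[rows, i - 1]
    v_next = vals[rows, i]
    frac = (v_prev - 0.5) / np.maximum(v_prev - v_next, 1e-12)
    out[rows] = ts[i - 1] + frac * step
    return out


def refine_centerline(
    mask: np.ndarray,
    init: InitialAxis,
    n_samples: int = 200,
    step: float = 0.25,
    edge_inset: float = 0.02,
    outlier_factor: float = 2.5,
) -> np.ndarray:
    """Move sampled polynomial points to the normal-line midpoints.

    For each of ``n_samples`` points on the initial polynomial, the line
    perpendicular to it is scanned in both directions; the point is
    replaced by the midpoint of the two boundary crossings, i.e. the
    location equidistant from the opposite band boundaries.  Points whose
    normal fails to cross the boundary on either side, or whose crossing
    distance is an outlier (``outlier_factor`` x median — normals escaping
    through the band's end caps), are dropped.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    x0, x1 = init.x_range
    span = x1 - x0
    xs = np.linspace(x0 + edge_inset * span, x1 - edge_inset * span, n_samples)
    ys = init(xs)
    dy = np.polynomial.polynomial.polyval(
        xs, np.polynomial.polynomial.polyder(init.coeffs)
    )
    pts = init.to_image(xs, ys)
    tan_r = np.column_stack([np.ones_like(xs), dy])
    ca, sa = np.cos(init.angle), np.sin(init.angle)
    tan = np.column_stack(
        [ca * tan_r[:, 0] - sa * tan_r[:, 1], sa * tan_r[:, 0] + ca * tan_r[:, 1]]
    )
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    nrm = np.column_stack([tan[:, 1], -tan[:, 0]])

    d_plus = scan_half_thickness(mask, pts, nrm, step=step)
    d_minus = scan_half_thickness(mask, pts, -nrm, step=step)
    ok = np.isfinite(d_plus) & np.isfinite(d_minus)
    if ok.sum() < 0.5 * n_samples:
        raise CenterlineError(
            f"refinement failure: only {int(ok.sum())}/{n_samples} normals "
            "crossed the band boundary on both sides"
        )
    med_p = np.median(d_plus[ok])
    med_m = np.median(d_minus[ok])
    total = d_plus + d_minus
    med_t = np.median(total[ok])
    # drop outliers: normals escaping through the band's end caps either
    # travel far along the band (large one-sided distance) or cross a
    # foreshortened cap profile (total thickness well below the median)
    keep = (
        ok
        & (d_plus <= outlier_factor * med_p)
        & (d_minus <= outlier_factor * med_m)
        & (total >= 0.85 * med_t)
    )
    shift = (d_plus[keep] - d_minus[keep]) / 2.0
    return pts[keep] + shift[:, None] * nrm[keep]


def smooth_centerline(
    points: np.ndarray,
    smoothing: Optional[float] = None,
    n_out: int = 200,
    mask: Optional[np.ndarray] = None,
) -> CenterLine:
    """Cubic smoothing spline through refined points, equal-arc resampled.

    ``smoothing`` is the spline residual budget (scipy's ``s``); the
    default ``0.25 * n_points`` corresponds to ~0.5 px point noise.  With
    ``smoothing=0`` the spline interpolates.  When ``mask`` is given the
    dense spline samples are trimmed to the mask before resampling so
    every returned point lies inside the band.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise CenterlineError("at least 4 points are required for a cubic spline")
    if smoothing is None:
        smoothing = 0.25 * len(points)
    # parametrize by chord length to keep the fit stable on curved bands
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    u /= u[-1]
    tck, _ = interpolate.splprep(
        [points[:, 0], points[:, 1]], u=u, s=smoothing, k=3
    )
    dense_u = np.linspace(0.0, 1.0, max(20 * n_out, 4000))
    dx, dyv = interpolate.splev(dense_u, tck)
    dense = np.column_stack([dx, dyv])
    if mask is not None:
        inside = _mask_interp(mask)(dense) >= 0.5
        # keep the longest contiguous inside run (trim ends that exited)
        if not inside.all():
            runs = np.flatnonzero(np.diff(np.concatenate([[0], inside, [0]])))
            starts, ends = runs[::2], runs[1::2]
            best = np.argmax(ends - starts)
            dense = dense[starts[best] : ends[best]]
        if len(dense) < 2:
            raise CenterlineError("centerline left the mask entirely")
    return centerline_from_points(dense, n_out=n_out)


def extract_centerline(
    mask: np.ndarray,
    n_samples: int = 200,
    smoothing: Optional[float] = None,
    n_out: int = 200,
    refine_iterations: int = 1,
) -> CenterLine:
    """Full medial-axis pipeline: cubic init, normal refinement, spline."""
    init = fit_initial_polynomial(mask)
    pts = None
    for _ in range(max(1, refine_iterations)):
        pts = refine_centerline(mask, init, n_samples=n_samples)
        # re-fit the cubic to the refined points for optional extra passes
        if refine_iterations > 1:
            ca, sa = np.cos(init.angle), np.sin(init.angle)
            d = pts - init.centroid
            xr = ca * d[:, 0] + sa * d[:, 1]
            yr = -sa * d[:, 0] + ca * d[:, 1]
            coeffs = np.polynomial.polynomial.polyfit(xr, yr, 3)
            init = InitialAxis(coeffs, init.angle, init.centroid, init.x_range)
    return smooth_centerline(pts, smoothing=smoothing, n_out=n_out, mask=mask)
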