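"""Synthetic H&E-like cornea sections with analytic ground truth.

Real corneal sections are curved bands of darkly stained stroma on a bright
slide background; stromal damage shows up as bright unstained fissures
(gaps and holes) inside the band.  This module draws such bands as circular
arcs so that the mask, the medial axis and the layer geometry are known
exactly, which makes every downstream stage of the pipeline testable
without slide scans.

Only the green channel carries signal (the quantification uses the green
channel exclusively); red and blue are affine pink-tint functions of green.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .centerline import CenterLine, centerline_from_points
from .roi_grid import RoiGrid, layer_index_from_offset

logger = logging.getLogger(__name__)

__all__ = [
    "SynthParams",
    "CohortSpec",
    "SyntheticSection",
    "generate_section",
    "generate_cohort",
    "default_cohort_spec",
]

#: default populations mirroring a three-arm study design
DEFAULT_POPULATIONS = ("healthy", "injured", "treated")


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic cornea section.

    Attributes
    ----------
    image_height, image_width : int
        Canvas size in pixels.
    band_curvature : float
        Dimensionless sagitta ratio in [0, 1): the vertical bulge of the
        band's medial arc as a fraction of ``image_height / 3``.  0 gives a
        straight horizontal band.
    band_thickness : float
        Band thickness in pixels (>= 8 so that four depth layers are each
        at least two pixels).
    tissue_base_intensity, background_intensity : float
        Green-channel grey levels (0-255) of stained tissue and of the
        empty slide.  Background must be brighter than tissue, as in H&E.
    fissure_density : float
        Expected number of bright fissures per 1000 tissue pixels.
    fissure_brightness : float
        Green grey level inside fissures (bright, unstained).
    fissure_axis_lengths : (float, float)
        Uniform range of ellipse semi-axis lengths in pixels.
    layer_gain : 4-tuple of float
        Additive grey-level offset per depth layer (index 0 = layer 1,
        the anterior side).
    staining_sd : float
        Standard deviation (grey levels) of a smooth random staining
        field emulating non-uniform H&E uptake, with correlation length
        ``staining_corr_length`` — small patches so that every region of
        interest averages over many independent stain fluctuations.
    noise_sd : float
        Per-pixel Gaussian noise SD in grey levels.
    seed : int
        Seed of the per-section random stream.
    """

    image_height: int = 360
    image_width: int = 480
    band_curvature: float = 0.5
    band_thickness: float = 81.0
    tissue_base_intensity: float = 140.0
    background_intensity: float = 230.0
    fissure_density: float = 2.0
    fissure_brightness: float = 235.0
    fissure_axis_lengths: Tuple[float, float] = (1.5, 4.5)
    layer_gain: Tuple[float, float, float, float] = (0.0, 10.0, 10.0, 0.0)
    staining_sd: float = 10.0
    staining_corr_length: float = 4.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image_height and image_width must be >= 32")
        if not (0.0 <= self.band_curvature < 1.0):
            raise ValueError("band_curvature must lie in [0, 1)")
        if self.band_thickness < 8:
            raise ValueError(
                "band_thickness must be >= 8 pixels so each of the 4 depth "
                "layers spans at least 2 pixels"
            )
        if not (self.background_intensity > self.tissue_base_intensity):
            raise ValueError(
                "background_intensity must exceed tissue_base_intensity "
                "(H&E background is bright, stained tissue dark)"
            )
        if self.fissure_density < 0:
            raise ValueError("fissure_density must be >= 0")
        lo, hi = self.fissure_axis_lengths
        if not (0 < lo <= hi):
            raise ValueError("fissure_axis_lengths must satisfy 0 < lo <= hi")
        if len(self.layer_gain) != 4:
            raise ValueError("layer_gain must have exactly 4 entries")
        if self.noise_sd < 0 or self.staining_sd < 0:
            raise ValueError("noise_sd and staining_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of sections across populations with known effect structure.

    Each population contributes ``n_per_group`` corneas with
    ``slides_per_cornea`` serial sections each, mirroring the multiple
    H&E slides cut from one cornea.  A cornea-level random intercept
    (SD ``between_cornea_sd``) is shared by its slides.

    ``population_effects`` maps each population label to a triple
    ``(mean_offset, fissure_multiplier, variance_multiplier)``:

    * ``mean_offset`` — grey levels added to the tissue base intensity;
    * ``fissure_multiplier`` — scales the fissure density;
    * ``variance_multiplier`` m — scales the *variance* of every
      stochastic brightness component while leaving the mean unchanged:
      the cornea intercept and staining-field SDs grow by sqrt(m), and
      the fissure population trades count for size (density / m, axis
      lengths x sqrt(m)), i.e. fewer but larger residual gaps — a
      heterogeneous-response population.

    The default preset encodes the study conditions: injured sections
    brighter by ~5 grey levels overall (a diffuse stain-loss offset plus
    a 1.3x fissure density, whose measured mean contribution is ~+2),
    treated sections healthy-like in mean but with the stochastic
    variance inflated 1.5x.
    """

    n_per_group: "int | Dict[str, int]" = 10
    slides_per_cornea: int = 4
    population_effects: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "healthy": (0.0, 1.0, 1.0),
            "injured": (4.0, 1.3, 1.0),
            "treated": (0.0, 1.0, 1.5),
        }
    )
    between_cornea_sd: float = 0.35
    seed: int = 0

    def group_size(self, population: str) -> int:
        if isinstance(self.n_per_group, dict):
            return int(self.n_per_group.get(population, 0))
        return int(self.n_per_group)

    def validate(self) -> None:
        sizes = (
            list(self.n_per_group.values())
            if isinstance(self.n_per_group, dict)
            else [self.n_per_group]
        )
        if any(n < 0 for n in sizes):
            raise ValueError("n_per_group must be >= 0")
        if self.slides_per_cornea < 1:
            raise ValueError("slides_per_cornea must be >= 1")
        if not self.population_effects:
            raise ValueError("population_effects must not be empty")
        for pop, eff in self.population_effects.items():
            if len(eff) != 3:
                raise ValueError(f"effect triple required for {pop!r}")
            if eff[1] < 0 or eff[2] <= 0:
                raise ValueError(
                    f"{pop!r}: fissure multiplier must be >= 0 and variance "
                    "multiplier > 0"
                )


def default_cohort_spec(n_per_group: int = 10, seed: int = 0) -> CohortSpec:
    """The default three-population preset (healthy / injured / treated)."""
    return CohortSpec(n_per_group=n_per_group, seed=seed)


@dataclass
class SyntheticSection:
    """One generated section plus its analytic ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W bool, ground-truth tissue band
    centerline: CenterLine  # ground-truth medial arc, equally sampled
    grid: RoiGrid  # ground-truth 4 x 6 ROI labelling
    anterior_side: str  # "left" or "right" of centerline travel direction
    metadata: Dict[str, object]


# ----------------------------------------------------------------------
# geometry helpers


def _arc_geometry(params: SynthParams):
    """Return (signed distance field, arc-length field, truth centerline).

    The medial axis is a circular arc through the two chord endpoints
    (margin-inset on the left/right image borders) with sagitta
    ``band_curvature * image_height / 3``; curvature 0 degenerates to the
    straight chord.  Signed distance is positive *above* the axis (toward
    smaller row indices), which is the anterior side by convention.
    """
    h, w = params.image_height, params.image_width
    t = params.band_thickness
    margin = max(8.0, 0.04 * w)
    x0, x1 = margin, w - 1 - margin
    # vertical placement: keep the whole band inside the canvas
    sag = params.band_curvature * h / 3.0
    yc = (h - 1) / 2.0 - sag / 2.0  # chord height

    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    if sag < 1e-9:
        d_signed = yc - yy  # positive above the line
        s_field = xx - x0
        s0, s1 = 0.0, x1 - x0
        n_pts = 512
        s_pts = np.linspace(s0, s1, n_pts)
        pts = np.column_stack([x0 + s_pts, np.full(n_pts, yc)])
    else:
        chord = x1 - x0
        radius = (chord**2 / 4.0 + sag**2) / (2.0 * sag)
        cx = (x0 + x1) / 2.0
        cy = yc + (radius - sag)  # circle center below the chord
        rr = np.hypot(xx - cx, yy - cy)
        d_signed = radius - rr  # positive inside the circle = above arc
        ang = np.arctan2(cx - xx, cy - yy)  # 0 at apex, increasing with x
        ang0 = np.arctan2(cx - x0, cy - yc)
        ang1 = np.arctan2(cx - x1, cy - yc)
        s_field = radius * (ang0 - ang)
        s0, s1 = 0.0, radius * (ang0 - ang1)
        n_pts = 512
        ang_pts = np.linspace(ang0, ang1, n_pts)
        pts = np.column_stack(
            [cx - radius * np.sin(ang_pts), cy - radius * np.cos(ang_pts)]
        )

    half = (t - 1.0) / 2.0
    mask = (np.abs(d_signed) <= half) & (s_field >= s0) & (s_field <= s1)
    return d_signed, s_field, s1, half, mask, pts


def _smooth_staining_field(rng, shape, sd, corr_length=4.0):
    """Stationary correlated Gaussian field: blurred white noise.

    White noise smoothed with a Gaussian of ``corr_length`` pixels and
    rescaled to pointwise SD ``sd``; stationarity avoids any systematic
    spatial structure that could masquerade as a layer or frame effect.
    """
    if sd <= 0:
        return np.zeros(shape)
    from scipy.ndimage import gaussian_filter

    f = gaussian_filter(rng.normal(0.0, 1.0, size=shape), corr_length,
                        mode="reflect")
    return f * (sd / f.std())


def _draw_fissures(rng, green, mask, params: SynthParams):
    """Stamp bright elliptical fissures onto tissue pixels in place."""
    from skimage.draw import ellipse

    n_tissue = int(mask.sum())
    lam = params.fissure_density * n_tissue / 1000.0
    n_fissures = int(rng.poisson(lam)) if lam > 0 else 0
    if n_fissures == 0:
        return
    tissue_rc = np.argwhere(mask)
    centers = tissue_rc[rng.integers(0, len(tissue_rc), size=n_fissures)]
    lo, hi = params.fissure_axis_lengths
    h, w = mask.shape
    for (r0, c0) in centers:
        a, b = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, a, b, shape=(h, w), rotation=theta)
        keep = mask[rr, cc]
        green[rr[keep], cc[keep]] = params.fissure_brightness


def _tint(green: np.ndarray) -> np.ndarray:
    """H&E-pink RGB from the green plane (red/blue affine in green)."""
    g = green.astype(float)
    red = np.clip(0.35 * g + 160.0, 0, 255)
    blue = np.clip(0.45 * g + 120.0, 0, 255)
    return np.stack([red, g, blue], axis=-1).astype(np.uint8)


# ----------------------------------------------------------------------
# public API


def generate_section(
    params: SynthParams,
    metadata: Optional[Dict[str, object]] = None,
) -> SyntheticSection:
    """Generate one section image with exact mask / centerline / ROI truth.

    The green channel equals ``background_intensity`` outside the band and
    ``tissue_base_intensity + layer_gain[i] (+ fissures + staining field +
    noise)`` inside; values are clipped to [0, 255] and rounded to uint8.
    Identical ``params`` (including seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height, params.image_width

    d_signed, s_field, total_len, half, mask, pts = _arc_geometry(params)

    # ground-truth ROI grid from the analytic geometry: the normalized
    # offset u in [-1, 1] (+1 = anterior boundary) and arc-length sextiles
    half_extent = half + 0.5  # mask edge sits half a pixel beyond centers
    u = np.clip(d_signed / half_extent, -1.0, 1.0)
    layer = layer_index_from_offset(u)
    frame = np.clip((s_field / total_len * 6.0).astype(int) + 1, 1, 6)
    labels = np.where(mask, (layer - 1) * 6 + frame, 0).astype(np.int32)

    green = np.full((h, w), params.background_intensity, dtype=float)
    gains = np.asarray(params.layer_gain, dtype=float)
    tissue_vals = params.tissue_base_intensity + gains[layer - 1]
    green[mask] = tissue_vals[mask]

    _draw_fissures(rng, green, mask, params)
    if params.staining_sd > 0:
        field_ = _smooth_staining_field(
            rng, (h, w), params.staining_sd,
            corr_length=params.staining_corr_length,
        )
        green[mask] += field_[mask]
    if params.noise_sd > 0:
        green += rng.normal(0.0, params.noise_sd, size=(h, w))
    green = np.clip(np.rint(green), 0, 255)

    cl = centerline_from_points(pts, n_out=200)
    grid = RoiGrid(label_image=labels, n_layers=4, n_frames=6)

    meta = dict(metadata or {})
    meta.setdefault("anterior_side", "left")
    return SyntheticSection(
        image=_tint(green),
        mask=mask,
        centerline=cl,
        grid=grid,
        anterior_side="left",  # travelling with increasing s, anterior is up
        metadata=meta,
    )


def generate_cohort(
    spec: CohortSpec,
    params: Optional[SynthParams] = None,
) -> List[SyntheticSection]:
    """Generate a full multi-population cohort with known effect structure.

    Each section draws a population-specific mean offset, a between-section
    random intercept, a fissure density scaled by the population's
    multiplier, and stochastic-component SDs scaled by sqrt(variance
    multiplier).  The default preset reproduces the qualitative study
    pattern: injured sections brighter than healthy, treated sections
    healthy-like in mean but more variable, central layers brighter than
    the outer ones.
    """
    spec.validate()
    base = params if params is not None else SynthParams()
    base.validate()
    root = np.random.default_rng(spec.seed)

    sections: List[SyntheticSection] = []
    idx = 0
    for pop in spec.population_effects:
        n_corneas = spec.group_size(pop)
        if n_corneas == 0:
            logger.warning("population %r requested with 0 corneas; skipped", pop)
            continue
        mean_off, fiss_mult, var_mult = spec.population_effects[pop]
        sd_scale = float(np.sqrt(var_mult))
        for k in range(n_corneas):
            idx += 1
            cornea_rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
            intercept = float(
                cornea_rng.normal(0.0, spec.between_cornea_sd * sd_scale)
            )
            lo, hi = base.fissure_axis_lengths
            for s in range(spec.slides_per_cornea):
                child_seed = int(cornea_rng.integers(0, 2**31 - 1))
                p = replace(
                    base,
                    tissue_base_intensity=base.tissue_base_intensity
                    + mean_off
                    + intercept,
                    fissure_density=base.fissure_density * fiss_mult / var_mult,
                    fissure_axis_lengths=(lo * sd_scale, hi * sd_scale),
                    staining_sd=base.staining_sd * sd_scale,
                    seed=child_seed,
                )
                meta = {
                    "cornea_id": f"C{idx:03d}",
                    "population": pop,
                    "slide_id": f"S{s + 1}",
                    "seed": child_seed,
                    "anterior_side": "left",
                }
                sections.append(generate_section(p, metadata=meta))
    return sections


def write_cohort(
    sections: List[SyntheticSection], out_dir
) -> "pd.DataFrame":  # noqa: F821
    """Write cohort PNGs plus a sidecar metadata CSV; return the manifest."""
    import os

    import pandas as pd

    from .io import write_image

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for sec in sections:
        fname = f"{sec.metadata['cornea_id']}_{sec.metadata['slide_id']}.png"
        write_image(os.path.join(out_dir, fname), sec.image)
        rows.append(
            {
                "file": fname,
                "cornea_id": sec.metadata["cornea_id"],
                "population": sec.metadata["population"],
                "slide_id": sec.metadata["slide_id"],
                "seed": sec.metadata["seed"],
                "anterior_side": sec.anterior_side,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    return manifest
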