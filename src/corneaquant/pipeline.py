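"""End-to-end orchestration: images + metadata in, result bundle out.

One call processes every section listed in a metadata table through
segmentation, centerline extraction, ROI subdivision and brightness
measurement, then runs the statistical battery and writes the bundle
(brightness table, ANOVA, pairwise tests, rankings, heat maps, QC
overlays, run summary) to an output directory.  The run is deterministic
given the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .brightness import aggregate_to_cornea, roi_brightness, summarize_population
from .centerline import extract_centerline
from .io import read_section, write_label_image, write_mask, write_table
from .roi_grid import build_roi_grid
from .segmentation import extract_green, segment_cornea
from .stats import multiway_anova, pairwise_population_tests, roi_heatmap

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "uv_fluence",
           "ProtocolParams"]


@dataclass(frozen=True)
class ProtocolParams:
    """UV-A phototherapy protocol parameters."""

    irradiance_mw_cm2: float = 30.0
    exposure_min: float = 3.0
    wavelength_nm: float = 365.0

    def validate(self) -> None:
        if self.irradiance_mw_cm2 <= 0 or self.exposure_min <= 0:
            raise ValueError("irradiance and exposure must be positive")


def uv_fluence(params: ProtocolParams) -> float:
    """Total UV-A energy density in J/cm^2.

    energy = irradiance [mW/cm^2] x exposure [min] x 60 / 1000; e.g. the
    standard cross-linking protocol of 30 mW/cm^2 for 3 min delivers
    5.4 J/cm^2.
    """
    params.validate()
    return params.irradiance_mw_cm2 * params.exposure_min * 60.0 / 1000.0


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    image_dir: str = "."
    metadata_csv: str = "metadata.csv"
    output_dir: str = "corneaquant_out"
    # segmentation
    min_object_area: Optional[float] = None  # default: 0.1% of image pixels
    closing_radius: int = 5
    # centerline
    n_samples: int = 200
    smoothing: Optional[float] = None
    n_out: int = 200
    # grid
    n_layers: int = 4
    n_frames: int = 6
    anterior_side: Optional[str] = None  # "left" / "right"; may come per-row
    # statistics
    n_permutations: int = 4999
    seed: int = 0
    alpha: float = 0.05
    aggregate: str = "record"  # or "cornea"
    heatmap_pairs: Optional[List[Tuple[str, str]]] = None
    write_qc: bool = True

    def validate(self) -> None:
        if self.n_layers < 1 or self.n_frames < 1:
            raise ValueError("n_layers and n_frames must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.aggregate not in ("record", "cornea"):
            raise ValueError("aggregate must be 'record' or 'cornea'")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header(self) -> Dict[str, object]:
        return {
            "tool": f"corneaquant {__version__}",
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "aggregation": self.aggregate,
            "permutation_unit": "brightness records",
        }


@dataclass
class PipelineResult:
    brightness: pd.DataFrame
    anova: Optional[object]
    pairwise: Optional[pd.DataFrame]
    rankings: Dict[str, object]
    heatmaps: Dict[Tuple[str, str], object]
    skipped: List[Dict[str, str]]
    exit_code: int  # 0 full success, 2 partial, 1 fatal


def process_section(
    image: np.ndarray,
    config: PipelineConfig,
    metadata: Optional[Dict[str, object]] = None,
):
    """Segment one section and measure its ROI brightness table.

    Returns ``(table, mask, centerline, grid)``.
    """
    green = extract_green(image)
    mask = segment_cornea(
        green,
        min_object_area=config.min_object_area,
        closing_radius=config.closing_radius,
    )
    line = extract_centerline(
        mask,
        n_samples=config.n_samples,
        smoothing=config.smoothing,
        n_out=config.n_out,
    )
    meta = metadata or {}
    side = meta.get("anterior_side", config.anterior_side)
    grid = build_roi_grid(
        mask, line,
        n_layers=config.n_layers, n_frames=config.n_frames,
        anterior_side=side,
    )
    table = roi_brightness(green, grid, metadata=meta)
    return table, mask, line, grid


def _qc_overlay(path, image, mask, line, grid):
    """Mask boundary + centerline + ROI grid rendering for visual QC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 4.5), dpi=100)
    ax.imshow(image)
    ax.contour(mask.astype(float), levels=[0.5], colors="cyan", linewidths=0.8)
    bounds = find_boundaries(grid.label_image, mode="thick") & mask
    yy, xx = np.nonzero(bounds)
    ax.plot(xx, yy, ".", color="yellow", markersize=0.3)
    ax.plot(line.points[:, 0], line.points[:, 1], "-", color="red", lw=1.2)
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full assay on every image listed in the metadata CSV.

    Individual image failures are logged and skipped (exit code 2);
    a run with no readable image at all is fatal (exit code 1).
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    meta = pd.read_csv(config.metadata_csv)
    required = {"file", "cornea_id", "population", "slide_id"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata CSV must have columns {sorted(required)}")

    tables, skipped = [], []
    log_rows = []
    for _, row in meta.iterrows():
        path = os.path.join(config.image_dir, str(row["file"]))
        t0 = time.perf_counter()
        try:
            image = read_section(path)
            table, mask, line, grid = process_section(
                image, config, metadata=row.to_dict()
            )
        except Exception as exc:  # per-image failures are not fatal
            logger.error("section %s skipped: %s", row["file"], exc)
            skipped.append({"file": str(row["file"]), "reason": str(exc)})
            continue
        tables.append(table)
        stem = os.path.splitext(os.path.basename(path))[0]
        if config.write_qc:
            qc_dir = os.path.join(config.output_dir, "qc")
            os.makedirs(qc_dir, exist_ok=True)
            write_mask(os.path.join(qc_dir, f"{stem}_mask.png"), mask)
            write_label_image(
                os.path.join(qc_dir, f"{stem}_rois.png"), grid.label_image
            )
            _qc_overlay(
                os.path.join(qc_dir, f"{stem}_overlay.png"),
                image, mask, line, grid,
            )
        log_rows.append(
            {
                "file": row["file"],
                "mask_area": grid.mask_area,
                "n_rois": grid.n_nonzero_labels,
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )

    if not tables:
        raise RuntimeError("no readable images: pipeline cannot proceed")

    brightness = pd.concat(tables, ignore_index=True)
    header = config.header()
    write_table(
        os.path.join(config.output_dir, "brightness.csv"), brightness, header
    )

    stats_table = (
        aggregate_to_cornea(brightness)
        if config.aggregate == "cornea"
        else brightness
    )

    anova = None
    pairwise = None
    rankings: Dict[str, object] = {}
    heatmaps: Dict[Tuple[str, str], object] = {}
    pops = sorted(stats_table["population"].unique())
    if len(pops) >= 2:
        anova = multiway_anova(stats_table)
        write_table(
            os.path.join(config.output_dir, "anova.csv"),
            pd.DataFrame(anova.terms, columns=["term", "F", "p"]),
            header,
        )
        battery = pairwise_population_tests(
            stats_table,
            n_permutations=config.n_permutations,
            seed=config.seed,
            alpha=config.alpha,
        )
        pairwise = battery["results"]
        rankings = battery["rankings"]
        write_table(
            os.path.join(config.output_dir, "pairwise.csv"), pairwise, header
        )
        rank_rows = [
            {"aspect": aspect, "population": pop, "rank": rank}
            for aspect, rr in rankings.items()
            for pop, rank in sorted(rr.ranks.items())
        ]
        write_table(
            os.path.join(config.output_dir, "ranking.csv"),
            pd.DataFrame(rank_rows),
            header,
        )
        write_table(
            os.path.join(config.output_dir, "population_summary.csv"),
            summarize_population(stats_table).round(2),
            header,
        )
        hpairs = config.heatmap_pairs or [(pops[-1], pops[0])]
        for pair in hpairs:
            hm = roi_heatmap(
                stats_table, tuple(pair),
                n_permutations=config.n_permutations,
                seed=config.seed, alpha=config.alpha,
                n_layers=config.n_layers, n_frames=config.n_frames,
            )
            heatmaps[tuple(pair)] = hm
            tag = f"{pair[0]}_vs_{pair[1]}"
            for aspect, mat in (("location", hm.p_location),
                                ("scatter", hm.p_scatter)):
                df = pd.DataFrame(
                    mat,
                    index=[f"layer{i+1}" for i in range(config.n_layers)],
                    columns=[f"frame{j+1}" for j in range(config.n_frames)],
                )
                write_table(
                    os.path.join(
                        config.output_dir, f"heatmap_{tag}_{aspect}.csv"
                    ),
                    df.reset_index(names="layer"),
                    header,
                )
            _render_heatmap(
                os.path.join(config.output_dir, f"heatmap_{tag}.png"),
                hm,
            )

    summary = {
        **{k: str(v) for k, v in header.items()},
        "n_sections": int(len(tables)),
        "n_skipped": int(len(skipped)),
        "sections": log_rows,
        "skipped": skipped,
    }
    with open(os.path.join(config.output_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)

    exit_code = 2 if skipped else 0
    return PipelineResult(
        brightness=brightness, anova=anova, pairwise=pairwise,
        rankings=rankings, heatmaps=heatmaps, skipped=skipped,
        exit_code=exit_code,
    )


def _render_heatmap(path, hm):
    """Render the 4x6 p-value matrices; red deepens as p decreases and
    cells below the significance level are outlined."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 3.2), dpi=100)
    for ax, (aspect, mat) in zip(
        axes, (("location", hm.p_location), ("scatter", hm.p_scatter))
    ):
        shade = 1.0 - np.nan_to_num(mat, nan=1.0)
        im = ax.imshow(shade, cmap="Reds", vmin=0, vmax=1)
        for (r, c), p in np.ndenumerate(mat):
            txt = "n/a" if not np.isfinite(p) else f"{p:.3f}"
            ax.text(c, r, txt, ha="center", va="center", fontsize=7)
            if np.isfinite(p) and p <= hm.alpha:
                ax.add_patch(
                    plt.Rectangle((c - 0.5, r - 0.5), 1, 1, fill=False,
                                  edgecolor="black", lw=1.5)
                )
        ax.set_title(f"{hm.pair[0]} vs {hm.pair[1]} — {aspect}")
        ax.set_xticks(range(mat.shape[1]),
                      [f"F{j+1}" for j in range(mat.shape[1])])
        ax.set_yticks(range(mat.shape[0]),
                      [f"L{i+1}" for i in range(mat.shape[0])])
        fig.colorbar(im, ax=ax, label=f"1 − p (α = {hm.alpha})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
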