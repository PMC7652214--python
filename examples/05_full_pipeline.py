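"""End-to-end run: images + metadata in, reproducible bundle out.

Writes a small cohort to disk as PNGs with a metadata CSV, then runs the
whole pipeline (segmentation, centerline, grid, brightness, statistics,
heat maps, QC overlays) into an output directory, exactly as the
`corneaquant run` command does.
"""

import tempfile
from pathlib import Path

from corneaquant import (
    CohortSpec,
    PipelineConfig,
    ProtocolParams,
    generate_cohort,
    run_pipeline,
    uv_fluence,
)
from corneaquant.synthetic import write_cohort

workdir = Path(tempfile.mkdtemp(prefix="corneaquant_demo_"))
sections = generate_cohort(CohortSpec(n_per_group=2, slides_per_cornea=2,
                                      seed=5))
write_cohort(sections, workdir / "images")
print(f"wrote {len(sections)} sections to {workdir / 'images'}")

cfg = PipelineConfig(
    image_dir=str(workdir / "images"),
    metadata_csv=str(workdir / "images" / "metadata.csv"),
    output_dir=str(workdir / "results"),
    n_permutations=999,
    seed=5,
)
result = run_pipeline(cfg)
print(f"exit code {result.exit_code}; "
      f"{len(result.brightness)} brightness records "
      f"({len(result.skipped)} skipped)")
print("outputs:", sorted(p.name for p in (workdir / "results").iterdir()))
for aspect, ranking in result.rankings.items():
    print(f"{aspect} ranking: {ranking.ranks}")

fluence = uv_fluence(ProtocolParams(irradiance_mw_cm2=30.0, exposure_min=3.0))
print(f"\nphototherapy protocol check: 30 mW/cm2 x 3 min = "
      f"{fluence} J/cm2 UV-A dose")
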