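"""Subdivide a section into 4 layers x 6 frames and measure brightness.

Each tissue pixel is assigned to a depth layer (anterior to posterior)
and a radial frame (along the band); the per-ROI mean green intensity
b_ij is the damage proxy: bright unstained gaps raise it, compact
stained stroma lowers it.
"""

from corneaquant import (
    PipelineConfig,
    SynthParams,
    generate_section,
    process_section,
)

section = generate_section(SynthParams(seed=1))
cfg = PipelineConfig()
table, mask, line, grid = process_section(
    section.image, cfg, metadata={"cornea_id": "C001",
                                  "population": "healthy",
                                  "slide_id": "S1",
                                  "anterior_side": "left"})

print(f"{grid.n_nonzero_labels} ROIs; areas sum to mask area: "
      f"{sum(grid.areas.values())} == {grid.mask_area}")

print("\nper-ROI brightness (rows = depth layers, cols = radial frames):")
pivot = table.pivot(index="layer", columns="frame", values="brightness")
print(pivot.round(1).to_string())

layer_means = table.groupby("layer").brightness.mean()
print("\nlayer means:", ", ".join(f"L{i}={v:.1f}"
                                  for i, v in layer_means.items()))
print("the central layers (2-3) are brighter than the outer ones "
      "(1, 4), the generator's built-in stromal structure.")
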