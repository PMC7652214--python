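"""Generate synthetic H&E-like cornea sections with known ground truth.

Builds one section and a small three-population cohort, and prints the
tissue statistics that the generator controls: mean green brightness per
population (injured elevated by ~5 grey levels, treated healthy-like)
and the exact mask/centerline geometry every downstream stage is tested
against.
"""

import numpy as np

from corneaquant import (
    SynthParams,
    default_cohort_spec,
    extract_green,
    generate_cohort,
    generate_section,
)

section = generate_section(SynthParams(seed=1))
green = extract_green(section.image)
print(f"one section: image {section.image.shape}, "
      f"tissue pixels {int(section.mask.sum())}, "
      f"centerline length {section.centerline.total_length:.1f} px")
print(f"mean tissue brightness {green[section.mask].mean():.2f} "
      f"(grey levels; higher = more damage)")

cohort = generate_cohort(default_cohort_spec(n_per_group=3, seed=1))
print(f"\ncohort: {len(cohort)} sections "
      f"(3 corneas x 4 slides x 3 populations)")
means = {}
for sec in cohort:
    g = extract_green(sec.image)
    means.setdefault(sec.metadata["population"], []).append(g[sec.mask].mean())
for pop, vals in sorted(means.items()):
    print(f"  {pop:8s} mean brightness {np.mean(vals):7.2f} "
          f"(between-section SD {np.std(vals, ddof=1):.2f})")
print("\ninjured sections are brighter (more fissures + diffuse stain "
      "loss); treated match healthy in mean but vary more.")
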