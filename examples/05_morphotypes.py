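"""Classify morphotypes on the body-composition chart.

Within each weight band the BFMI and FFMI axes are cut at the band's own
mean +/- 1 SD, giving nine cells; the four corners (adipo-slender,
adipo-solid, lean-slender, lean-solid) are the extreme morphotypes that a
pure weight criterion hides.
"""

from collections import Counter

from weightgrade import (
    default_scheme,
    extreme_counts,
    generate,
    grid_thresholds,
    label_cohort,
)
from weightgrade.composition import profile_cohort
from weightgrade.hattori import classify_group
from weightgrade.simulate import default_spec

scheme = default_scheme()
df = label_cohort(profile_cohort(generate(default_spec(seed=1))), scheme)

for w_label in scheme.weight_labels:
    grp = df[df.weight_cat == w_label]
    grid = grid_thresholds(grp.bfmi, grp.ffmi, group=w_label)
    labels = classify_group(grp.bfmi, grp.ffmi, grid)
    counts, share = extreme_counts(labels)
    print(f"\n{w_label} (n={len(grp)})")
    print(f"  BFMI thresholds: lean < {grid.bfmi_low:.1f} < intermediate"
          f" < {grid.bfmi_high:.1f} < adipose  kg/m^2")
    print(f"  FFMI thresholds: slender < {grid.ffmi_low:.1f} < intermediate"
          f" < {grid.ffmi_high:.1f} < solid  kg/m^2")
    common = Counter(labels).most_common(3)
    print(f"  most common cells: {common}")
    print(f"  extremes {counts}  share {share:.1f}%")
# Roughly a tenth of each band sits in an extreme corner: same weight,
# very different build.
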