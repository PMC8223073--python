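"""Build weight-category bands from within-age-group weight quartiles.

The weight model takes the 25th and 75th weight percentiles of each age
group and harmonizes them into contiguous bands. The shipped preset uses
the reference boundaries {30, 45, 60, 80} kg; the rule-based mode derives
boundaries from a new cohort's own quartiles (outer limits from the
youngest P25 / oldest P75, interior boundaries from grid-rounded midpoints).
"""

from weightgrade import default_scheme, generate, harmonize_cutpoints, weight_percentiles
from weightgrade.composition import profile_cohort
from weightgrade.simulate import default_spec

preset = default_scheme()
print("shipped preset bands:")
for label, lo, hi in preset.weight_bands:
    print(f"  {label:10s} [{lo:5.1f}, {hi:5.1f}) kg")

# derive bands from a synthetic cohort's own quartiles instead
df = profile_cohort(generate(default_spec(seed=4)))
groups = {
    label: df.loc[(df.decimal_age >= lo) & (df.decimal_age < hi), "weight_kg"].to_numpy()
    for label, lo, hi in preset.age_bands
}
quartiles = weight_percentiles(groups)
print("\nwithin-age-group weight quartiles (P25, P75) of a synthetic cohort:")
for label, (p25, p75) in quartiles.items():
    print(f"  {label}: ({p25:.1f}, {p75:.1f}) kg")

derived = harmonize_cutpoints(quartiles, grid_kg=5.0)
print("\nrule-derived bands (midpoints rounded to the 5 kg grid):")
for label, lo, hi in derived.weight_bands:
    print(f"  {label:10s} [{lo:5.1f}, {hi:5.1f}) kg")
# Players lighter than the first band or heavier than the last are excluded
# from the weight model rather than stretched into a band.
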