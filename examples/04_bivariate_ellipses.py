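"""Compare the (BFMI, FFMI) scatter of paired age and weight groups.

Each group is summarised by its centroid and 95% bivariate-normal ellipse;
Wilks' lambda tests the centroid difference and Box's M the difference in
scatter shape. Weight bands flatten the ellipse: restricting weight removes
most of the shared size variation, so BFMI and FFMI decorrelate.
"""

from weightgrade import compare_models, default_scheme, generate, label_cohort
from weightgrade.composition import profile_cohort
from weightgrade.simulate import default_spec

scheme = default_scheme()
df = label_cohort(profile_cohort(generate(default_spec(seed=1))), scheme)

for age_label, w_label in zip(scheme.age_labels, scheme.weight_labels):
    a = df.loc[df.age_cat == age_label, ["bfmi", "ffmi"]].to_numpy()
    w = df.loc[df.weight_cat == w_label, ["bfmi", "ffmi"]].to_numpy()
    comp = compare_models(a, w)
    print(f"\n{age_label} vs {w_label}")
    print(f"  centroids (BFMI, FFMI): age ({comp.centroid_a[0]:.2f}, {comp.centroid_a[1]:.2f})"
          f"  weight ({comp.centroid_b[0]:.2f}, {comp.centroid_b[1]:.2f})")
    print(f"  Wilks lambda {comp.wilks.extra['lambda']:.4f}  F {comp.wilks.statistic:.2f}"
          f"  p {comp.wilks.p_value:.2g}")
    print(f"  Box M {comp.box.extra['M']:.2f}  F {comp.box.statistic:.2f}"
          f"  p {comp.box.p_value:.2g}")
    print(f"  r(BFMI, FFMI): age {comp.pearson_a.statistic:.2f}"
          f"  weight {comp.pearson_b.statistic:.2f}")
    print(f"  note: {comp.caveat}")
# Small lambda deficits (0.94-0.99) with tiny p-values mirror large-sample
# centroid shifts; the drop in r is the ellipse "flattening".
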