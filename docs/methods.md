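# Methods

## Scope and model

The package compares two ways of grouping schoolboy rugby players —
two-year chronological age bands versus body-mass bands — on a cohort of
per-player anthropometry (decimal age, height, weight, replicate skinfolds
at biceps/triceps/subscapular/suprailiac). Its chain is:

1. skinfold aggregation and two-compartment body composition;
2. BMI-status classification (NW/OW/OB) against an age-indexed cut-off table;
3. construction of the weight-band scheme and dual labelling;
4. univariate dispersion/mean comparisons per paired group;
5. bivariate (BFMI, FFMI) centroid/shape comparisons;
6. morphotype classification on the body-composition chart.

## Body composition

Site values are the arithmetic mean of the 3 (or 5) replicate caliper
readings. When exactly three replicates span more than **0.2 mm** the field
protocol requires two further readings; the package raises a warning rather
than an error or any re-imputation, because software cannot retroactively
measure. Body density uses the schoolboy regression
`BD = 1.1533 − 0.0643·log10(S)` with S the four-site sum in mm. The
logarithm is base 10: the original regression was fitted on log10, and a
natural-log reading produces physiologically impossible densities for
ordinary sums. Percent fat follows Siri, `%BF = (4.95/BD − 4.5)·100`,
flagged (not clipped) outside [0, 75]%. Fat and fat-free mass divided by
squared height give BFMI and FFMI with the exact identities
`BMI = BFMI + FFMI`, `FM + FFM = weight`, `%BF = 100·BFMI/(BFMI+FFMI)`,
which the test suite enforces to 1e-9. The same density constants are
applied uniformly over the 9–15 y range; no age-specific recalibration is
attempted.

## Weight status

Cut-offs are tabulated per half-year of age for one sex (boys) and linearly
interpolated at the player's exact decimal age (a nearest-half-year mode
exists for protocols that record age that way). A BMI exactly on a cut-off
takes the heavier class. The packaged grid is a **synthetic reconstruction**
of the published IOTF-style boys' table, shipped only so the pipeline runs
end-to-end; analyses of real cohorts should substitute an authoritative
file, and no test asserts the shipped values.

## Grading schemes

Age bands default to U11 [9, 11), U13 [11, 13), U15 [13, 15) years
(half-open). Weight bands are stored half-open `[lower, upper)` and
displayed with the conventional `upper − 0.1` label (W30–44.9 ≙ [30, 45)),
so no weight can fall between bands. Quartiles use linear interpolation of
order statistics (`numpy` "linear"/type-7), recorded in run metadata because
percentile conventions differ by more than a kilogram in the tails at
n ≈ 250.

Two harmonization modes exist because the published boundaries cannot be
derived mechanically from the published quartiles: the **manual preset**
{30, 45, 60, 80} kg (the default, matching the reference scheme) and a
**midpoint-grid rule** for new cohorts — outer limits from the youngest
group's P25 and the oldest group's P75, interior boundaries from the
midpoint of adjacent P75/P25 pairs, all rounded half-up to a 5 kg grid. On
the reference quartiles the rule yields a 40 kg (not 45 kg) interior
boundary, which is exactly why it is configurable rather than silently
applied. Harmonization refuses cohorts whose interquartile midpoints do not
increase with age. Players outside the outer limits are excluded from the
weight model and tracked explicitly.

Movement tables count every player into (weight band × age group) with
exclusion rows. Percentages are reported under **two denominators**: per
weight band (each band's row sums to 100; the convention of the reference
distribution table) and per age group (including exclusions). A player's
*home* band is the weight band at his age band's ordinal position; movement
is up/down/retained relative to it, with exclusion above/below counting as
up/down. Empty (age × status) strata are omitted, not reported as 0/0.

## Univariate statistics

Dispersion is CV = SD/mean × 100 with the sample (n−1) SD throughout. The
CV-equality test is **Forkman's approximate F** (ratio of shrunken squared
CV estimates referred to F(n₁−1, n₂−1), two-sided): the choice among
published "approximate F tests" is not determinable from the reference
text, so the test name is recorded in metadata and its type-I error is
verified by simulation (2,000 null replicates, n = 100 per group, rejection
rate within [0.035, 0.065] at α = 0.05). Mean comparisons use one-way ANOVA
with Fisher's LSD (unadjusted pairwise t on the pooled MSE, as LSD
prescribes — no multiplicity correction is added). Cohen's d uses the
pooled SD with the age group as reference, so positive d means the weight
band is higher.

## Bivariate statistics

The 95% normal ellipse is centred at the sample mean with axes along the
sample-covariance eigenvectors and semi-axes √(λᵢ·q), q = χ²₂(0.95) ≈ 5.99;
Monte-Carlo coverage is verified to [0.948, 0.952] at 10⁵ points. Two-group
Wilks' Λ = det(W)/det(T) is converted with the exact two-group/two-variable
transform F = ((N−3)/2)(1−Λ)/Λ on (2, N−3) df — exact for this design and
testable against Hotelling's T² (Λ = 1/(1+T²/(N−2))), which the suite
checks to 1e-10. Box's M uses the F approximation (not χ²), matching the
style of the reference report; the variant is named in metadata. The paired
groups **share members** (a U11 boy is usually also in W30–44.9); the tests
are nevertheless computed as if independent because that is the practice
being replicated, and every bivariate report carries an explicit
anti-conservativeness caveat.

## Morphotypes and chart geometry

Within each group of the active grading model, BFMI and FFMI are cut at the
group's own mean ± 1 sample SD (recomputed from members by default; a
pinned-from-printed-moments mode exists). Values exactly on a threshold are
*intermediate* — the strict below/above reading — and ties are documented
because they move a handful of players at 1-decimal data. Nine cells
partition the plane; adipose×slender, adipose×solid, lean×slender and
lean×solid collapse to the four extreme labels. Chart guides: iso-BMI lines
x + y = BMI and iso-%BF rays y = x(100−p)/p (BFMI horizontal, FFMI
vertical), clipped by Liang–Barsky to the plotting window.

## Synthetic cohort generator

Per age block: age ~ truncated normal inside the band; height linear in age
plus a normal residual; log weight linear in age and in the height residual
plus N(0, σ_w) plus, with probability 0.12, a right-tail shift
(δ + |N(0, δ/2)|, δ ≈ 0.25) that creates the overweight/obese fraction; the
log10 skinfold sum is `a + k·e + N(0, σ_s)` where e is the
log-weight-for-height residual — heavier-for-height boys are fatter. That
single coupling produces the three signature phenomena: positive BFMI–FFMI
correlation inside age groups, its collapse inside weight bands, and
status-dependent upgrading. Replicates are small normal perturbations
(SD 0.04 mm) of each site mean, keeping within-site spread under the 0.2 mm
protocol trigger. Heights/weights are rounded to 0.1 (instrument
resolution), ages to 4 decimals, skinfolds to 0.01 mm. One `numpy`
Generator stream per cohort; the seed lands in cohort metadata and CSV
exports are byte-identical per (spec, seed).

The default calibration was fitted by moment matching (linearized moment
equations plus simulation polish at n = 30,000/group) against published
schoolboy-rugby group summaries: weight, height, BMI, BFMI, FFMI means and
SDs per age group. Means land within ~1% and SDs within ~5%; the printed
(rounded) SD triple of one group is mutually inconsistent with its printed
BFMI–FFMI correlation, so where forced the calibration keeps SDs inside 5%
and the correlation inside 0.6–0.85. What the generator does **not**
emulate: measurement error correlated across sites, maturation offset,
seasonal drift, club-level clustering, and any longitudinal structure —
so passing pipeline tests demonstrates the machinery and the modelled joint
structure, not field data quality.

## Numerical and reporting choices

Percentile method, CV test, Box variant, boundary rule, tie conventions and
the seed are all written to `run_metadata.json`; bundles contain no
timestamps and are byte-identical across reruns. Table/figure CSVs are
rounded to 6 decimals to keep bytes stable across BLAS variations. Printed
percentages in the replay module are compared after round-half-up to the
printed decimals; recomputed Cohen's d is compared at ±0.03 because the
reference values were computed on unrounded data. Degenerate inputs
(constant vectors, singular covariances, <3 replicates, ages outside the
cut-off span) raise typed errors rather than propagating NaNs.

## Problem sizes used in tests

Unit tests run on toy vectors and 400-per-group synthetic cohorts; the
calibration and qualitative-reproduction checks use 5,000 per group with a
fixed seed; parameter recovery uses 20,000 for one group; ellipse coverage
uses 10⁵ points. These sizes give Monte-Carlo noise comfortably below the
asserted tolerances.

## Known limitations

* The two-compartment density equations are applied from age 9 although
  validated in adolescents; derived %BF is best treated comparatively.
* The shipped status grid is synthetic (see above).
* Bivariate p-values ignore the group-overlap dependence (flagged in every
  report).
* The weight model's exclusion counts depend on the preset outer limits;
  with rule-derived boundaries they are cohort-specific.
* No maturation, skill or hybrid banding models are implemented.
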