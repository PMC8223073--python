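"""Grading schemes: age bands, percentiles, harmonization, weight-band
assignment, and movement tables."""

import numpy as np
import pandas as pd
import pytest

from weightgrade.errors import AssignmentError, DomainError, HarmonizationError
from weightgrade.grading import (
    DEFAULT_AGE_BANDS,
    EXCLUDED_ABOVE,
    EXCLUDED_BELOW,
    REFERENCE_PERCENTILES,
    GradingScheme,
    assign_age_category,
    assign_weight_category,
    default_scheme,
    harmonize_cutpoints,
    movement_by_status,
    movement_crosstab,
    scheme_from_boundaries,
    weight_percentiles,
)


class TestAgeAssignment:
    @pytest.mark.parametrize("age, label", [(9.8, "U11"), (11.0, "U13"), (12.99, "U13")])
    def test_half_open_bands(self, age, label):
        assert assign_age_category(age, DEFAULT_AGE_BANDS) == label

    def test_out_of_band_age_rejected(self):
        with pytest.raises(AssignmentError):
            assign_age_category(15.0, DEFAULT_AGE_BANDS)


class TestPercentiles:
    def test_order_statistic_interpolation(self):
        pct = weight_percentiles({"g": [1, 2, 3, 4, 5]})
        assert pct["g"][0] == pytest.approx(2.0)
        pct = weight_percentiles({"g": [1, 2, 3, 4]})
        assert pct["g"][1] == pytest.approx(3.25)

    def test_degenerate_constant_group(self):
        pct = weight_percentiles({"g": [40.0] * 10})
        assert pct["g"] == (40.0, 40.0)

    def test_small_group_rejected(self):
        with pytest.raises(DomainError):
            weight_percentiles({"g": [1, 2, 3]})


class TestHarmonization:
    def test_midpoint_grid_rule(self):
        scheme = harmonize_cutpoints({"A": (20.0, 30.0), "B": (30.0, 40.0)}, grid_kg=5)
        assert [(b[1], b[2]) for b in scheme.weight_bands] == [(20.0, 30.0), (30.0, 40.0)]

    def test_rule_applied_to_reference_percentiles(self):
        # midpoint of (44.1, 39.7) is 41.9 -> grid 40; the rule does NOT
        # reproduce the shipped manual preset boundary 45, which is why the
        # preset exists
        scheme = harmonize_cutpoints(REFERENCE_PERCENTILES, grid_kg=5)
        bounds = [scheme.weight_bands[0][1]] + [b[2] for b in scheme.weight_bands]
        assert bounds == [30.0, 40.0, 60.0, 80.0]

    def test_identical_adjacent_groups_collapse(self):
        with pytest.raises(HarmonizationError):
            harmonize_cutpoints({"A": (30.0, 40.0), "B": (30.0, 40.0)}, grid_kg=5)

    def test_idempotence_on_harmonized_boundaries(self):
        scheme = default_scheme()
        edges = {
            label: (lo, hi) for label, lo, hi in scheme.weight_bands
        }
        again = harmonize_cutpoints(edges, grid_kg=5)
        assert [b[1:] for b in again.weight_bands] == [b[1:] for b in scheme.weight_bands]

    def test_default_preset_bands_and_labels(self):
        scheme = default_scheme()
        assert scheme.weight_labels == ["W30-44.9", "W45-59.9", "W60-79.9"]
        assert scheme.exclusion == (30.0, 80.0)

    def test_scheme_requires_contiguous_bands(self):
        with pytest.raises(Exception):
            GradingScheme(
                age_bands=DEFAULT_AGE_BANDS,
                weight_bands=(("a", 30.0, 45.0), ("b", 50.0, 60.0)),
            )

    def test_yaml_round_trip(self, tmp_path):
        scheme = default_scheme()
        path = tmp_path / "scheme.yaml"
        scheme.to_yaml(path)
        back = GradingScheme.from_yaml(path)
        assert back.weight_bands == scheme.weight_bands
        assert back.age_bands == scheme.age_bands
        assert back.boundary_rule == scheme.boundary_rule


class TestWeightAssignment:
    @pytest.mark.parametrize(
        "weight, label",
        [
            (45.0, "W45-59.9"),
            (44.95, "W30-44.9"),
            (29.0, EXCLUDED_BELOW),
            (80.0, EXCLUDED_ABOVE),
            (30.0, "W30-44.9"),
        ],
    )
    def test_half_open_band_assignment(self, weight, label):
        assert assign_weight_category(weight, default_scheme()) == label

    def test_partition_over_random_weights(self, rng):
        scheme = default_scheme()
        weights = rng.uniform(15, 120, size=2000)
        labels = [assign_weight_category(w, scheme) for w in weights]
        valid = set(scheme.weight_labels) | {EXCLUDED_BELOW, EXCLUDED_ABOVE}
        assert set(labels) <= valid
        # half-open cover: every weight lands somewhere
        assert len(labels) == 2000


def _toy_labeled(rows):
    return pd.DataFrame(rows, columns=["age_cat", "weight_cat", "status"])


class TestMovement:
    def test_six_player_toy_crosstab(self):
        scheme = default_scheme()
        rows = [
            ("U11", "W30-44.9", "NW"), ("U11", "W45-59.9", "OW"),
            ("U13", "W45-59.9", "NW"), ("U13", "W30-44.9", "NW"),
            ("U15", "W60-79.9", "NW"), ("U15", "W45-59.9", "NW"),
        ]
        mt = movement_crosstab(_toy_labeled(rows), scheme)
        assert np.trace(mt.counts.loc[scheme.weight_labels].to_numpy()) == 3
        assert mt.counts.to_numpy().sum() == 6
        # each age column (with exclusions) sums to that age group's n
        assert mt.counts.sum(axis=0).tolist() == [2, 2, 2]

    def test_all_home_cohort_has_full_retention(self):
        scheme = default_scheme()
        rows = [("U11", "W30-44.9", "NW")] * 4 + [("U13", "W45-59.9", "NW")] * 3 + [
            ("U15", "W60-79.9", "NW")
        ] * 5
        mt = movement_crosstab(_toy_labeled(rows), scheme)
        diag = np.diag(mt.pct_weight_denominator.to_numpy())
        assert np.allclose(diag, 100.0)

    def test_reference_counts_reproduce_reference_percentages(self):
        # replaying the published distribution counts through the
        # weight-band-denominator convention gives the published percentages
        counts = pd.DataFrame(
            [[161, 106, 1], [47, 108, 39], [7, 30, 130]],
            index=["W30-44.9", "W45-59.9", "W60-79.9"],
            columns=["U11", "U13", "U15"],
        )
        from weightgrade.grading import movement_percentages

        pct = movement_percentages(counts)
        assert round(pct.loc["W30-44.9", "U11"]) == 60
        assert pct.loc["W45-59.9", "U13"] == pytest.approx(55.7, abs=0.05)
        assert pct.loc["W60-79.9", "U15"] == pytest.approx(77.8, abs=0.05)

    def test_status_stratified_toy_counts(self):
        scheme = default_scheme()
        rows = [
            ("U11", "W45-59.9", "OB"), ("U11", "W60-79.9", "OB"),
            ("U11", EXCLUDED_ABOVE, "OB"), ("U11", "W30-44.9", "OB"),
        ]
        out = movement_by_status(_toy_labeled(rows), scheme)
        row = out[(out.age_cat == "U11") & (out.status == "OB")].iloc[0]
        assert row.pct_up == pytest.approx(75.0)
        assert row.pct_down == pytest.approx(0.0)
        assert row.pct_retained == pytest.approx(25.0)

    def test_fully_retained_stratum(self):
        scheme = default_scheme()
        rows = [("U13", "W45-59.9", "NW")] * 5
        out = movement_by_status(_toy_labeled(rows), scheme)
        row = out.iloc[0]
        assert (row.pct_up, row.pct_down, row.pct_retained) == (0.0, 0.0, 100.0)

    def test_empty_strata_absent(self):
        scheme = default_scheme()
        out = movement_by_status(_toy_labeled([("U11", "W30-44.9", "NW")]), scheme)
        assert len(out) == 1  # no 0/0 rows for missing (group, status) pairs

    def test_percentages_sum_to_100_within_strata(self, rng):
        scheme = default_scheme()
        cats = scheme.weight_labels + [EXCLUDED_BELOW, EXCLUDED_ABOVE]
        rows = [
            (rng.choice(["U11", "U13", "U15"]), rng.choice(cats), rng.choice(["NW", "OW", "OB"]))
            for _ in range(300)
        ]
        out = movement_by_status(_toy_labeled(rows), scheme)
        assert np.allclose(out.pct_up + out.pct_down + out.pct_retained, 100.0)


class TestDispersionProperty:
    def test_weight_cv_smaller_within_bands_than_within_ages(self, small_profile):
        from weightgrade.grading import label_cohort

        scheme = default_scheme()
        df = label_cohort(small_profile, scheme)
        cv = lambda x: x.std(ddof=1) / x.mean() * 100
        for age_label, w_label in zip(scheme.age_labels, scheme.weight_labels):
            cv_age = cv(df.loc[df.age_cat == age_label, "weight_kg"])
            cv_w = cv(df.loc[df.weight_cat == w_label, "weight_kg"])
            assert cv_w < cv_age


class TestBoundariesApi:
    def test_non_increasing_boundaries_rejected(self):
        with pytest.raises(HarmonizationError):
            scheme_from_boundaries([30, 30, 60])
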