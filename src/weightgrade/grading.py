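"""Age-based and body-mass-based grading schemes and movement between them.

The age model groups players into two-year bands (U11, U13, U15 by
default). The weight model is built from the 25th and 75th weight
percentiles of each age group, harmonized into contiguous, non-overlapping
bands; players below the first band or above the last are excluded from
the weight model. Bands are stored half-open [lower, upper) and displayed
with the conventional "upper - 0.1 kg" label (W30-44.9 for [30, 45)).

Two harmonization rules are available:

* ``manual`` — boundaries supplied directly; the shipped default preset is
  the {30, 45, 60, 80} kg scheme used for schoolboy rugby cohorts.
* ``midpoint_grid`` — outer limits are the youngest group's P25 and the
  oldest group's P75, interior boundaries the midpoints of adjacent P75/P25
  pairs, everything rounded to the nearest multiple of a kg grid step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import AssignmentError, DomainError, HarmonizationError, ValidationError

EXCLUDED_BELOW = "excluded_below"
EXCLUDED_ABOVE = "excluded_above"

#: Default two-year age bands, [min, max) in decimal years.
DEFAULT_AGE_BANDS = (("U11", 9.0, 11.0), ("U13", 11.0, 13.0), ("U15", 13.0, 15.0))

#: Within-age-group (P25, P75) weight percentiles of the reference schoolboy
#: rugby cohort, the provenance of the shipped manual preset.
REFERENCE_PERCENTILES = {"U11": (32.4, 44.1), "U13": (39.7, 54.9), "U15": (61.0, 79.9)}

#: Harmonized band boundaries of the shipped manual preset, kg.
REFERENCE_BOUNDARIES = (30.0, 45.0, 60.0, 80.0)


def band_label(lower: float, upper: float) -> str:
    """Display label for a half-open [lower, upper) kg band, e.g. W30-44.9."""
    return f"W{lower:g}-{upper - 0.1:g}"


@dataclass(frozen=True)
class GradingScheme:
    """Age bands plus harmonized weight bands with global exclusion limits."""

    age_bands: tuple  # (label, min_age_inclusive, max_age_exclusive)
    weight_bands: tuple  # (label, lower_kg_inclusive, upper_kg_exclusive)
    boundary_rule: str = "manual"
    grid_kg: float = 5.0
    percentile_method: str = "linear"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        bands = tuple(self.weight_bands)
        if not bands:
            raise ValidationError("scheme needs at least one weight band")
        for label, lo, hi in bands:
            if not lo < hi:
                raise ValidationError(f"band {label}: lower {lo} must be < upper {hi}")
        for (_, _, hi_prev), (lab, lo, _) in zip(bands, bands[1:]):
            if lo != hi_prev:
                raise ValidationError(f"bands must be contiguous; gap/overlap before {lab}")

    @property
    def exclusion(self) -> tuple[float, float]:
        return self.weight_bands[0][1], self.weight_bands[-1][2]

    @property
    def weight_labels(self) -> list[str]:
        return [b[0] for b in self.weight_bands]

    @property
    def age_labels(self) -> list[str]:
        return [b[0] for b in self.age_bands]

    def home_band(self, age_label: str) -> str:
        """Weight band matching an age band's ordinal position."""
        idx = self.age_labels.index(age_label)
        if idx >= len(self.weight_bands):
            raise AssignmentError(f"no weight band at ordinal position of {age_label}")
        return self.weight_bands[idx][0]

    def to_yaml(self, path) -> None:
        doc = {
            "age_bands": [list(b) for b in self.age_bands],
            "weight_bands": [list(b) for b in self.weight_bands],
            "boundary_rule": self.boundary_rule,
            "grid_kg": self.grid_kg,
            "percentile_method": self.percentile_method,
            "provenance": {k: list(v) if isinstance(v, tuple) else v for k, v in self.provenance.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GradingScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            age_bands=tuple(tuple(b) for b in doc["age_bands"]),
            weight_bands=tuple(tuple(b) for b in doc["weight_bands"]),
            boundary_rule=doc.get("boundary_rule", "manual"),
            grid_kg=doc.get("grid_kg", 5.0),
            percentile_method=doc.get("percentile_method", "linear"),
            provenance=doc.get("provenance", {}),
        )


def scheme_from_boundaries(
    boundaries,
    age_bands=DEFAULT_AGE_BANDS,
    boundary_rule: str = "manual",
    provenance: dict | None = None,
) -> GradingScheme:
    """Build a scheme from an increasing sequence of band boundaries in kg."""
    bounds = [float(b) for b in boundaries]
    if len(bounds) < 2 or any(b >= c for b, c in zip(bounds, bounds[1:])):
        raise HarmonizationError(f"boundaries must be strictly increasing, got {bounds}")
    bands = tuple(
        (band_label(lo, hi), lo, hi) for lo, hi in zip(bounds, bounds[1:])
    )
    return GradingScheme(
        age_bands=tuple(age_bands),
        weight_bands=bands,
        boundary_rule=boundary_rule,
        provenance=provenance or {},
    )


def default_scheme() -> GradingScheme:
    """The shipped manual preset: bands W30-44.9, W45-59.9, W60-79.9."""
    return scheme_from_boundaries(
        REFERENCE_BOUNDARIES,
        boundary_rule="manual",
        provenance={"percentiles": dict(REFERENCE_PERCENTILES)},
    )


def assign_age_category(decimal_age: float, bands=DEFAULT_AGE_BANDS) -> str:
    """The unique age band with min <= age < max (half-open convention)."""
    for label, lo, hi in bands:
        if lo <= decimal_age < hi:
            return label
    raise AssignmentError(f"age {decimal_age} outside all age bands {[b[0] for b in bands]}")


def weight_percentiles(groups: dict, q=(25.0, 75.0)) -> dict:
    """Per-group weight percentiles by linear interpolation of order statistics
    (the 'type 7' convention, h = (n-1) q/100 + 1)."""
    out = {}
    for label, weights in groups.items():
        w = np.asarray(weights, dtype=float)
        if w.size < 4:
            raise DomainError(f"group {label!r} too small for quartiles (n={w.size})")
        lo, hi = (float(np.percentile(w, qq, method="linear")) for qq in q)
        out[label] = (lo, hi)
    return out


def _round_to_grid(x: float, grid: float) -> float:
    # round-half-up on the grid, so e.g. 57.95 with grid 5 -> 60
    return float(np.floor(x / grid + 0.5) * grid)


def harmonize_cutpoints(
    percentiles: dict,
    grid_kg: float = 5.0,
    age_bands=DEFAULT_AGE_BANDS,
) -> GradingScheme:
    """Harmonize per-age-group (P25, P75) weight percentiles into contiguous bands.

    Outer limits are the youngest group's P25 and the oldest group's P75;
    each interior boundary is the midpoint of adjacent groups' P75 and P25;
    all are rounded to the nearest grid multiple. Groups must be passed in
    age order (insertion order of the dict).
    """
    labels = list(percentiles)
    if len(labels) < 2:
        raise HarmonizationError("need at least two age groups to harmonize")
    p25 = [percentiles[g][0] for g in labels]
    p75 = [percentiles[g][1] for g in labels]
    mids = [(lo + hi) / 2.0 for lo, hi in zip(p25, p75)]
    if any(m2 <= m1 for m1, m2 in zip(mids, mids[1:])):
        raise HarmonizationError(
            f"group interquartile midpoints do not increase with age ({mids}); "
            "supply manual boundaries instead"
        )
    bounds = [_round_to_grid(p25[0], grid_kg)]
    for g in range(len(labels) - 1):
        bounds.append(_round_to_grid((p75[g] + p25[g + 1]) / 2.0, grid_kg))
    bounds.append(_round_to_grid(p75[-1], grid_kg))
    if any(b >= c for b, c in zip(bounds, bounds[1:])):
        raise HarmonizationError(
            f"harmonized boundaries not strictly increasing: {bounds}; "
            "supply manual boundaries instead"
        )
    return scheme_from_boundaries(
        bounds,
        age_bands=age_bands,
        boundary_rule="midpoint_grid",
        provenance={"percentiles": dict(percentiles), "grid_kg": grid_kg},
    )


def assign_weight_category(weight: float, scheme: GradingScheme) -> str:
    """Half-open band containing the weight, or an exclusion marker."""
    lo_all, hi_all = scheme.exclusion
    if weight < lo_all:
        return EXCLUDED_BELOW
    if weight >= hi_all:
        return EXCLUDED_ABOVE
    for label, lo, hi in scheme.weight_bands:
        if lo <= weight < hi:
            return label
    raise AssignmentError(f"weight {weight} fell through contiguous bands")  # pragma: no cover


@dataclass(frozen=True)
class MovementTable:
    """Cross-tabulation of age categories into weight categories.

    ``counts`` has one row per weight band plus the two exclusion rows, one
    column per age band. ``pct_weight_denominator`` divides each in-band cell
    by its weight band's total n (the convention of the reference study's
    distribution table); ``pct_age_denominator`` divides every cell, including
    exclusions, by its age group's n.
    """

    counts: pd.DataFrame
    pct_weight_denominator: pd.DataFrame
    pct_age_denominator: pd.DataFrame


def movement_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Percentages with weight-band denominators: cell / its row total x 100.

    ``counts`` has weight bands as rows and age groups as columns; exclusion
    rows, if present, are dropped from this view (they have no weight-band n).
    """
    in_band = counts.loc[[r for r in counts.index if r not in (EXCLUDED_BELOW, EXCLUDED_ABOVE)]]
    row_n = in_band.sum(axis=1)
    return in_band.div(row_n.replace(0, np.nan), axis=0) * 100.0


def movement_crosstab(df: pd.DataFrame, scheme: GradingScheme) -> MovementTable:
    """Build the movement table from a cohort labelled with age_cat and weight_cat."""
    if df["age_cat"].isna().any() or df["weight_cat"].isna().any():
        raise ValidationError("every player must carry both an age and a weight label")
    age_labels = scheme.age_labels
    w_labels = scheme.weight_labels + [EXCLUDED_BELOW, EXCLUDED_ABOVE]
    counts = (
        pd.crosstab(df["weight_cat"], df["age_cat"])
        .reindex(index=w_labels, columns=age_labels, fill_value=0)
        .astype(int)
    )
    pct_w = movement_percentages(counts)
    col_n = counts.sum(axis=0)
    pct_a = counts.div(col_n.replace(0, np.nan), axis=1) * 100.0
    return MovementTable(counts=counts, pct_weight_denominator=pct_w, pct_age_denominator=pct_a)


def _movement_direction(age_idx: int, weight_cat: str, scheme: GradingScheme) -> str:
    if weight_cat == EXCLUDED_BELOW:
        return "down"
    if weight_cat == EXCLUDED_ABOVE:
        return "up"
    w_idx = scheme.weight_labels.index(weight_cat)
    if w_idx == age_idx:
        return "retained"
    return "up" if w_idx > age_idx else "down"


def movement_by_status(df: pd.DataFrame, scheme: GradingScheme) -> pd.DataFrame:
    """Up/down/retained percentages per (age group, BMI status) stratum.

    A player's home band is the weight band at his age band's ordinal
    position; exclusion below/above counts as down/up movement. Empty strata
    are absent from the result rather than reported as 0/0.
    """
    needed = {"age_cat", "weight_cat", "status"}
    if not needed <= set(df.columns):
        raise ValidationError(f"need columns {sorted(needed)}")
    rows = []
    for age_label in scheme.age_labels:
        age_idx = scheme.age_labels.index(age_label)
        for status in ("NW", "OW", "OB"):
            stratum = df[(df["age_cat"] == age_label) & (df["status"] == status)]
            n = len(stratum)
            if n == 0:
                continue
            moves = stratum["weight_cat"].map(
                lambda w: _movement_direction(age_idx, w, scheme)
            )
            rows.append(
                {
                    "age_cat": age_label,
                    "status": status,
                    "n": n,
                    "pct_up": float((moves == "up").sum()) / n * 100.0,
                    "pct_down": float((moves == "down").sum()) / n * 100.0,
                    "pct_retained": float((moves == "retained").sum()) / n * 100.0,
                }
            )
    return pd.DataFrame(rows)


def label_cohort(df: pd.DataFrame, scheme: GradingScheme) -> pd.DataFrame:
    """Return a copy of an augmented cohort table with age_cat and weight_cat."""
    out = df.copy()
    out["age_cat"] = [assign_age_category(a, scheme.age_bands) for a in out["decimal_age"]]
    out["weight_cat"] = [assign_weight_category(w, scheme) for w in out["weight_kg"]]
    return out
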