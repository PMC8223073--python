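"""BMI weight-status classification against an age-indexed cut-off table.

Children are classed normal-weight (NW), overweight (OW) or obese (OB) by
comparing BMI to age- and sex-specific cut-off curves of the IOTF style:
curves that pass through adult BMI 25 and 30 at age 18. Cut-offs between
tabulated grid ages are linearly interpolated; a BMI exactly on a cut-off
takes the heavier class.

The packaged grid ``data/iotf_boys_synthetic.csv`` is a synthetic
reconstruction approximating the published boys' half-year cut-off table;
it is shipped so the pipeline runs out of the box, but analyses of real
cohorts should point ``load_cutoff_table`` at an authoritative copy. No
test in this package depends on the shipped values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

NW, OW, OB = "NW", "OW", "OB"
STATUS_ORDER = (NW, OW, OB)


@dataclass(frozen=True)
class CutoffTable:
    """Age grid with overweight and obesity BMI cut-offs for one sex."""

    ages: np.ndarray  # years, strictly increasing
    ow_cut: np.ndarray  # kg m^-2
    ob_cut: np.ndarray  # kg m^-2

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        ow = np.asarray(self.ow_cut, dtype=float)
        ob = np.asarray(self.ob_cut, dtype=float)
        if not (ages.size == ow.size == ob.size) or ages.size == 0:
            raise ValidationError("cut-off table columns must be equal-length and nonempty")
        if ages.size > 1 and np.any(np.diff(ages) <= 0):
            raise ValidationError("cut-off table ages must be strictly increasing")
        if np.any(ow <= 0) or np.any(ob <= 0):
            raise ValidationError("cut-offs must be positive")
        if np.any(ob <= ow):
            raise ValidationError("obesity cut-off must exceed overweight cut-off at every age")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "ow_cut", ow)
        object.__setattr__(self, "ob_cut", ob)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def cutoffs_at(self, age: float, mode: str = "exact") -> tuple[float, float]:
        """Interpolated (ow_cut, ob_cut) at a decimal age.

        mode 'exact' interpolates linearly on age; 'half_year' first snaps
        the age to the nearest half-year grid point.
        """
        lo, hi = self.span
        if not (lo <= age <= hi):
            raise DomainError(f"age {age} outside cut-off table span [{lo}, {hi}]")
        if mode == "half_year":
            age = np.clip(round(age * 2.0) / 2.0, lo, hi)
        elif mode != "exact":
            raise ValueError(f"unknown interpolation mode {mode!r}")
        return (
            float(np.interp(age, self.ages, self.ow_cut)),
            float(np.interp(age, self.ages, self.ob_cut)),
        )


def load_cutoff_table(path=None) -> CutoffTable:
    """Load a cut-off table CSV (columns age, ow_cut, ob_cut).

    With no path, loads the packaged synthetic boys' grid.
    """
    if path is None:
        src = resources.files("weightgrade.data").joinpath("iotf_boys_synthetic.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = {"age", "ow_cut", "ob_cut"} - set(df.columns)
    if missing:
        raise ValidationError(f"cut-off table missing columns: {sorted(missing)}")
    return CutoffTable(df["age"].to_numpy(), df["ow_cut"].to_numpy(), df["ob_cut"].to_numpy())


def classify_status(
    decimal_age: float, bmi: float, table: CutoffTable, mode: str = "exact"
) -> str:
    """NW / OW / OB from age and BMI; a BMI on a cut-off takes the heavier class."""
    ow, ob = table.cutoffs_at(decimal_age, mode=mode)
    if bmi >= ob:
        return OB
    if bmi >= ow:
        return OW
    return NW


def classify_cohort_status(
    df: pd.DataFrame, table: CutoffTable, mode: str = "exact"
) -> pd.Series:
    """Vector status for an augmented cohort table (decimal_age, bmi columns)."""
    return pd.Series(
        [classify_status(a, b, table, mode) for a, b in zip(df["decimal_age"], df["bmi"])],
        index=df.index,
        name="status",
    )
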