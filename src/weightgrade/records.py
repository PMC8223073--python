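"""Player records, cohorts, and delimited-file I/O.

A cohort is stored on disk in *wide* form: one row per player, with the
replicate skinfold measurements in explicit columns ``<site>_1 .. <site>_5``
(at least three per site must be filled). Units are fixed at the I/O
boundary: height in cm, weight in kg, skinfolds in mm. Ages are decimal
years; a ``decimal_age`` column is required unless both ``birth_date`` and
``test_date`` columns (ISO dates) are present, in which case the age is
computed with the 365.25-day year convention.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError, SchemaError, ValidationError

SKINFOLD_SITES = ("biceps", "triceps", "subscapular", "suprailiac")

#: Days per year used to convert a (birth date, test date) pair to decimal age.
DAYS_PER_YEAR = 365.25

#: Plausibility window for decimal age, in years.
DEFAULT_AGE_WINDOW = (6.0, 18.0)

MAX_REPLICATES = 5


@dataclass(frozen=True)
class Dialect:
    """Delimited-file dialect.

    The default is RFC-4180 CSV with a ``.`` decimal separator; European
    exports commonly use ``;`` as delimiter and ``,`` as decimal mark.
    """

    sep: str = ","
    decimal: str = "."

    @classmethod
    def european(cls) -> "Dialect":
        return cls(sep=";", decimal=",")


@dataclass
class PlayerRecord:
    """One child's raw anthropometry.

    skinfolds maps each of the four sites to the ordered list of replicate
    caliper readings in mm (3 or 5 per site under the measurement protocol).
    """

    player_id: str
    decimal_age: float
    height: float  # cm
    weight: float  # kg
    skinfolds: dict[str, list[float]]

    def validate(self, age_window: tuple[float, float] = DEFAULT_AGE_WINDOW) -> list[str]:
        """Return a list of invariant-violation messages (empty if valid)."""
        problems: list[str] = []
        if not self.player_id:
            problems.append("player_id: empty")
        if not np.isfinite(self.height) or self.height <= 0:
            problems.append(f"height: must be > 0, got {self.height}")
        if not np.isfinite(self.weight) or self.weight <= 0:
            problems.append(f"weight: must be > 0, got {self.weight}")
        lo, hi = age_window
        if not np.isfinite(self.decimal_age) or not (lo <= self.decimal_age <= hi):
            problems.append(
                f"decimal_age: {self.decimal_age} outside plausibility window [{lo}, {hi}]"
            )
        for site in SKINFOLD_SITES:
            reps = self.skinfolds.get(site)
            if reps is None or len(reps) < 3:
                problems.append(f"{site}: needs >=3 replicates")
                continue
            if any((not np.isfinite(r)) or r <= 0 for r in reps):
                problems.append(f"{site}: all replicates must be > 0, got {reps}")
        return problems


@dataclass
class Cohort:
    """An ordered collection of validated player records plus free metadata."""

    records: list[PlayerRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.player_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-player table with site means left out (raw data only)."""
        rows = []
        for r in self.records:
            row: dict = {
                "player_id": r.player_id,
                "decimal_age": r.decimal_age,
                "height_cm": r.height,
                "weight_kg": r.weight,
            }
            for site in SKINFOLD_SITES:
                reps = r.skinfolds[site]
                for k in range(MAX_REPLICATES):
                    row[f"{site}_{k + 1}"] = reps[k] if k < len(reps) else np.nan
            rows.append(row)
        return pd.DataFrame(rows, columns=_wide_columns())


def _wide_columns() -> list[str]:
    cols = ["player_id", "decimal_age", "height_cm", "weight_kg"]
    for site in SKINFOLD_SITES:
        cols.extend(f"{site}_{k + 1}" for k in range(MAX_REPLICATES))
    return cols


REQUIRED_COLUMNS = tuple(
    ["player_id", "height_cm", "weight_kg"]
    + [f"{site}_{k}" for site in SKINFOLD_SITES for k in (1, 2, 3)]
)


def compute_decimal_age(birth_date: _dt.date, test_date: _dt.date) -> float:
    """Decimal age in years: (test_date - birth_date) in days / 365.25."""
    if test_date < birth_date:
        raise DomainError(f"test_date {test_date} precedes birth_date {birth_date}")
    return (test_date - birth_date).days / DAYS_PER_YEAR


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Convert a long replicate table to the wide schema.

    Expects columns player_id, decimal_age, height_cm, weight_kg, site,
    replicate (1-based), value_mm.
    """
    needed = {"player_id", "site", "replicate", "value_mm"}
    missing = needed - set(long.columns)
    if missing:
        raise SchemaError(f"long table missing columns: {sorted(missing)}")
    base = (
        long.drop_duplicates("player_id")
        .loc[:, ["player_id", "decimal_age", "height_cm", "weight_kg"]]
        .set_index("player_id")
    )
    wide = long.pivot_table(
        index="player_id", columns=["site", "replicate"], values="value_mm", aggfunc="first"
    )
    wide.columns = [f"{site}_{int(rep)}" for site, rep in wide.columns]
    out = base.join(wide).reset_index()
    return out.reindex(columns=_wide_columns())


def read_cohort(
    path,
    dialect: Dialect = Dialect(),
    age_window: tuple[float, float] = DEFAULT_AGE_WINDOW,
) -> Cohort:
    """Read and validate a wide-form cohort CSV.

    Raises SchemaError for missing columns, ParseError for non-numeric cells
    (naming row and column), and ValidationError (with row-indexed
    diagnostics) when any record violates its invariants, including duplicate
    player ids.
    """
    raw = pd.read_csv(
        path,
        sep=dialect.sep,
        decimal=dialect.decimal,
        dtype={"player_id": str},
        float_precision="round_trip",
    )

    has_age = "decimal_age" in raw.columns
    has_dates = {"birth_date", "test_date"} <= set(raw.columns)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if not (has_age or has_dates):
        missing.append("decimal_age")
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    numeric_cols = [c for c in raw.columns if c not in ("player_id", "birth_date", "test_date")]
    for col in numeric_cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value {raw[col].iloc[row]!r} in row {row}, column {col!r}")
        raw[col] = coerced

    if not has_age:
        ages = []
        for _, row in raw.iterrows():
            b = _dt.date.fromisoformat(str(row["birth_date"]))
            t = _dt.date.fromisoformat(str(row["test_date"]))
            ages.append(compute_decimal_age(b, t))
        raw["decimal_age"] = ages

    records: list[PlayerRecord] = []
    diagnostics: list[tuple[int, str, str]] = []
    seen: dict[str, int] = {}
    for i, row in raw.iterrows():
        pid = str(row["player_id"])
        if pid in seen:
            diagnostics.append((int(i), "player_id", f"duplicate id {pid!r} (first seen row {seen[pid]})"))
            continue
        seen[pid] = int(i)
        skinfolds = {}
        for site in SKINFOLD_SITES:
            reps = []
            for k in range(MAX_REPLICATES):
                col = f"{site}_{k + 1}"
                if col in raw.columns and pd.notna(row[col]):
                    reps.append(float(row[col]))
            skinfolds[site] = reps
        rec = PlayerRecord(
            player_id=pid,
            decimal_age=float(row["decimal_age"]),
            height=float(row["height_cm"]),
            weight=float(row["weight_kg"]),
            skinfolds=skinfolds,
        )
        problems = rec.validate(age_window)
        if problems:
            diagnostics.extend((int(i), p.split(":")[0], p) for p in problems)
        else:
            records.append(rec)

    if diagnostics:
        lines = "; ".join(f"row {r}: {msg}" for r, _f, msg in diagnostics[:10])
        raise ValidationError(f"{len(diagnostics)} invalid record field(s): {lines}", diagnostics)
    return Cohort(records=records, metadata={"source": str(path)})


def write_cohort(cohort: Cohort, path, dialect: Dialect = Dialect()) -> None:
    """Write a cohort in the wide CSV schema (round-trips through read_cohort)."""
    cohort.to_frame().to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False)
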