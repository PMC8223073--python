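"""Skinfold-based body composition: BD, %BF, FM, FFM, BMI, BFMI, FFMI.

Body density comes from the sum of four skinfold site means (biceps,
triceps, subscapular, suprailiac) through the schoolboy regression

    BD (g cm^-3) = 1.1533 - 0.0643 * log10(S)

with S the four-site sum in mm, and percent body fat through the Siri
two-compartment conversion

    %BF = (4.95 / BD - 4.5) * 100.

Fat mass and fat-free mass are then expressed per squared height, giving
the additive decomposition BMI = BFMI + FFMI with
%BF = 100 * BFMI / (BFMI + FFMI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ProtocolError
from .records import SKINFOLD_SITES, Cohort

#: Replicate-spread threshold (mm) above which the measurement protocol
#: requires two additional caliper readings at the site.
REPLICATE_SPREAD_MM = 0.2

#: Plausibility band for percent body fat; values outside are flagged.
PBF_PLAUSIBLE = (0.0, 75.0)


class ProtocolWarning(UserWarning):
    """Raw measurements deviate from the caliper protocol but remain usable."""


class PlausibilityWarning(UserWarning):
    """A derived quantity is outside its physiological plausibility band."""


@dataclass(frozen=True)
class BodyComposition:
    """Derived body-composition profile for one player.

    sum4 is the sum of the four skinfold site means (mm); indices are in
    kg m^-2. Invariants: bmi == bfmi + ffmi, fat_mass + fat_free_mass ==
    weight, and percent_fat == 100 * bfmi / (bfmi + ffmi).
    """

    sum4: float
    body_density: float
    percent_fat: float
    fat_mass: float
    fat_free_mass: float
    bmi: float
    bfmi: float
    ffmi: float


def aggregate_site(replicates) -> float:
    """Mean of the replicate caliper readings at one site.

    With exactly three replicates whose spread exceeds 0.2 mm the protocol
    calls for two further readings; that situation raises ProtocolWarning
    (never an error — the package cannot retroactively measure).
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 3:
        raise ProtocolError(f"need >=3 replicates per site, got {reps.size}")
    if np.any(~np.isfinite(reps)) or np.any(reps <= 0):
        raise DomainError(f"skinfold replicates must be positive, got {replicates}")
    if reps.size == 3 and (reps.max() - reps.min()) > REPLICATE_SPREAD_MM:
        warnings.warn(
            f"replicate spread {reps.max() - reps.min():.2f} mm exceeds "
            f"{REPLICATE_SPREAD_MM} mm with only 3 readings; protocol asks for 5",
            ProtocolWarning,
            stacklevel=2,
        )
    return float(reps.mean())


def body_density(sum4) -> float:
    """Body density (g cm^-3) from the four-site skinfold sum in mm."""
    s = np.asarray(sum4, dtype=float)
    if np.any(s <= 0):
        raise DomainError(f"sum of skinfolds must be > 0, got {sum4}")
    out = 1.1533 - 0.0643 * np.log10(s)
    return float(out) if out.ndim == 0 else out


def percent_fat(bd) -> float:
    """Percent body fat from body density (Siri conversion)."""
    d = np.asarray(bd, dtype=float)
    if np.any(d <= 0):
        raise DomainError(f"body density must be > 0, got {bd}")
    pbf = (4.95 / d - 4.5) * 100.0
    lo, hi = PBF_PLAUSIBLE
    if np.any((pbf < lo) | (pbf > hi)):
        warnings.warn(
            f"percent fat outside plausibility band [{lo}, {hi}]",
            PlausibilityWarning,
            stacklevel=2,
        )
    return float(pbf) if pbf.ndim == 0 else pbf


def compose_profile(height: float, weight: float, site_means) -> BodyComposition:
    """Full body-composition profile from height (cm), weight (kg) and the
    four skinfold site means (mm)."""
    if height <= 0 or weight <= 0:
        raise DomainError("height and weight must be positive")
    means = np.asarray(site_means, dtype=float)
    if means.size != 4:
        raise DomainError(f"expected 4 site means, got {means.size}")
    if np.any(means <= 0):
        raise DomainError("site means must be positive")
    s4 = float(means.sum())
    bd = body_density(s4)
    pbf = percent_fat(bd)
    fm = weight * pbf / 100.0
    ffm = weight - fm
    h2 = (height / 100.0) ** 2
    return BodyComposition(
        sum4=s4,
        body_density=bd,
        percent_fat=pbf,
        fat_mass=fm,
        fat_free_mass=ffm,
        bmi=weight / h2,
        bfmi=fm / h2,
        ffmi=ffm / h2,
    )


def profile_cohort(cohort: Cohort) -> pd.DataFrame:
    """Augmented cohort table: raw columns plus sum4, bd, pbf, fm, ffm, bmi,
    bfmi, ffmi — one row per player."""
    rows = []
    with warnings.catch_warnings():
        # Site spreads/plausibility are screened at entry; a cohort-level
        # pass would otherwise emit one warning per flagged player.
        warnings.simplefilter("ignore", ProtocolWarning)
        warnings.simplefilter("ignore", PlausibilityWarning)
        for rec in cohort:
            means = [aggregate_site(rec.skinfolds[site]) for site in SKINFOLD_SITES]
            prof = compose_profile(rec.height, rec.weight, means)
            rows.append(
                {
                    "player_id": rec.player_id,
                    "decimal_age": rec.decimal_age,
                    "height_cm": rec.height,
                    "weight_kg": rec.weight,
                    "sum4": prof.sum4,
                    "bd": prof.body_density,
                    "pbf": prof.percent_fat,
                    "fm": prof.fat_mass,
                    "ffm": prof.fat_free_mass,
                    "bmi": prof.bmi,
                    "bfmi": prof.bfmi,
                    "ffmi": prof.ffmi,
                }
            )
    return pd.DataFrame(rows)
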