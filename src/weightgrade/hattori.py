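"""Hattori body-composition chart and mean +/- 1 SD morphotype classification.

The chart plots BFMI on the horizontal axis and FFMI on the vertical axis,
so iso-BMI guides are lines x + y = BMI (slope -1) and iso-%BF guides are
rays y = x (100 - p) / p through the origin, since %BF = 100 x / (x + y).

Within a group, each axis is cut at the group mean -/+ 1 sample SD, giving
three classes per axis — {lean, intermediate, adipose} for BFMI and
{slender, intermediate, solid} for FFMI — and nine morphotype cells. The
four corner cells (adipo-slender, adipo-solid, lean-slender, lean-solid)
are the extreme morphotypes. Values exactly on a threshold fall to the
intermediate class (strict below/above reading).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

BFMI_CLASSES = ("lean", "intermediate", "adipose")
FFMI_CLASSES = ("slender", "intermediate", "solid")

EXTREME_LABELS = ("adipo-slender", "adipo-solid", "lean-slender", "lean-solid")


@dataclass(frozen=True)
class MorphotypeGrid:
    """Mean +/- 1 SD thresholds on both chart axes for one group."""

    group: str
    bfmi_low: float
    bfmi_high: float
    ffmi_low: float
    ffmi_high: float


def grid_thresholds(bfmi_values, ffmi_values, group: str = "") -> MorphotypeGrid:
    """Thresholds at mean -/+ 1 sample SD of each axis, from the group's own members."""
    b = np.asarray(bfmi_values, dtype=float)
    f = np.asarray(ffmi_values, dtype=float)
    if b.size < 2 or f.size < 2:
        raise DomainError("need n >= 2 on each axis for a morphotype grid")
    bs, fs = b.std(ddof=1), f.std(ddof=1)
    if bs == 0.0 or fs == 0.0:
        raise DomainError("constant axis gives a degenerate (zero-width) grid")
    return MorphotypeGrid(
        group=group,
        bfmi_low=float(b.mean() - bs),
        bfmi_high=float(b.mean() + bs),
        ffmi_low=float(f.mean() - fs),
        ffmi_high=float(f.mean() + fs),
    )


def grid_from_moments(
    bfmi_mean: float, bfmi_sd: float, ffmi_mean: float, ffmi_sd: float, group: str = ""
) -> MorphotypeGrid:
    """Grid pinned from printed summary statistics instead of raw members."""
    if bfmi_sd <= 0 or ffmi_sd <= 0:
        raise DomainError("SDs must be positive")
    return MorphotypeGrid(
        group=group,
        bfmi_low=bfmi_mean - bfmi_sd,
        bfmi_high=bfmi_mean + bfmi_sd,
        ffmi_low=ffmi_mean - ffmi_sd,
        ffmi_high=ffmi_mean + ffmi_sd,
    )


def _axis_class(value: float, low: float, high: float, classes) -> str:
    if value < low:
        return classes[0]
    if value > high:
        return classes[2]
    return classes[1]


def classify_morphotype(bfmi: float, ffmi: float, grid: MorphotypeGrid) -> str:
    """One of the nine morphotype labels for a (BFMI, FFMI) point.

    Corner combinations collapse to the four extreme labels; other cells are
    reported as '<bfmi class>-<ffmi class>' with the doubly intermediate cell
    simply 'intermediate'.
    """
    bc = _axis_class(bfmi, grid.bfmi_low, grid.bfmi_high, BFMI_CLASSES)
    fc = _axis_class(ffmi, grid.ffmi_low, grid.ffmi_high, FFMI_CLASSES)
    if bc == "adipose" and fc == "slender":
        return "adipo-slender"
    if bc == "adipose" and fc == "solid":
        return "adipo-solid"
    if bc == "lean" and fc == "slender":
        return "lean-slender"
    if bc == "lean" and fc == "solid":
        return "lean-solid"
    if bc == "intermediate" and fc == "intermediate":
        return "intermediate"
    return f"{bc}-{fc}"


def classify_group(bfmi_values, ffmi_values, grid: MorphotypeGrid) -> list[str]:
    return [
        classify_morphotype(b, f, grid) for b, f in zip(bfmi_values, ffmi_values, strict=True)
    ]


def extreme_counts(morphotypes) -> tuple[dict[str, int], float]:
    """Counts of the four extreme morphotypes and their total share in percent."""
    labels = list(morphotypes)
    if not labels:
        raise DomainError("empty group")
    counts = {lab: labels.count(lab) for lab in EXTREME_LABELS}
    share = sum(counts.values()) / len(labels) * 100.0
    return counts, share


def chart_geometry(bmi_levels, pbf_levels, window) -> dict:
    """Guide-line polylines for the chart, clipped to a plotting window.

    ``window`` is ((bfmi_min, bfmi_max), (ffmi_min, ffmi_max)). Iso-BMI
    guides are the segments x + y = level; iso-%BF guides the rays
    y = x (100 - p)/p, with p = 0 mapping to the vertical axis itself.
    Returns {'iso_bmi': {level: 2x2 array}, 'iso_pbf': {level: 2x2 array}};
    guides that miss the window are omitted.
    """
    (x0, x1), (y0, y1) = window
    if not (x0 < x1 and y0 < y1):
        raise DomainError("window ranges must be increasing")
    out = {"iso_bmi": {}, "iso_pbf": {}}
    for level in bmi_levels:
        if level <= 0:
            raise DomainError(f"BMI level must be positive, got {level}")
        seg = _clip_line(p0=(level, 0.0), p1=(0.0, level), window=window)
        if seg is not None:
            out["iso_bmi"][level] = seg
    for p in pbf_levels:
        if not (0.0 <= p < 100.0):
            raise DomainError(f"%BF level must be in [0, 100), got {p}")
        if p == 0.0:
            seg = _clip_line(p0=(0.0, 0.0), p1=(0.0, max(y1, 1.0)), window=window)
        else:
            slope = (100.0 - p) / p
            far = max(x1, y1 / slope if slope > 0 else x1) * 2.0 + 1.0
            seg = _clip_line(p0=(0.0, 0.0), p1=(far, far * slope), window=window)
        if seg is not None:
            out["iso_pbf"][p] = seg
    return out


def _clip_line(p0, p1, window):
    """Liang–Barsky clip of segment p0-p1 to the window; None if outside."""
    (x0w, x1w), (y0w, y1w) = window
    x0, y0 = p0
    dx, dy = p1[0] - x0, p1[1] - y0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x0 - x0w),
        (dx, x1w - x0),
        (-dy, y0 - y0w),
        (dy, y1w - y0),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        r = q / p
        if p < 0.0:
            if r > t1:
                return None
            t0 = max(t0, r)
        else:
            if r < t0:
                return None
            t1 = min(t1, r)
    return np.array(
        [[x0 + t0 * dx, y0 + t0 * dy], [x0 + t1 * dx, y0 + t1 * dy]], dtype=float
    )
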