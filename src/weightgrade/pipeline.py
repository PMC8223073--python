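"""End-to-end comparison pipeline and report-bundle writer.

``run_pipeline`` drives the full analysis — body-composition profiling,
status classification, dual grading, dispersion and mean comparisons,
bivariate ellipse tests, and morphotype charting — and writes a
deterministic bundle of delimited/JSON artifacts:

* ``table1.csv``   per-variable group summaries with CV tests and Cohen's d
* ``table2.csv``   age-into-weight movement counts and percentages (both
  denominator conventions)
* ``figure1.csv``  status-stratified up/down/retained percentages
* ``figure2/``     per-pair scatter points, ellipse polylines, test results
* ``figure3/``     morphotype labels, grid thresholds, chart guide lines
* ``run_metadata.json``  seed, package/library versions, and every method
  choice needed to recompute the bundle

Identical configuration and seed give a byte-identical bundle; no
timestamps or machine-specific values are written.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from importlib import metadata as _md
from pathlib import Path

import numpy as np
import pandas as pd

from . import bivariate, hattori, simulate, stats
from .composition import profile_cohort
from .errors import ValidationError, WeightGradeError
from .grading import (
    GradingScheme,
    default_scheme,
    harmonize_cutpoints,
    label_cohort,
    movement_by_status,
    movement_crosstab,
    weight_percentiles,
)
from .records import Dialect, read_cohort
from .status import classify_cohort_status, load_cutoff_table
from .verify import replay_printed_tables

VARIABLES = {
    "weight": "weight_kg",
    "height": "height_cm",
    "bmi": "bmi",
    "bfmi": "bfmi",
    "ffmi": "ffmi",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (a cohort CSV) and ``synthetic`` (a
    generator spec) must be given. ``n_per_group`` rescales a synthetic
    spec's block sizes; ``boundary_rule`` picks the weight-band scheme
    ('manual' = shipped preset bands, 'midpoint_grid' = rebuild from this
    cohort's within-age quartiles).
    """

    out_dir: str | Path
    input_path: str | Path | None = None
    synthetic: simulate.CohortSpec | None = None
    n_per_group: int | None = None
    seed: int = 0
    boundary_rule: str = "manual"
    grid_kg: float = 5.0
    scheme: GradingScheme | None = None
    cutoff_path: str | Path | None = None
    status_mode: str = "exact"
    dialect: Dialect = field(default_factory=Dialect)
    ellipse_coverage: float = 0.95
    ellipse_vertices: int = 128

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValidationError("exactly one of input_path / synthetic must be set")
        if self.boundary_rule not in ("manual", "midpoint_grid"):
            raise ValidationError(f"unknown boundary_rule {self.boundary_rule!r}")


@dataclass
class PipelineResult:
    """In-memory results plus the paths of the written bundle."""

    out_dir: Path
    table1: pd.DataFrame
    movement: object
    movement_status: pd.DataFrame
    comparisons: dict
    morphotypes: pd.DataFrame
    scheme: GradingScheme
    labeled: pd.DataFrame
    artifacts: list


class _Stage:
    """Context manager naming the failing stage and cleaning partial output."""

    def __init__(self, name: str, out_dir: Path, created: bool):
        self.name, self.out_dir, self.created = name, out_dir, created

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            if self.created and self.out_dir.exists():
                shutil.rmtree(self.out_dir, ignore_errors=True)
            raise WeightGradeError(f"pipeline stage {self.name!r} failed: {exc}") from exc


def _table1(labeled: pd.DataFrame, scheme: GradingScheme) -> pd.DataFrame:
    rows = []
    for age_label, w_label in zip(scheme.age_labels, scheme.weight_labels):
        grp_a = labeled[labeled["age_cat"] == age_label]
        grp_w = labeled[labeled["weight_cat"] == w_label]
        for var, col in VARIABLES.items():
            a, w = grp_a[col].to_numpy(), grp_w[col].to_numpy()
            sa, sw = stats.summarize(a), stats.summarize(w)
            cvt = stats.compare_cv(w, a)
            an = stats.anova_lsd([w, a])
            rows.append(
                {
                    "pair": f"{age_label}_vs_{w_label}",
                    "variable": var,
                    "age_n": sa.n, "age_mean": sa.mean, "age_sd": sa.sd,
                    "age_median": sa.median, "age_min": sa.range[0], "age_max": sa.range[1],
                    "age_cv": sa.cv,
                    "weight_n": sw.n, "weight_mean": sw.mean, "weight_sd": sw.sd,
                    "weight_median": sw.median, "weight_min": sw.range[0],
                    "weight_max": sw.range[1], "weight_cv": sw.cv,
                    "cv_reduction_pct": stats.cv_reduction(sa.cv, sw.cv),
                    "cv_test_F": cvt.statistic, "cv_test_p": cvt.p_value,
                    "anova_F": an.statistic, "anova_p": an.p_value,
                    "cohens_d": stats.cohens_d(w, a),
                }
            )
    return pd.DataFrame(rows)


def _round_df(df: pd.DataFrame, decimals: int = 6) -> pd.DataFrame:
    # fixed rounding keeps CSV bytes stable across BLAS/platform noise
    return df.round(decimals)


def _write_csv(df: pd.DataFrame, path: Path, artifacts: list, index: bool = False) -> None:
    _round_df(df).to_csv(path, index=index)
    artifacts.append(path)


def _write_json(obj, path: Path, artifacts: list) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts.append(path)


def _test_dict(t: stats.TestResult) -> dict:
    out = {
        "statistic": round(float(t.statistic), 6),
        "df": [round(float(d), 6) for d in t.df],
        "p_value": float(f"{t.p_value:.6g}"),
        "method": t.method,
    }
    for k, v in t.extra.items():
        if isinstance(v, (int, float)):
            out[k] = round(float(v), 6)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full comparison and write the report bundle. See module docs."""
    config.validate()
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    with _Stage("load_cohort", out_dir, created):
        if config.synthetic is not None:
            spec = config.synthetic.with_seed(config.seed)
            if config.n_per_group is not None:
                spec = spec.with_n(config.n_per_group)
            cohort = simulate.generate(spec)
        else:
            spec = None
            cohort = read_cohort(config.input_path, dialect=config.dialect)

    with _Stage("profile", out_dir, created):
        df = profile_cohort(cohort)

    with _Stage("grade", out_dir, created):
        if config.scheme is not None:
            scheme = config.scheme
        elif config.boundary_rule == "manual":
            scheme = default_scheme()
        else:
            age_cats = [
                (label, df[(df["decimal_age"] >= lo) & (df["decimal_age"] < hi)])
                for label, lo, hi in default_scheme().age_bands
            ]
            pct = weight_percentiles(
                {label: sub["weight_kg"].to_numpy() for label, sub in age_cats}
            )
            scheme = harmonize_cutpoints(pct, grid_kg=config.grid_kg)
        labeled = label_cohort(df, scheme)
        table = load_cutoff_table(config.cutoff_path)
        labeled["status"] = classify_cohort_status(labeled, table, mode=config.status_mode)

    with _Stage("table1", out_dir, created):
        table1 = _table1(labeled, scheme)
        _write_csv(table1, out_dir / "table1.csv", artifacts)

    with _Stage("table2", out_dir, created):
        movement = movement_crosstab(labeled, scheme)
        tidy = (
            movement.counts.stack()
            .rename("n")
            .reset_index()
            .merge(
                movement.pct_weight_denominator.stack().rename("pct_weight_denom").reset_index(),
                how="left",
            )
            .merge(
                movement.pct_age_denominator.stack().rename("pct_age_denom").reset_index(),
                how="left",
            )
        )
        _write_csv(tidy, out_dir / "table2.csv", artifacts)
        _write_json(
            {
                "counts": {c: movement.counts[c].to_dict() for c in movement.counts},
                "pct_weight_denominator": json.loads(
                    _round_df(movement.pct_weight_denominator).to_json()
                ),
                "pct_age_denominator": json.loads(
                    _round_df(movement.pct_age_denominator).to_json()
                ),
            },
            out_dir / "table2.json",
            artifacts,
        )

    with _Stage("figure1", out_dir, created):
        movement_status = movement_by_status(labeled, scheme)
        _write_csv(movement_status, out_dir / "figure1.csv", artifacts)

    with _Stage("figure2", out_dir, created):
        fig2 = out_dir / "figure2"
        fig2.mkdir(exist_ok=True)
        comparisons: dict[str, bivariate.BivariateComparison] = {}
        tests_json: dict[str, dict] = {"caveat": bivariate.OVERLAP_CAVEAT}
        ellipse_rows, point_rows = [], []
        for age_label, w_label in zip(scheme.age_labels, scheme.weight_labels):
            pair = f"{age_label}_vs_{w_label}"
            pts_a = labeled.loc[labeled["age_cat"] == age_label, ["bfmi", "ffmi"]]
            pts_w = labeled.loc[labeled["weight_cat"] == w_label, ["bfmi", "ffmi"]]
            comp = bivariate.compare_models(
                pts_a.to_numpy(), pts_w.to_numpy(), coverage=config.ellipse_coverage
            )
            comparisons[pair] = comp
            for model, sub in (("age", pts_a), ("weight", pts_w)):
                ids = labeled.loc[sub.index, "player_id"]
                point_rows.append(
                    pd.DataFrame(
                        {"pair": pair, "model": model, "player_id": ids,
                         "bfmi": sub["bfmi"], "ffmi": sub["ffmi"]}
                    )
                )
            for model, ell in (("age", comp.ellipse_a), ("weight", comp.ellipse_b)):
                poly = ell.polyline(config.ellipse_vertices)
                ellipse_rows.append(
                    pd.DataFrame(
                        {"pair": pair, "model": model,
                         "vertex": np.arange(poly.shape[0]),
                         "bfmi": poly[:, 0], "ffmi": poly[:, 1]}
                    )
                )
            tests_json[pair] = {
                "centroid_age": [round(v, 6) for v in comp.centroid_a],
                "centroid_weight": [round(v, 6) for v in comp.centroid_b],
                "wilks": _test_dict(comp.wilks),
                "box": _test_dict(comp.box),
                "pearson_age": _test_dict(comp.pearson_a),
                "pearson_weight": _test_dict(comp.pearson_b),
            }
        _write_csv(pd.concat(point_rows, ignore_index=True), fig2 / "points.csv", artifacts)
        _write_csv(pd.concat(ellipse_rows, ignore_index=True), fig2 / "ellipses.csv", artifacts)
        _write_json(tests_json, fig2 / "tests.json", artifacts)

    with _Stage("figure3", out_dir, created):
        fig3 = out_dir / "figure3"
        fig3.mkdir(exist_ok=True)
        morph_rows, grids_json = [], {}
        in_band = labeled[labeled["weight_cat"].isin(scheme.weight_labels)]
        for w_label in scheme.weight_labels:
            grp = in_band[in_band["weight_cat"] == w_label]
            grid = hattori.grid_thresholds(
                grp["bfmi"].to_numpy(), grp["ffmi"].to_numpy(), group=w_label
            )
            labels = hattori.classify_group(grp["bfmi"], grp["ffmi"], grid)
            counts, share = hattori.extreme_counts(labels)
            grids_json[w_label] = {
                "bfmi_low": round(grid.bfmi_low, 6), "bfmi_high": round(grid.bfmi_high, 6),
                "ffmi_low": round(grid.ffmi_low, 6), "ffmi_high": round(grid.ffmi_high, 6),
                "extreme_counts": counts, "extreme_share_pct": round(share, 6),
            }
            morph_rows.append(
                pd.DataFrame(
                    {"weight_cat": w_label, "player_id": grp["player_id"],
                     "bfmi": grp["bfmi"], "ffmi": grp["ffmi"], "morphotype": labels}
                )
            )
        morphotypes = pd.concat(morph_rows, ignore_index=True)
        _write_csv(morphotypes, fig3 / "morphotypes.csv", artifacts)
        _write_json(grids_json, fig3 / "grids.json", artifacts)
        window = (
            (0.0, float(np.ceil(in_band["bfmi"].max() + 1))),
            (0.0, float(np.ceil(in_band["ffmi"].max() + 1))),
        )
        guides = hattori.chart_geometry(
            bmi_levels=[15, 20, 25, 30, 35], pbf_levels=[10, 20, 30, 40, 50], window=window
        )
        guide_rows = [
            {"guide": kind, "level": level, "x0": seg[0, 0], "y0": seg[0, 1],
             "x1": seg[1, 0], "y1": seg[1, 1]}
            for kind, levels in guides.items()
            for level, seg in levels.items()
        ]
        _write_csv(pd.DataFrame(guide_rows), fig3 / "guides.csv", artifacts)

    with _Stage("metadata", out_dir, created):
        meta = {
            "seed": config.seed,
            "n_players": int(len(labeled)),
            "input": str(config.input_path) if config.input_path else "synthetic",
            "boundary_rule": scheme.boundary_rule,
            "weight_bands": [list(b) for b in scheme.weight_bands],
            "age_bands": [list(b) for b in scheme.age_bands],
            "percentile_method": scheme.percentile_method,
            "cv_test": "forkman_approximate_F",
            "anova_posthoc": "fisher_lsd_unadjusted",
            "box_test": "box_m_F_approximation",
            "wilks": "two_group_exact_F_transform",
            "status_mode": config.status_mode,
            "status_boundary": "cutoff_value_takes_heavier_class",
            "morphotype_ties": "threshold_value_is_intermediate",
            "ellipse_coverage": config.ellipse_coverage,
            "versions": {
                "weightgrade": _md.version("weightgrade"),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        if spec is not None:
            meta["generator_groups"] = [g.label for g in spec.groups]
            meta["generator_n"] = [g.n for g in spec.groups]
        _write_json(meta, out_dir / "run_metadata.json", artifacts)

    return PipelineResult(
        out_dir=out_dir,
        table1=table1,
        movement=movement,
        movement_status=movement_status,
        comparisons=comparisons,
        morphotypes=morphotypes,
        scheme=scheme,
        labeled=labeled,
        artifacts=artifacts,
    )


def verification_report() -> pd.DataFrame:
    """Frame of the printed-arithmetic replay (see :mod:`weightgrade.verify`)."""
    return replay_printed_tables().to_frame()
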