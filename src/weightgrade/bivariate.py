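"""Bivariate (BFMI, FFMI) comparison of grading models.

Each group's scatter is summarised by its centroid, sample covariance, and
the 95% bivariate-normal ellipse (axes along covariance eigenvectors,
semi-axis lengths sqrt(eigenvalue * chi2_2(coverage))). Centroid equality
between the paired age and weight groups is tested with the two-group
Wilks' lambda (det(within)/det(total)), converted exactly to
F = ((N-3)/2) (1-lambda)/lambda with (2, N-3) df for two groups and two
variables; covariance equality with Box's M and its standard F
approximation. Membership of the paired groups overlaps (a player can sit
in both U11 and its home weight band); the tests are computed as if the
groups were independent, which mirrors common practice but overstates
precision — reports carry that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DomainError
from .stats import TestResult, pearson

OVERLAP_CAVEAT = (
    "paired groups share members; independence-based p-values are anti-conservative"
)


@dataclass(frozen=True)
class Ellipse:
    """Coverage ellipse: center, semi-axis lengths (major first), orientation.

    ``angle`` is the angle in radians from the +x axis to the major axis.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    coverage: float

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])

    def polyline(self, n_vertices: int = 128) -> np.ndarray:
        """(n+1) x 2 closed polyline tracing the ellipse."""
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices + 1)
        a, b = self.semi_axes
        xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, -s], [s, c]])
        return xy @ rot.T + np.asarray(self.center)

    def contains(self, points) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])
        uv = pts @ rot.T
        a, b = self.semi_axes
        if a == 0.0 or b == 0.0:
            return np.all(np.isclose(uv, 0.0), axis=1)
        # boundary-inclusive with an epsilon so polyline vertices count as inside
        return (uv[:, 0] / a) ** 2 + (uv[:, 1] / b) ** 2 <= 1.0 + 1e-12


@dataclass(frozen=True)
class BivariateComparison:
    """Full two-group (BFMI, FFMI) comparison for one age/weight pair."""

    centroid_a: tuple[float, float]
    centroid_b: tuple[float, float]
    cov_a: np.ndarray
    cov_b: np.ndarray
    ellipse_a: Ellipse
    ellipse_b: Ellipse
    wilks: TestResult
    box: TestResult
    pearson_a: TestResult
    pearson_b: TestResult
    caveat: str = OVERLAP_CAVEAT


def _as_points(points, min_n: int, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError(f"{name} must be an n x 2 array")
    if pts.shape[0] < min_n:
        raise DomainError(f"{name} needs at least {min_n} points, got {pts.shape[0]}")
    return pts


def normal_ellipse(points, coverage: float = 0.95) -> Ellipse:
    """Bivariate-normal coverage ellipse fitted to a point cloud.

    Centered at the sample mean, axes along the sample-covariance
    eigenvectors, semi-axes sqrt(eigenvalue * q) with q the chi-square
    quantile at the requested coverage with 2 df. Coverage 0 degenerates to
    a point.
    """
    pts = _as_points(points, 3, "points")
    if not 0.0 <= coverage < 1.0:
        raise DomainError(f"coverage must be in [0, 1), got {coverage}")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 0:
        raise DomainError("degenerate covariance; ellipse undefined")
    evals, evecs = np.linalg.eigh(cov)  # ascending
    q = sps.chi2.ppf(coverage, df=2) if coverage > 0 else 0.0
    major, minor = np.sqrt(evals[1] * q), np.sqrt(evals[0] * q)
    vmaj = evecs[:, 1]
    return Ellipse(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(float(major), float(minor)),
        angle=float(np.arctan2(vmaj[1], vmaj[0])),
        coverage=float(coverage),
    )


def _scatter(pts: np.ndarray) -> np.ndarray:
    d = pts - pts.mean(axis=0)
    return d.T @ d


def wilks_two_group(points_a, points_b) -> TestResult:
    """Two-group Wilks' lambda on bivariate data with the exact F transform.

    lambda = det(W)/det(T) where W pools the two groups' centered scatter and
    T is the scatter about the grand mean; for g=2 groups, p=2 variables
    F = ((N-3)/2)(1-lambda)/lambda with df (2, N-3).
    """
    a = _as_points(points_a, 3, "points_a")
    b = _as_points(points_b, 3, "points_b")
    allp = np.vstack([a, b])
    n = allp.shape[0]
    W = _scatter(a) + _scatter(b)
    T = _scatter(allp)
    det_w, det_t = np.linalg.det(W), np.linalg.det(T)
    if det_t <= 0 or det_w <= 0:
        raise DomainError("singular scatter matrix; Wilks' lambda undefined")
    lam = det_w / det_t
    lam = min(lam, 1.0)
    df1, df2 = 2, n - 3
    if lam == 1.0:
        f, p = 0.0, 1.0
    else:
        f = (df2 / df1) * (1.0 - lam) / lam
        p = float(sps.f.sf(f, df1, df2))
    return TestResult(
        statistic=float(f),
        df=(df1, df2),
        p_value=p,
        method="wilks_two_group",
        extra={"lambda": float(lam)},
    )


def box_m(points_a, points_b) -> TestResult:
    """Box's M test of covariance-matrix equality with the F approximation.

    M = (N-g) ln|S_pooled| - sum_i (n_i - 1) ln|S_i| for g = 2 groups; the
    F statistic and df follow the standard Box approximation.
    """
    a = _as_points(points_a, 4, "points_a")
    b = _as_points(points_b, 4, "points_b")
    groups = [a, b]
    p = 2
    g = len(groups)
    ns = np.array([grp.shape[0] for grp in groups])
    vs = ns - 1
    v = int(vs.sum())  # N - g
    covs = [np.cov(grp, rowvar=False) for grp in groups]
    dets = [np.linalg.det(c) for c in covs]
    if any(d <= 0 for d in dets):
        raise DomainError("singular group covariance; Box's M undefined")
    s_pool = sum(vi * ci for vi, ci in zip(vs, covs)) / v
    det_pool = np.linalg.det(s_pool)
    m = v * np.log(det_pool) - float(np.sum(vs * np.log(dets)))
    m = max(m, 0.0)  # numerically tiny negatives for near-identical covariances

    c1 = (np.sum(1.0 / vs) - 1.0 / v) * (2 * p**2 + 3 * p - 1) / (6.0 * (p + 1) * (g - 1))
    c2 = (np.sum(1.0 / vs**2) - 1.0 / v**2) * (p - 1) * (p + 2) / (6.0 * (g - 1))
    df1 = p * (p + 1) * (g - 1) / 2.0
    denom = abs(c2 - c1**2)
    if denom == 0.0:  # pragma: no cover - only for pathological equal tiny groups
        denom = np.finfo(float).tiny
    df2 = (df1 + 2.0) / denom
    if c2 > c1**2:
        a_plus = df1 / (1.0 - c1 - df1 / df2)
        f = m / a_plus
    else:
        a_minus = df2 / (1.0 - c1 + 2.0 / df2)
        f = df2 * m / (df1 * (a_minus - m))
    f = max(float(f), 0.0)
    pval = float(sps.f.sf(f, df1, df2)) if f > 0 else 1.0
    return TestResult(
        statistic=f,
        df=(float(df1), float(df2)),
        p_value=pval,
        method="box_m_F_approximation",
        extra={"M": float(m)},
    )


def compare_models(points_age, points_weight, coverage: float = 0.95) -> BivariateComparison:
    """Full bivariate comparison of one age group against its paired weight group.

    Inputs are n x 2 arrays of (BFMI, FFMI). Also reports each group's
    within-group Pearson r of BFMI vs FFMI, the ellipse-flattening
    diagnostic.
    """
    a = _as_points(points_age, 3, "points_age")
    b = _as_points(points_weight, 3, "points_weight")
    return BivariateComparison(
        centroid_a=(float(a[:, 0].mean()), float(a[:, 1].mean())),
        centroid_b=(float(b[:, 0].mean()), float(b[:, 1].mean())),
        cov_a=np.cov(a, rowvar=False),
        cov_b=np.cov(b, rowvar=False),
        ellipse_a=normal_ellipse(a, coverage),
        ellipse_b=normal_ellipse(b, coverage),
        wilks=wilks_two_group(a, b),
        box=box_m(a, b),
        pearson_a=pearson(a[:, 0], a[:, 1]),
        pearson_b=pearson(b[:, 0], b[:, 1]),
    )
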