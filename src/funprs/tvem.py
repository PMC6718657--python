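"""Time-varying effect models with penalized B-splines (P-splines).

The model for observation j of subject i at age t is

    y_ij = sum_v beta_v(t_ij) * x_v,ij + gamma' z_i + e_ij,

where each coefficient function beta_v(t) (the intercept included) is a
B-spline expansion with equally spaced interior knots and a difference
penalty of configurable order on adjacent spline coefficients.  Estimation is
penalized least squares with a single smoothing parameter shared across
coefficient functions, chosen from a log-spaced grid by AIC with effective
degrees of freedom equal to the trace of the smoother matrix.  Within-subject
correlation is handled by working independence plus a cluster-robust sandwich
covariance by subject; pointwise confidence bands and the age intervals where
they exclude zero are the inferential output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .dataio import InputError, LongRecord

logger = logging.getLogger("funprs")

INTERCEPT = "(intercept)"

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 6, 25))


@dataclass
class TvemSpec:
    """Configuration of a time-varying effect model fit."""

    time_varying_predictors: list[str] = field(default_factory=list)
    invariant_covariates: list[str] = field(default_factory=list)
    degree: int = 3
    n_interior_knots: int = 10
    penalty_order: int = 2
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    ci_level: float = 0.95
    n_grid: int = 101
    age_grid: np.ndarray | None = None  # default: n_grid points over data range

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.n_interior_knots < 1:
            raise ValueError("n_interior_knots must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


def bspline_knots(age_min: float, age_max: float, degree: int,
                  n_interior_knots: int) -> np.ndarray:
    """Equidistant extended knot vector (the P-spline convention).

    Interior knots are equally spaced over the observed range and the grid is
    continued ``degree`` steps beyond each boundary at the same spacing, so a
    difference penalty of order r shrinks each coefficient function toward a
    polynomial of degree r-1 in age (order 2 -> linear) and the basis keeps
    the partition of unity on the whole observed range.
    """
    h = (age_max - age_min) / (n_interior_knots + 1)
    t = age_min + h * np.arange(-degree, n_interior_knots + 2 + degree)
    t[degree] = age_min  # pin the base interval exactly
    t[degree + n_interior_knots + 1] = age_max
    return t


def bspline_basis(
    ages: np.ndarray,
    degree: int,
    n_interior_knots: int,
    age_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Evaluate the clamped B-spline basis at ``ages``.

    Rows are basis evaluations (partition of unity); ages outside the knot
    span raise an evaluation error.
    """
    ages = np.asarray(ages, dtype=float)
    lo, hi = age_range if age_range is not None else (ages.min(), ages.max())
    if ages.min() < lo or ages.max() > hi:
        raise InputError(
            f"ages outside knot span [{lo}, {hi}]: "
            f"[{ages.min()}, {ages.max()}]"
        )
    knots = bspline_knots(lo, hi, degree, n_interior_knots)
    return BSpline.design_matrix(ages, knots, degree, extrapolate=False).toarray()


@dataclass
class TvemFit:
    """Estimated coefficient functions with pointwise sandwich bands."""

    age_grid: np.ndarray
    beta: dict[str, np.ndarray]  # predictor -> beta(t) on the grid
    se: dict[str, np.ndarray]
    ci_lo: dict[str, np.ndarray]
    ci_hi: dict[str, np.ndarray]
    gamma: dict[str, float]  # invariant-covariate coefficients
    gamma_se: dict[str, float]
    lambda_: float
    edf: float
    aic: float
    ci_level: float
    condition_number: float
    n_obs: int
    n_subjects: int

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.beta:
            rows.append(
                pd.DataFrame(
                    {
                        "age": self.age_grid,
                        "predictor": name,
                        "beta": self.beta[name],
                        "se": self.se[name],
                        "ci_lo": self.ci_lo[name],
                        "ci_hi": self.ci_hi[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _design(
    records: Sequence[LongRecord], spec: TvemSpec, age_range: tuple[float, float]
):
    """Build (y, X, penalty, block slices, cluster ids, invariant names)."""
    ages = np.array([r.age for r in records])
    y = np.array([r.phenotype for r in records])
    B = bspline_basis(ages, spec.degree, spec.n_interior_knots, age_range)
    nb = B.shape[1]

    tv_names = [INTERCEPT] + [
        p for p in spec.time_varying_predictors if p != INTERCEPT
    ]
    blocks, slices = [], {}
    col = 0
    for name in tv_names:
        x = (
            np.ones(len(records))
            if name == INTERCEPT
            else np.array([r.covariates[name] for r in records])
        )
        blocks.append(B * x[:, None])
        slices[name] = slice(col, col + nb)
        col += nb
    inv_names = list(spec.invariant_covariates)
    for name in inv_names:
        blocks.append(np.array([[r.covariates[name]] for r in records]))
        slices[name] = slice(col, col + 1)
        col += 1
    X = np.hstack(blocks)

    D = np.diff(np.eye(nb), n=spec.penalty_order, axis=0)
    P_block = D.T @ D
    P = np.zeros((col, col))
    for name in tv_names:
        s = slices[name]
        P[s, s] = P_block
    subjects = pd.factorize(np.array([r.subject_id for r in records]))[0]
    return y, X, P, slices, tv_names, inv_names, subjects


def fit_tvem(records: Sequence[LongRecord], spec: TvemSpec) -> TvemFit:
    """Fit the penalized varying-coefficient model.

    The smoothing parameter is selected from ``spec.lambda_grid`` by AIC
    (n log(RSS/n) + 2 edf, edf = trace of the smoother matrix); standard
    errors come from the cluster-robust (by subject) sandwich covariance of
    the spline coefficients propagated through the basis.
    """
    if len({r.subject_id for r in records}) < 2:
        raise InputError("fit_tvem needs >= 2 subjects")
    ages = np.array([r.age for r in records])
    age_range = (float(ages.min()), float(ages.max()))
    y, X, P, slices, tv_names, inv_names, subjects = _design(
        records, spec, age_range
    )
    n, p = X.shape

    # columns that are identically zero carry no information; pivot them out
    active = np.flatnonzero(np.abs(X).max(axis=0) > 0)
    Xa, Pa = X[:, active], P[np.ix_(active, active)]
    XtX = Xa.T @ Xa
    Xty = Xa.T @ y

    best = None
    for lam in spec.lambda_grid:
        A = XtX + lam * Pa
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            if lam == max(spec.lambda_grid):
                raise InputError("singular fit even at the largest penalty")
            continue
        theta = Ainv @ Xty
        resid = y - Xa @ theta
        rss = float(resid @ resid)
        edf = float(np.trace(Ainv @ XtX))
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * edf
        if best is None or aic < best["aic"]:
            best = {"lam": lam, "theta": theta, "Ainv": Ainv,
                    "resid": resid, "edf": edf, "aic": aic}
    if best is None:
        raise InputError("singular fit at every penalty in the grid")

    # cluster-robust sandwich: A^-1 (sum_c Xc' e_c e_c' Xc) A^-1
    resid = best["resid"]
    n_subj = int(subjects.max()) + 1
    G = np.zeros((n_subj, len(active)))
    np.add.at(G, subjects, Xa * resid[:, None])
    Ainv, lam = best["Ainv"], best["lam"]
    meat = (G.T @ G) * (n_subj / max(n_subj - 1, 1))  # CR1 cluster factor
    cov_a = Ainv @ meat @ Ainv
    # smoothing-bias-aware (Bayesian) augmentation: without it, pointwise
    # bands ignore the penalty's shrinkage bias and under-cover
    sigma2 = float(resid @ resid) / max(n - best["edf"], 1.0)
    cov_a = cov_a + lam * sigma2 * (Ainv @ Pa @ Ainv)

    theta_full = np.zeros(p)
    theta_full[active] = best["theta"]
    cov = np.zeros((p, p))
    cov[np.ix_(active, active)] = cov_a

    grid = (
        np.asarray(spec.age_grid, dtype=float)
        if spec.age_grid is not None
        else np.linspace(age_range[0], age_range[1], spec.n_grid)
    )
    Bg = bspline_basis(grid, spec.degree, spec.n_interior_knots, age_range)
    from scipy.stats import norm

    zcrit = norm.ppf(0.5 + spec.ci_level / 2)
    beta, se, lo, hi = {}, {}, {}, {}
    for name in tv_names:
        s = slices[name]
        b = Bg @ theta_full[s]
        v = np.einsum("ij,jk,ik->i", Bg, cov[s, s], Bg)
        sd = np.sqrt(np.maximum(v, 0.0))
        beta[name], se[name] = b, sd
        lo[name], hi[name] = b - zcrit * sd, b + zcrit * sd
    gamma = {name: float(theta_full[slices[name].start]) for name in inv_names}
    gamma_se = {
        name: float(np.sqrt(max(cov[slices[name].start, slices[name].start], 0.0)))
        for name in inv_names
    }
    sv = np.linalg.svd(Xa, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    return TvemFit(
        age_grid=grid,
        beta=beta,
        se=se,
        ci_lo=lo,
        ci_hi=hi,
        gamma=gamma,
        gamma_se=gamma_se,
        lambda_=float(best["lam"]),
        edf=best["edf"],
        aic=float(best["aic"]),
        ci_level=spec.ci_level,
        condition_number=cond,
        n_obs=n,
        n_subjects=len(np.unique(subjects)),
    )


def significant_intervals(fit: TvemFit) -> dict[str, list[tuple[float, float]]]:
    """Maximal age intervals where the pointwise CI excludes zero.

    Runs of grid points with ci_lo > 0 or ci_hi < 0, reported at grid
    resolution, per time-varying predictor.
    """
    if fit.age_grid.size < 50:
        raise InputError("significant_intervals needs a grid of >= 50 points")
    out: dict[str, list[tuple[float, float]]] = {}
    for name in fit.beta:
        flags = (fit.ci_lo[name] > 0) | (fit.ci_hi[name] < 0)
        intervals: list[tuple[float, float]] = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                intervals.append((float(fit.age_grid[start]),
                                  float(fit.age_grid[i - 1])))
                start = None
        if start is not None:
            intervals.append((float(fit.age_grid[start]),
                              float(fit.age_grid[-1])))
        out[name] = intervals
    return out


def subgroup_fit(
    records: Sequence[LongRecord],
    spec: TvemSpec,
    group_column: str,
) -> dict[str, TvemFit]:
    """Independent fits per level of a grouping covariate.

    Levels with fewer than 2 subjects are skipped with a warning.  No
    cross-model test is performed.
    """
    levels: dict[str, list[LongRecord]] = {}
    for r in records:
        levels.setdefault(str(r.covariates[group_column]), []).append(r)
    if len(levels) < 2:
        raise InputError(f"group column {group_column!r} has < 2 levels")
    out = {}
    for level, recs in sorted(levels.items()):
        n_subj = len({r.subject_id for r in recs})
        if n_subj < 2:
            logger.warning("group %s=%s has %d subject(s); skipped",
                           group_column, level, n_subj)
            continue
        sub_spec = TvemSpec(
            time_varying_predictors=list(spec.time_varying_predictors),
            invariant_covariates=[
                c for c in spec.invariant_covariates if c != group_column
            ],
            degree=spec.degree,
            n_interior_knots=spec.n_interior_knots,
            penalty_order=spec.penalty_order,
            lambda_grid=spec.lambda_grid,
            ci_level=spec.ci_level,
            n_grid=spec.n_grid,
            age_grid=spec.age_grid,
        )
        out[level] = fit_tvem(recs, sub_spec)
    return out
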