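"""Per-gene lifespan expression trajectories.

Expression is regressed on a natural cubic spline of age (default three
degrees of freedom, interior knots at age quantiles) plus optional
covariate columns, then interpolated on a regular age grid with the
covariates held constant.  We call the interpolated curve a lifespan
trajectory; it is the substrate for turning-point detection.

The natural-spline basis reproduces the classical construction: a cubic
B-spline basis on [min age, max age] projected onto the null space of
the second-derivative-at-boundary constraints, so the fitted curve is
linear beyond the boundary knots (no extrapolation is performed here).
A locally weighted (lowess) smoother is available behind the same
trajectory interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.interpolate import BSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datamodel import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_GRID_STEP = {"year": 0.1, "day": 1.0}


# ---------------------------------------------------------------------------
# natural cubic spline basis
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, interior_knots: np.ndarray,
                         boundary_knots: tuple[float, float]) -> np.ndarray:
    """Natural cubic spline basis (without intercept column).

    Returns an (len(x), len(interior_knots)+1) array spanning, together
    with a constant, all cubic splines on the knots that are linear
    beyond the boundary knots.
    """
    lo, hi = float(boundary_knots[0]), float(boundary_knots[1])
    interior = np.asarray(interior_knots, dtype=float)
    if interior.size and not ((interior > lo) & (interior < hi)).all():
        raise ValueError("interior knots must lie strictly inside the boundary knots")
    t = np.r_[[lo] * 4, np.sort(interior), [hi] * 4]
    nb = len(t) - 4
    x = np.asarray(x, dtype=float)
    if ((x < lo) | (x > hi)).any():
        raise ValueError("evaluation points outside the boundary knots")

    full = BSpline.design_matrix(np.clip(x, lo, hi), t, 3).toarray()
    # second derivative of every basis function at the two boundaries
    d2 = BSpline(t, np.eye(nb), 3).derivative(2)(np.array([lo, hi]))  # (2, nb)

    # drop the first B-spline column (absorbed by the model intercept),
    # then project onto the null space of the boundary constraints
    basis = full[:, 1:]
    const = d2[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return basis @ q[:, 2:]


def knots_from_quantiles(ages: np.ndarray, df: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Interior knots at the (1/df, ..., (df-1)/df) quantiles of sample
    ages; boundary knots at the age range."""
    ages = np.asarray(ages, dtype=float)
    boundary = (float(ages.min()), float(ages.max()))
    probs = np.arange(1, df) / df
    interior = np.quantile(ages, probs)
    eps = 1e-9 * max(1.0, abs(boundary[1] - boundary[0]))
    interior = np.clip(interior, boundary[0] + eps, boundary[1] - eps)
    return interior, boundary


# ---------------------------------------------------------------------------
# covariate encoding (reference-level dummies; numerics held at mean)
# ---------------------------------------------------------------------------

def _encode_covariates(cov: pd.DataFrame):
    columns, names, info = [], [], {}
    for name in cov.columns:
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            info[name] = ("numeric", float(v.mean()))
            columns.append(v)
            names.append(name)
        else:
            levels = sorted(map(str, pd.unique(col.astype(str))))
            info[name] = ("categorical", levels)
            for lev in levels[1:]:
                columns.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    X = np.column_stack(columns) if columns else np.empty((len(cov), 0))
    return X, names, info


def _fixed_covariate_row(info: dict, names: list[str],
                         fixed: dict | None) -> np.ndarray:
    fixed = dict(fixed or {})
    row = dict.fromkeys(names, 0.0)
    for name, (kind, detail) in info.items():
        if kind == "numeric":
            row[name] = float(fixed.pop(name, detail))
        else:
            levels = detail
            value = str(fixed.pop(name, levels[0]))
            if value not in levels:
                raise ValueError(f"unknown level {value!r} for covariate {name!r}")
            for lev in levels[1:]:
                row[f"{name}[{lev}]"] = 1.0 if value == lev else 0.0
    if fixed:
        raise ValueError(f"unknown covariates in covariates_fixed: {sorted(fixed)}")
    return np.array([row[n] for n in names], dtype=float)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class SplineFit:
    """Least-squares fit of expression on a natural spline of age plus
    covariates, with everything needed to interpolate."""

    feature_id: str
    df: int
    interior_knots: np.ndarray
    boundary_knots: tuple[float, float]
    coefficients: np.ndarray          # [intercept, spline..., covariates...]
    column_names: list[str]
    covariate_info: dict = field(default_factory=dict)
    covariate_names: list[str] = field(default_factory=list)

    def design(self, ages: np.ndarray, covariates_fixed: dict | None = None) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        spline = natural_spline_basis(ages, self.interior_knots, self.boundary_knots)
        cov_row = _fixed_covariate_row(self.covariate_info, self.covariate_names,
                                       covariates_fixed)
        cov = np.broadcast_to(cov_row, (len(ages), len(cov_row)))
        return np.column_stack([np.ones(len(ages)), spline, cov])

    def predict(self, ages: np.ndarray, covariates_fixed: dict | None = None) -> np.ndarray:
        return self.design(ages, covariates_fixed) @ self.coefficients

    def fitted_values(self, ages: np.ndarray, covariate_design: np.ndarray) -> np.ndarray:
        spline = natural_spline_basis(np.asarray(ages, float),
                                      self.interior_knots, self.boundary_knots)
        X = np.column_stack([np.ones(len(spline)), spline, covariate_design])
        return X @ self.coefficients


@dataclass
class LifespanTrajectory:
    """Interpolated trajectory on a regular age grid."""

    feature_id: str
    age_grid: np.ndarray
    values: np.ndarray
    grid_step: float

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.age_grid.shape != self.values.shape:
            raise ValueError("age grid and values must have equal length")
        if not np.isfinite(self.values).all():
            raise ValueError("trajectory values must be finite")
        if (np.diff(self.age_grid) <= 0).any():
            raise ValueError("age grid must be strictly increasing")


def fit_spline(ages, expression, covariates: pd.DataFrame | None = None,
               df: int = 3, feature_id: str = "") -> SplineFit:
    """Fit expression ~ natural_spline(age, df) + covariates by least squares."""
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(np.unique(ages)) < df + 2:
        raise ValueError(f"need at least df+2={df + 2} distinct ages")
    interior, boundary = knots_from_quantiles(ages, df)
    spline = natural_spline_basis(ages, interior, boundary)
    names = ["intercept"] + [f"ns{i + 1}" for i in range(spline.shape[1])]
    if covariates is not None and covariates.shape[1] > 0:
        cov_X, cov_names, info = _encode_covariates(covariates)
    else:
        cov_X, cov_names, info = np.empty((len(ages), 0)), [], {}
    X = np.column_stack([np.ones(len(ages)), spline, cov_X])
    names = names + cov_names

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, pivot = scipy.linalg.qr(X, mode="economic", pivoting=True)
        collinear = [names[j] for j in pivot[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SplineFit(feature_id=feature_id, df=df, interior_knots=interior,
                     boundary_knots=boundary, coefficients=coef,
                     column_names=names, covariate_info=info,
                     covariate_names=cov_names)


def interpolate_trajectory(fit: SplineFit, grid_step: float,
                           covariates_fixed: dict | None = None) -> LifespanTrajectory:
    """Evaluate the fitted model on a regular age grid spanning the
    boundary knots (no extrapolation)."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = fit.boundary_knots
    n = int(np.floor((hi - lo) / grid_step + 1e-9)) + 1
    grid = lo + grid_step * np.arange(n)
    values = fit.predict(grid, covariates_fixed)
    return LifespanTrajectory(fit.feature_id, grid, values, grid_step)


def loess_trajectory(ages, expression, grid_step: float, span: float = 0.75,
                     feature_id: str = "") -> LifespanTrajectory:
    """Locally weighted alternative smoother behind the same interface."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(expression, dtype=float)
    lo, hi = float(ages.min()), float(ages.max())
    n = int(np.floor((hi - lo) / grid_step + 1e-9)) + 1
    grid = lo + grid_step * np.arange(n)
    values = lowess(y, ages, frac=span, xvals=grid)
    return LifespanTrajectory(feature_id, grid, values, grid_step)


# ---------------------------------------------------------------------------
# dataset-level convenience
# ---------------------------------------------------------------------------

def fit_dataset(ds: ExpressionDataset, df: int = 3,
                covariates: list[str] | None = None) -> dict[str, SplineFit]:
    """Fit one spline per feature.  ``covariates`` names columns of
    ``ds.samples`` (e.g. ["sex", "strain"]); default none, matching
    inputs whose extraneous variation was already adjusted upstream."""
    cov = ds.samples[covariates] if covariates else None
    ages = ds.sample_age
    fits = {}
    for fid in ds.feature_ids:
        fits[fid] = fit_spline(ages, ds.values.loc[fid].to_numpy(dtype=float),
                               covariates=cov, df=df, feature_id=str(fid))
    return fits


def dataset_trajectories(ds: ExpressionDataset, df: int = 3,
                         covariates: list[str] | None = None,
                         grid_step: float | None = None,
                         smoother: str = "spline", span: float = 0.75,
                         covariates_fixed: dict | None = None,
                         ) -> dict[str, LifespanTrajectory]:
    """Fit and interpolate every feature of a dataset."""
    if grid_step is None:
        grid_step = DEFAULT_GRID_STEP[ds.age_unit]
    if smoother == "loess":
        ages = ds.sample_age
        return {str(fid): loess_trajectory(ages, ds.values.loc[fid].to_numpy(float),
                                           grid_step, span=span, feature_id=str(fid))
                for fid in ds.feature_ids}
    if smoother != "spline":
        raise ValueError(f"unknown smoother {smoother!r}")
    fits = fit_dataset(ds, df=df, covariates=covariates)
    return {fid: interpolate_trajectory(fit, grid_step, covariates_fixed)
            for fid, fit in fits.items()}
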