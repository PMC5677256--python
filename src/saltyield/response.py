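"""Fitting crop response models from site-level trial data.

Estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params``, fitted attributes with a trailing underscore) so they
compose with pipelines and model selection:

* :class:`FullYieldRegression` — OLS (optionally distance-decay GLS) fit of
  the full polynomial yield model.
* :class:`TwoPieceSaltTolerance` — threshold/slope salt tolerance curve via
  deterministic breakpoint grid search.
* :class:`ThreePieceBoronTolerance` — deficiency/optimum/toxicity boron
  curve via grid search over both thresholds.
* :class:`QuadraticTolerance` — least-squares quadratic dose-response.

Module-level functions (:func:`fit_yield_regression`, :func:`backward_select`,
:func:`fit_two_piece_salt`, :func:`fit_three_piece_boron`,
:func:`fit_quadratic_tolerance`) are thin wrappers over the estimators,
returning plain parameter objects.

Breakpoints are estimated by grid search rather than derivative-based
segmented regression: the objective is piecewise-smooth with many local
minima, and a grid is deterministic and exactly reproducible.  Within a
candidate breakpoint the plateau is fixed at 100% and the declining slope has
a closed-form least-squares solution, so the search is exact over the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    NoDeclineDetectedError,
    SegmentUnderdeterminedError,
    SingularDesignError,
    UnderdeterminedError,
)
from .params import (
    BoronToleranceParams,
    QuadraticToleranceParams,
    SaltToleranceParams,
    YieldModelCoefficients,
)
from .yield_models import argmax_quadratic, relative_yield_boron, relative_yield_salt

__all__ = [
    "FitResult",
    "FullYieldRegression",
    "TwoPieceSaltTolerance",
    "ThreePieceBoronTolerance",
    "QuadraticTolerance",
    "fit_yield_regression",
    "backward_select",
    "fit_two_piece_salt",
    "fit_three_piece_boron",
    "fit_quadratic_tolerance",
]

#: Canonical design terms of the full model, in fixed order (also the
#: deterministic tie-break order for backward selection).
FULL_MODEL_TERMS = ("boron", "boron_sq", "ec_e", "ec_e_sq", "lf", "theta_g")

_SQUARES = {"boron_sq": "boron", "ec_e_sq": "ec_e"}


@dataclass
class FitResult:
    """Outcome of a least-squares regression fit.

    Houses the random error component of the yield model: ``residuals`` are
    the fitted epsilon-hats.
    """

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    residuals: np.ndarray
    terms: tuple[str, ...]
    nobs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"R^2 out of [0, 1]: {self.r_squared}")

    @property
    def coefficients(self) -> YieldModelCoefficients:
        """Coefficients as a :class:`YieldModelCoefficients` (full-model terms only)."""
        if tuple(self.terms) != FULL_MODEL_TERMS:
            raise ValueError(
                "coefficients are only defined for the full six-term model; "
                f"fitted terms were {self.terms}"
            )
        p = self.params
        return YieldModelCoefficients(
            beta0=float(p["const"]),
            beta1=float(p["boron"]),
            beta2=float(p["boron_sq"]),
            beta3=float(p["ec_e"]),
            beta4=float(p["ec_e_sq"]),
            beta5=float(p["lf"]),
            beta6=float(p["theta_g"]),
            strict=False,
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "tvalues": self.tvalues.to_dict(),
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "nobs": self.nobs,
        }


def _design(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Build the design matrix (with intercept) for the given terms."""
    cols = {}
    for t in terms:
        base = _SQUARES.get(t)
        cols[t] = data[base] ** 2 if base is not None else data[t]
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank deficient (constant or collinear regressor)"
        )


def _spatial_sigma(data: pd.DataFrame, spatial_range: float) -> np.ndarray:
    xy = data[["x_m", "y_m"]].to_numpy(float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    return np.exp(-d / spatial_range)


class FullYieldRegression(RegressorMixin, BaseEstimator):
    """Least-squares fit of the full polynomial yield model.

    Parameters
    ----------
    truncate : bool
        Truncate predictions below at 0 kg/ha.
    spatial_range : float or None
        If set, refit by generalized least squares with an exponential
        distance-decay error correlation exp(-d / range) built from the
        site coordinates passed to :meth:`fit`.  This is a pragmatic
        stand-in for a spatially-adjusted likelihood fit and is documented
        as an assumption; the default path is plain OLS.

    Attributes
    ----------
    coefficients_ : YieldModelCoefficients
    result_ : FitResult
    """

    def __init__(self, truncate: bool = True, spatial_range: float | None = None):
        self.truncate = truncate
        self.spatial_range = spatial_range

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError(
                "X must be (n, 4) with columns (boron, ec_e, lf, theta_g)"
            )
        return pd.DataFrame(X, columns=["boron", "ec_e", "lf", "theta_g"])

    def fit(self, X, y, coords: np.ndarray | None = None):
        data = self._frame(X).copy()
        y = np.asarray(y, dtype=float)
        if len(y) != len(data):
            raise ValueError("X and y lengths differ")
        design = _design(data, FULL_MODEL_TERMS)
        _check_rank(design)
        if self.spatial_range is not None:
            if coords is not None:
                data = data.assign(x_m=coords[:, 0], y_m=coords[:, 1])
            sigma = _spatial_sigma(data, self.spatial_range)
            model = sm.GLS(y, design, sigma=sigma)
        else:
            model = sm.OLS(y, design)
        res = model.fit()
        self.result_ = FitResult(
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            r_squared=float(res.rsquared),
            r_squared_adj=float(res.rsquared_adj),
            residuals=np.asarray(res.resid, dtype=float),
            terms=FULL_MODEL_TERMS,
            nobs=int(res.nobs),
        )
        self.coefficients_ = self.result_.coefficients
        return self

    @classmethod
    def from_coefficients(
        cls, coeffs: YieldModelCoefficients | None = None
    ) -> "FullYieldRegression":
        """Pre-fitted estimator wrapping known coefficients (no data needed)."""
        est = cls()
        est.coefficients_ = coeffs or YieldModelCoefficients()
        return est

    def predict(self, X) -> np.ndarray:
        from .yield_models import full_polynomial

        data = self._frame(X)
        raw = full_polynomial(
            data["boron"], data["ec_e"], data["lf"], data["theta_g"],
            self.coefficients_,
        )
        raw = np.asarray(raw, dtype=float)
        return np.maximum(raw, 0.0) if self.truncate else raw


def fit_yield_regression(
    data: pd.DataFrame, spatial_range: float | None = None
) -> FitResult:
    """Fit the full yield regression to a site-level trial table.

    Sites with zero yield are excluded (they carry no information about the
    response surface of a growing crop).  Requires at least 10 usable sites.
    """
    usable = data[data["yield_kg_ha"] > 0].dropna(
        subset=["boron", "ec_e", "lf", "theta_g"]
    )
    if len(usable) < 10:
        raise ValueError(
            f"need >= 10 sites with positive yield and complete regressors, "
            f"got {len(usable)}"
        )
    est = FullYieldRegression(spatial_range=spatial_range)
    coords = None
    if spatial_range is not None:
        coords = usable[["x_m", "y_m"]].to_numpy(float)
    est.fit(usable[["boron", "ec_e", "lf", "theta_g"]], usable["yield_kg_ha"],
            coords=coords)
    return est.result_


def backward_select(
    data: pd.DataFrame,
    candidates=None,
    t_threshold: float = 1.8,
) -> tuple[list[str], FitResult]:
    """Backward t-screening of candidate predictors.

    Iteratively refits, dropping the predictor with the smallest absolute
    t-score while that score is below ``t_threshold``.  Ties break by the
    fixed candidate ordering (first listed is dropped first).  Returns the
    retained terms and the final fit; if nothing survives, an intercept-only
    fit is returned with a warning.
    """
    terms = list(candidates) if candidates is not None else list(FULL_MODEL_TERMS)
    missing = [t for t in FULL_MODEL_TERMS if t not in terms]
    if missing:
        raise ValueError(f"candidate set must include the full-model terms; missing {missing}")
    usable = data[data["yield_kg_ha"] > 0].dropna(
        subset=list({_SQUARES.get(t, t) for t in terms})
    )
    y = usable["yield_kg_ha"].to_numpy(float)

    def _fit(current) -> tuple[FitResult, sm.regression.linear_model.RegressionResults]:
        X = _design(usable, current)
        _check_rank(X)
        res = sm.OLS(y, X).fit()
        fr = FitResult(
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            r_squared=float(res.rsquared),
            r_squared_adj=float(res.rsquared_adj),
            residuals=np.asarray(res.resid, dtype=float),
            terms=tuple(current),
            nobs=int(res.nobs),
        )
        return fr, res

    current = list(terms)
    while current:
        fr, _ = _fit(current)
        tvals = fr.tvalues.drop("const").abs()
        # evaluate in fixed candidate order so ties are deterministic
        ordered = tvals.reindex(current)
        weakest = ordered.idxmin()
        if ordered[weakest] >= t_threshold:
            return current, fr
        current.remove(weakest)

    warnings.warn(
        "no predictor survived backward selection; returning intercept-only fit",
        stacklevel=2,
    )
    X = sm.add_constant(pd.DataFrame(index=usable.index), has_constant="add")
    res = sm.OLS(y, X).fit()
    fr = FitResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        r_squared=float(res.rsquared),
        r_squared_adj=min(float(res.rsquared_adj), float(res.rsquared)),
        residuals=np.asarray(res.resid, dtype=float),
        terms=(),
        nobs=int(res.nobs),
    )
    return [], fr


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Grid of multiples of ``step`` covering [lo, hi]."""
    start = np.ceil(lo / step) * step
    if start > hi:
        return np.array([lo])
    return np.arange(start, hi + 0.5 * step, step)


def _decline_fit(dev: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """LS slope of dev ~ s * w through the origin and its SSE."""
    denom = float(w @ w)
    s = float(w @ dev) / denom
    resid = dev - s * w
    return s, float(resid @ resid)


class TwoPieceSaltTolerance(BaseEstimator):
    """Threshold/slope salt tolerance curve fitted by breakpoint grid search.

    The plateau is fixed at 100% relative yield; for each candidate
    threshold on a grid of ``grid_step`` multiples the declining slope is
    the closed-form least-squares solution over points beyond the
    threshold, and the pair minimising total squared error wins.

    Attributes
    ----------
    threshold_ : float, slope_ : float, sse_ : float
    params_ : SaltToleranceParams
    """

    def __init__(self, grid_step: float = 0.05, min_points_decline: int = 1):
        self.grid_step = grid_step
        self.min_points_decline = min_points_decline

    def fit(self, ec_e, relative_yield):
        x = np.asarray(ec_e, dtype=float).ravel()
        r = np.asarray(relative_yield, dtype=float).ravel()
        if len(x) < 4:
            raise ValueError("need at least 4 points to fit a two-piece curve")
        dev = 100.0 - r
        best = None
        for a in _grid(x.min(), x.max(), self.grid_step):
            above = x > a
            if above.sum() < self.min_points_decline:
                continue
            s, sse_above = _decline_fit(dev[above], x[above] - a)
            if s <= 0:
                continue
            sse = sse_above + float(dev[~above] @ dev[~above])
            if best is None or sse < best[0] - 1e-12:
                best = (sse, a, s)
        if best is None:
            raise NoDeclineDetectedError(
                "no candidate threshold produced a positive decline slope"
            )
        self.sse_, self.threshold_, self.slope_ = best
        self.params_ = SaltToleranceParams(self.threshold_, self.slope_)
        return self

    def predict(self, ec_e):
        return relative_yield_salt(ec_e, self.params_)


class ThreePieceBoronTolerance(BaseEstimator):
    """Deficiency/optimum/toxicity boron tolerance curve via grid search.

    The total squared error separates into a deficiency-side term depending
    only on the lower threshold, a toxicity-side term depending only on the
    upper threshold, and a constant, so the two thresholds are searched
    independently; if the independent minimisers cross, the constrained
    joint minimum over the same grids is taken instead.
    """

    def __init__(self, grid_step: float = 0.05, min_points_side: int = 2):
        self.grid_step = grid_step
        self.min_points_side = min_points_side

    def _side_profile(self, x, dev, grid, side: str):
        """Per-candidate (objective, slope) for one declining side.

        The objective is that side's SSE minus the plateau SSE of the same
        points, so plateau membership changes are accounted for.
        """
        obj = np.full(len(grid), np.inf)
        slope = np.full(len(grid), np.nan)
        for i, t in enumerate(grid):
            mask = x < t if side == "deficiency" else x > t
            if mask.sum() < self.min_points_side:
                continue
            w = (t - x[mask]) if side == "deficiency" else (x[mask] - t)
            s, sse = _decline_fit(dev[mask], w)
            if s <= 0:
                continue
            obj[i] = sse - float(dev[mask] @ dev[mask])
            slope[i] = s
        return obj, slope

    def fit(self, b, relative_yield):
        x = np.asarray(b, dtype=float).ravel()
        r = np.asarray(relative_yield, dtype=float).ravel()
        dev = 100.0 - r
        grid = _grid(x.min(), x.max(), self.grid_step)
        obj_lo, slope_lo = self._side_profile(x, dev, grid, "deficiency")
        obj_hi, slope_hi = self._side_profile(x, dev, grid, "toxicity")
        if not np.isfinite(obj_lo).any() or not np.isfinite(obj_hi).any():
            raise SegmentUnderdeterminedError(
                "need at least {n} points with positive decline on each side "
                "of the plateau".format(n=self.min_points_side)
            )
        i_lo, i_hi = int(np.argmin(obj_lo)), int(np.argmin(obj_hi))
        if grid[i_lo] >= grid[i_hi]:
            # independent minimisers crossed: constrained joint minimum
            total = obj_lo[:, None] + obj_hi[None, :]  # rows t_def, cols t_tox
            total[np.tril_indices(len(grid))] = np.inf  # need t_def < t_tox
            i_lo, i_hi = map(int, np.unravel_index(np.argmin(total), total.shape))
            if not np.isfinite(total[i_lo, i_hi]):
                raise SegmentUnderdeterminedError(
                    "no ordered threshold pair with declining sides found"
                )
        self.deficiency_threshold_ = float(grid[i_lo])
        self.toxicity_threshold_ = float(grid[i_hi])
        self.deficiency_slope_ = float(slope_lo[i_lo])
        self.toxicity_slope_ = float(slope_hi[i_hi])
        self.sse_ = float(obj_lo[i_lo] + obj_hi[i_hi] + dev @ dev)
        self.params_ = BoronToleranceParams(
            deficiency_threshold=self.deficiency_threshold_,
            toxicity_threshold=self.toxicity_threshold_,
            toxicity_slope=self.toxicity_slope_,
            deficiency_slope=self.deficiency_slope_,
        )
        return self

    def predict(self, b):
        return relative_yield_boron(b, self.params_)


class QuadraticTolerance(RegressorMixin, BaseEstimator):
    """Least-squares quadratic dose-response curve Y = c0 + c1 x + c2 x^2."""

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if len(np.unique(x)) < 3:
            raise UnderdeterminedError(
                "need at least 3 distinct stressor values for a quadratic fit"
            )
        c2, c1, c0 = np.polyfit(x, y, 2)
        self.params_ = (
            QuadraticToleranceParams(c0, c1, c2) if c2 < 0 else None
        )
        self.coef_ = (float(c0), float(c1), float(c2))
        fitted = c0 + c1 * x + c2 * x**2
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r_squared_ = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        self.vertex_ = argmax_quadratic((c1, c2)) if c2 < 0 else None
        return self

    def predict(self, x):
        c0, c1, c2 = self.coef_
        x = np.asarray(x, dtype=float)
        return np.maximum(c0 + c1 * x + c2 * x**2, 0.0)


def fit_two_piece_salt(ec_e, relative_yield, grid_step: float = 0.05):
    """Fit the two-piece salt tolerance curve; returns (params, sse)."""
    est = TwoPieceSaltTolerance(grid_step=grid_step).fit(ec_e, relative_yield)
    return est.params_, est.sse_


def fit_three_piece_boron(b, relative_yield, grid_step: float = 0.05):
    """Fit the three-piece boron tolerance curve; returns (params, sse)."""
    est = ThreePieceBoronTolerance(grid_step=grid_step).fit(b, relative_yield)
    return est.params_, est.sse_


def fit_quadratic_tolerance(x, y):
    """Fit a quadratic dose-response; returns (params-or-None, r_squared, vertex)."""
    est = QuadraticTolerance().fit(x, y)
    return est.params_, est.r_squared_, est.vertex_
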