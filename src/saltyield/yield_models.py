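"""Crop response models and the model-selection hierarchy.

The full yield model is a concave polynomial in boron and salinity with
linear leaching-fraction and water-content terms.  Where its inputs are
incomplete or out of the fitted range, the classical tolerance curves take
over: the two-piece linear (threshold/slope) salt tolerance model, a
three-piece linear boron tolerance model with an optimum plateau, or their
quadratic counterparts.  When both salinity and boron curves apply, the more
limiting (smaller) response governs.

All yield outputs are truncated below at zero — a negative polynomial value
has no physical meaning and would corrupt regional production totals.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingInputError, NoInteriorMaximumError
from .params import (
    BASELINE_PROFILE,
    REGRESSOR_NAMES,
    TABLE2B_SDS,
    Y_MAX_DEFAULT,
    BoronToleranceParams,
    ConversionParams,
    CurveFamily,
    EdaphicProfile,
    ModelChoice,
    QuadraticToleranceParams,
    SaltToleranceParams,
    YieldModelCoefficients,
)

__all__ = [
    "predict_yield_full",
    "full_polynomial",
    "relative_yield_salt",
    "relative_yield_boron",
    "predict_yield_quadratic",
    "argmax_quadratic",
    "zero_yield_threshold",
    "select_model",
    "predict_field_yield",
    "sensitivity_analysis",
]


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _ret(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def full_polynomial(
    boron, ec_e, lf, theta_g, coeffs: YieldModelCoefficients | None = None
):
    """Raw (untruncated) full-model polynomial; vectorised over its inputs."""
    c = coeffs or YieldModelCoefficients()
    b = np.asarray(boron, dtype=float)
    e = np.asarray(ec_e, dtype=float)
    return (
        c.beta0
        + c.beta1 * b
        + c.beta2 * b**2
        + c.beta3 * e
        + c.beta4 * e**2
        + c.beta5 * np.asarray(lf, dtype=float)
        + c.beta6 * np.asarray(theta_g, dtype=float)
    )


def predict_yield_full(
    profile: EdaphicProfile, coeffs: YieldModelCoefficients | None = None
) -> float:
    """Oilseed yield (kg/ha) from the full regression model.

    Requires all four regressors present; raises
    :class:`~saltyield.exceptions.MissingInputError` naming the first absent
    one.  The polynomial is truncated below at zero.
    """
    for name in REGRESSOR_NAMES:
        if not profile.available(name):
            raise MissingInputError(name)
    raw = full_polynomial(
        profile.boron, profile.ec_e, profile.lf, profile.theta_g, coeffs
    )
    return float(max(raw, 0.0))


def relative_yield_salt(ec_e, params: SaltToleranceParams | None = None):
    """Relative yield (%) from the two-piece linear salt tolerance model.

    100% on the plateau (EC_e <= threshold), declining at ``slope_b`` percent
    per dS/m beyond it, floored at 0.  Vectorised.
    """
    p = params or SaltToleranceParams()
    e, scalar = _as_array(ec_e)
    rel = 100.0 - p.slope_b * np.maximum(e - p.threshold_a, 0.0)
    return _ret(np.clip(rel, 0.0, 100.0), scalar)


def relative_yield_boron(b, params: BoronToleranceParams | None = None):
    """Relative yield (%) from the three-piece linear boron tolerance model.

    100% on the optimum plateau, linear decline below the deficiency
    threshold and above the toxicity threshold, floored at 0.  Vectorised.
    """
    p = params or BoronToleranceParams()
    x, scalar = _as_array(b)
    rel = (
        100.0
        - p.deficiency_slope * np.maximum(p.deficiency_threshold - x, 0.0)
        - p.toxicity_slope * np.maximum(x - p.toxicity_threshold, 0.0)
    )
    return _ret(np.clip(rel, 0.0, 100.0), scalar)


def predict_yield_quadratic(x, params: QuadraticToleranceParams):
    """Absolute yield (kg/ha) from a quadratic single-stressor curve, floored at 0."""
    v, scalar = _as_array(x)
    raw = params.c0 + params.c1 * v + params.c2 * v**2
    return _ret(np.maximum(raw, 0.0), scalar)


def argmax_quadratic(params) -> float:
    """Stressor value at the curve's interior maximum, -c1 / (2 c2).

    Accepts a :class:`QuadraticToleranceParams` or a ``(linear, quadratic)``
    coefficient pair (e.g. the B or EC_e pair of the full model).
    """
    if isinstance(params, QuadraticToleranceParams):
        linear, quadratic = params.c1, params.c2
    else:
        linear, quadratic = params
    if quadratic >= 0:
        raise NoInteriorMaximumError(
            f"quadratic coefficient {quadratic} is non-negative; "
            "the curve has no interior maximum"
        )
    return -linear / (2.0 * quadratic)


def zero_yield_threshold(params) -> float:
    """Stressor value at which the declining (toxicity) limb reaches zero yield.

    ``threshold + 100 / slope`` on the toxicity side of a
    :class:`SaltToleranceParams` or :class:`BoronToleranceParams`.
    """
    if isinstance(params, SaltToleranceParams):
        return params.threshold_a + 100.0 / params.slope_b
    if isinstance(params, BoronToleranceParams):
        return params.toxicity_threshold + 100.0 / params.toxicity_slope
    raise TypeError(f"unsupported tolerance parameter type: {type(params)!r}")


def select_model(
    profile: EdaphicProfile,
    coeffs: YieldModelCoefficients | None = None,
    texture: str = "fine",
) -> ModelChoice:
    """Choose the yield model a location's data can support.

    The full regression applies only when all four regressors are present,
    each inside its fitted applicability range, and the soil texture is fine
    (the model was developed on a fine-textured field).  Otherwise the
    tolerance curves are used over whichever of EC_e and B are available;
    with neither, conditions are assumed optimal for yield.
    """
    c = coeffs or YieldModelCoefficients()
    has = {name: profile.available(name) for name in REGRESSOR_NAMES}
    if all(has.values()) and texture == "fine":
        if all(c.in_range(name, profile.get(name)) for name in REGRESSOR_NAMES):
            return ModelChoice.FULL_MODEL
    if has["boron"]:
        # EC_e and B, or B alone: most-limiting rule over what is available.
        return ModelChoice.TOLERANCE_MOST_LIMITING
    if has["ec_e"]:
        return ModelChoice.SALT_TOLERANCE_ONLY
    return ModelChoice.OPTIMAL


def predict_field_yield(
    profile: EdaphicProfile,
    choice: ModelChoice,
    coeffs: YieldModelCoefficients | None = None,
    salt_params: SaltToleranceParams | None = None,
    boron_params: BoronToleranceParams | None = None,
    *,
    y_max: float = Y_MAX_DEFAULT,
    curve_family: CurveFamily = CurveFamily.PIECEWISE,
    quad_salt: QuadraticToleranceParams | None = None,
    quad_boron: QuadraticToleranceParams | None = None,
) -> float:
    """Oilseed yield (kg/ha) for one location under the selected model.

    Tolerance-curve relative yields are scaled by ``y_max`` (the plateau
    yield); the quadratic family predicts absolute yield directly.  The
    most-limiting rule takes the minimum over the available stressor curves.
    """
    if choice is ModelChoice.FULL_MODEL:
        return predict_yield_full(profile, coeffs)
    if choice is ModelChoice.OPTIMAL:
        return float(y_max)

    if curve_family is CurveFamily.QUADRATIC:
        qs = quad_salt or QuadraticToleranceParams.salt_default()
        qb = quad_boron or QuadraticToleranceParams.boron_default()
        candidates = []
        if profile.available("ec_e"):
            candidates.append(predict_yield_quadratic(profile.ec_e, qs))
        if choice is ModelChoice.TOLERANCE_MOST_LIMITING and profile.available("boron"):
            candidates.append(predict_yield_quadratic(profile.boron, qb))
        if not candidates:
            raise MissingInputError("ec_e")
        return float(min(candidates))

    rels = []
    if profile.available("ec_e"):
        rels.append(relative_yield_salt(profile.ec_e, salt_params))
    if choice is ModelChoice.TOLERANCE_MOST_LIMITING and profile.available("boron"):
        rels.append(relative_yield_boron(profile.boron, boron_params))
    if not rels:
        raise MissingInputError("ec_e")
    return float(y_max * min(rels) / 100.0)


def sensitivity_analysis(
    coeffs: YieldModelCoefficients | None = None,
    baseline: EdaphicProfile | None = None,
    sds: Mapping[str, float] | None = None,
    conversion: ConversionParams | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of the full yield model to +1 SD shifts.

    Each regressor is shifted one standard deviation above the baseline
    (others held at baseline) and the yield, biofuel volume and percent
    change relative to baseline are tabulated.  Defaults: baseline at the
    points of maximum yield for B and EC_e and at the trial means for LF and
    theta_g; SDs from the trial marginals.

    Returns a DataFrame with columns
    ``scenario, yield_kg_ha, biofuel_L_ha, pct_change, B, ECe, LF, theta_g``.
    """
    from .simulation import biofuel_mass_to_volume, oilseed_to_biofuel_mass

    c = coeffs or YieldModelCoefficients()
    base = baseline or EdaphicProfile(*BASELINE_PROFILE)
    sd = dict(TABLE2B_SDS if sds is None else sds)
    conv = conversion or ConversionParams()

    labels = {
        "boron": "B + 1 SD",
        "ec_e": "EC_e + 1 SD",
        "lf": "LF + 1 SD",
        "theta_g": "theta_g + 1 SD",
    }
    rows = []
    base_vals = {name: base.get(name) for name in REGRESSOR_NAMES}
    base_yield = predict_yield_full(base, c)
    scenarios = [("Baseline", dict(base_vals))]
    for name in REGRESSOR_NAMES:
        shifted = dict(base_vals)
        shifted[name] = base_vals[name] + sd[name]
        scenarios.append((labels[name], shifted))

    for label, vals in scenarios:
        y = predict_yield_full(EdaphicProfile(**vals), c)
        vol = biofuel_mass_to_volume(oilseed_to_biofuel_mass(y, conv), conv)
        pct = np.nan if label == "Baseline" else 100.0 * (y - base_yield) / base_yield
        rows.append(
            {
                "scenario": label,
                "yield_kg_ha": y,
                "biofuel_L_ha": vol,
                "pct_change": pct,
                "B": vals["boron"],
                "ECe": vals["ec_e"],
                "LF": vals["lf"],
                "theta_g": vals["theta_g"],
            }
        )
    return pd.DataFrame(rows)
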