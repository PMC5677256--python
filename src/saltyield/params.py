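"""Domain types and published default parameters.

Holds the building blocks of the Ida Gold mustard (*Sinapis alba* L.) oilseed
yield analysis on salt-affected soils: the root-zone edaphic profile that
drives yield, the fitted full-regression coefficients, the piecewise and
quadratic salt/boron tolerance curve parameters, and the oilseed-to-biofuel
conversion constants.  Every numeric default is a published constant of the
underlying field study; all of them are also mirrored in the versioned config
emitted by :func:`saltyield.io.default_config` so downstream runs can pin to
configuration rather than code literals.

Units
-----
* EC_e   — electrical conductivity of the saturation extract, dS/m
* B      — boron concentration in the saturation extract, mg/L
* LF     — leaching fraction, dimensionless in [0, 1]
* theta_g — gravimetric water content, kg/kg
* yield  — oilseed yield, kg/ha
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

__all__ = [
    "EdaphicProfile",
    "YieldModelCoefficients",
    "SaltToleranceParams",
    "BoronToleranceParams",
    "QuadraticToleranceParams",
    "ConversionParams",
    "ModelChoice",
    "CurveFamily",
    "REGRESSOR_NAMES",
    "TABLE2B_MEANS",
    "TABLE2B_SDS",
    "TABLE2B_RANGES",
    "BASELINE_PROFILE",
    "Y_MAX_DEFAULT",
    "TARGET_PRODUCTION_ML",
]

#: Names of the four yield-model regressors, in canonical order.
REGRESSOR_NAMES = ("boron", "ec_e", "lf", "theta_g")

#: Trial marginal means over the 34 sites with non-zero yield (0-1.2 m composite).
TABLE2B_MEANS: Mapping[str, float] = {
    "boron": 10.03,
    "ec_e": 9.97,
    "lf": 0.27,
    "theta_g": 0.19,
}

#: Trial marginal standard deviations (same 34 sites).
TABLE2B_SDS: Mapping[str, float] = {
    "boron": 6.06,
    "ec_e": 6.29,
    "lf": 0.15,
    "theta_g": 0.05,
}

#: Observed min/max of each regressor in the trial — the applicability range
#: of the full regression model.
TABLE2B_RANGES: Mapping[str, tuple[float, float]] = {
    "boron": (2.14, 24.24),
    "ec_e": (1.84, 29.97),
    "lf": (0.08, 0.61),
    "theta_g": (0.12, 0.25),
}

#: Reference profile for the sensitivity analysis: B and EC_e at their points
#: of maximum yield, LF and theta_g at their trial means.
BASELINE_PROFILE = (4.0, 6.8, 0.27, 0.19)

#: Default plateau yield (kg/ha) used to convert relative tolerance-model
#: yields to absolute yields: the vertex value of the quadratic salt
#: tolerance curve, 74.0 + 254.6^2 / (4 * 18.8) = 936.0.
Y_MAX_DEFAULT = 936.0

#: Annual biofuel production (ML/yr) needed to support a conversion facility.
TARGET_PRODUCTION_ML = 115.0


class ModelChoice(Enum):
    """Which yield model applies at a field, by data availability."""

    FULL_MODEL = "full_model"
    TOLERANCE_MOST_LIMITING = "tolerance_most_limiting"
    SALT_TOLERANCE_ONLY = "salt_tolerance_only"
    OPTIMAL = "optimal"


class CurveFamily(Enum):
    """Tolerance curve family used when the full model does not apply."""

    PIECEWISE = "piecewise"
    QUADRATIC = "quadratic"


def _check_nonneg(name: str, value: float | None, upper: float | None = None) -> None:
    if value is None:
        return
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")
    if upper is not None and value > upper:
        raise ValueError(f"{name} must be <= {upper}, got {value}")


@dataclass(frozen=True)
class EdaphicProfile:
    """Composite root-zone (0-1.2 m) edaphic state at one location.

    Any regressor may be ``None`` when no measurement or prediction is
    available; model selection reads availability from that.
    """

    boron: float | None = None
    ec_e: float | None = None
    lf: float | None = None
    theta_g: float | None = None

    def __post_init__(self) -> None:
        _check_nonneg("boron", self.boron)
        _check_nonneg("ec_e", self.ec_e)
        _check_nonneg("lf", self.lf, upper=1.0)
        _check_nonneg("theta_g", self.theta_g, upper=1.0)

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def available(self, name: str) -> bool:
        return getattr(self, name) is not None


@dataclass(frozen=True)
class YieldModelCoefficients:
    """Coefficients of the full oilseed yield regression.

    yield = beta0 + beta1*B + beta2*B^2 + beta3*EC_e + beta4*EC_e^2
            + beta5*LF + beta6*theta_g

    Defaults are the published spatially-adjusted fit; ``ranges`` bounds the
    regressor space over which the regression is considered applicable
    (inclusive endpoints).
    """

    beta0: float = 30.1
    beta1: float = 146.4
    beta2: float = -18.3
    beta3: float = 83.0
    beta4: float = -6.1
    beta5: float = 1301.0
    beta6: float = 319.8
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE2B_RANGES)
    )
    #: enforce the concave-response invariant; estimators constructing
    #: coefficients from noisy fits set this to False
    strict: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strict and (self.beta2 >= 0 or self.beta4 >= 0):
            raise ValueError(
                "quadratic coefficients beta2 and beta4 must be negative "
                "for a concave yield response"
            )

    @property
    def is_concave(self) -> bool:
        return self.beta2 < 0 and self.beta4 < 0

    def in_range(self, name: str, value: float) -> bool:
        lo, hi = self.ranges[name]
        return lo <= value <= hi

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.beta0,
            self.beta1,
            self.beta2,
            self.beta3,
            self.beta4,
            self.beta5,
            self.beta6,
        )


@dataclass(frozen=True)
class SaltToleranceParams:
    """Two-piece linear (threshold/slope) salt tolerance parameters.

    ``threshold_a`` is the maximum root-zone salinity with no yield loss
    (dS/m); ``slope_b`` is the percent yield decrement per dS/m beyond it.
    """

    threshold_a: float = 8.3
    slope_b: float = 17.0

    def __post_init__(self) -> None:
        if self.threshold_a <= 0 or self.slope_b <= 0:
            raise ValueError("threshold_a and slope_b must be positive")


@dataclass(frozen=True)
class BoronToleranceParams:
    """Three-piece linear boron tolerance parameters.

    Yield is optimal on [deficiency_threshold, toxicity_threshold] mg/L and
    declines linearly on either side.  The published toxicity side drops 28%
    per mg/L; the deficiency-side slope is not published and defaults to the
    slope implied by zero yield at B = 0 rising to 100% at 4.2 mg/L.
    """

    deficiency_threshold: float = 4.2
    toxicity_threshold: float = 8.0
    toxicity_slope: float = 28.0
    deficiency_slope: float = 100.0 / 4.2

    def __post_init__(self) -> None:
        if self.deficiency_threshold >= self.toxicity_threshold:
            raise ValueError("deficiency_threshold must be < toxicity_threshold")
        if self.toxicity_slope <= 0 or self.deficiency_slope <= 0:
            raise ValueError("slopes must be positive")


@dataclass(frozen=True)
class QuadraticToleranceParams:
    """Quadratic single-stressor yield curve: Y = c0 + c1*x + c2*x^2 (kg/ha)."""

    c0: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.c2 >= 0:
            raise ValueError("c2 must be negative for a concave response")

    @classmethod
    def salt_default(cls) -> "QuadraticToleranceParams":
        """Published quadratic salt tolerance curve (R^2 = 0.87)."""
        return cls(74.0, 254.6, -18.8)

    @classmethod
    def boron_default(cls) -> "QuadraticToleranceParams":
        """Published quadratic boron tolerance curve (R^2 = 0.90)."""
        return cls(-418.0, 555.2, -42.4)


@dataclass(frozen=True)
class ConversionParams:
    """Oilseed-to-biofuel conversion chain.

    1000 kg/ha of oilseed at 26% oil content and 64% extraction efficiency
    gives 166.4 kg/ha of biofuel, equal to 175.3 L/ha; the volumetric factor
    is stored as that printed ratio rather than an assumed fuel density.
    """

    oil_content_fraction: float = 0.26
    extraction_efficiency: float = 0.64
    liters_per_kg_biofuel: float = 175.3 / 166.4

    def __post_init__(self) -> None:
        for name in ("oil_content_fraction", "extraction_efficiency"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.liters_per_kg_biofuel <= 0:
            raise ValueError("liters_per_kg_biofuel must be positive")
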