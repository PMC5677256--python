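"""Regional field records, input uncertainty PDFs and filters.

A regional simulation treats the agricultural field as its unit: each field
carries an area, a remotely-predicted mean root-zone salinity, texture and
land-cover flags, and (when known) per-field distribution parameters or
survey-database bounds for boron, leaching fraction and water content.

Two uncertainty layers feed the Monte Carlo engine:

* Salinity prediction residuals, tabulated per 1 dS/m category of predicted
  EC_e (category means grow strongly positive above ~11 dS/m — the regional
  model over-predicts high salinity).  Residuals are *predicted − observed*,
  so a sampled "true" salinity is the prediction minus a residual draw.
* Lognormal PDFs for B, LF and theta_g moment-matched to target natural-scale
  means and SDs, optionally truncated to per-field bounds by rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "FieldRecord",
    "ResidualPDFTable",
    "LognormalSpec",
    "InputPDFs",
    "lf_from_em_ratio",
    "lf_from_cl_ratio",
    "reconcile_lf",
    "filter_salt_affected",
    "draw_ece",
    "draw_inputs",
    "lognormal_params",
    "sample_lognormal",
    "TABLE5_ROWS",
    "TABLE5_DATASET_ROW",
]

#: Salinity-category residual statistics: (lower bin edge dS/m, mean residual,
#: SD of residuals, count).  Bins are half-open [k, k+1); the last is open above.
TABLE5_ROWS: tuple[tuple[float, float, float, int], ...] = (
    (0, -2.29, 3.38, 131),
    (1, -0.38, 2.13, 577),
    (2, -0.68, 2.39, 623),
    (3, -0.32, 2.21, 584),
    (4, -0.86, 2.62, 351),
    (5, -0.97, 2.45, 245),
    (6, -0.95, 2.49, 298),
    (7, -0.75, 2.69, 267),
    (8, -0.86, 3.01, 215),
    (9, -0.52, 2.67, 143),
    (10, -0.50, 3.03, 82),
    (11, 1.27, 2.38, 83),
    (12, 2.18, 1.51, 121),
    (13, 3.00, 1.69, 193),
    (14, 3.64, 1.65, 127),
    (15, 4.91, 2.07, 77),
    (16, 6.57, 2.60, 194),
)

#: Whole-dataset residual row: (mean, SD, count).
TABLE5_DATASET_ROW: tuple[float, float, int] = (0.14, 3.11, 4311)


@dataclass(frozen=True)
class FieldRecord:
    """One regional field: the unit of the Monte Carlo simulation."""

    field_id: str
    area_ha: float
    ece_pred_dsm: float
    texture: str = "fine"  # fine | coarse
    landcover: str = "cropland"  # cropland | orchard | vineyard
    b_mean: float | None = None
    b_sd: float | None = None
    lf_mean: float | None = None
    lf_sd: float | None = None
    theta_mean: float | None = None
    theta_sd: float | None = None
    b_min: float | None = None
    b_max: float | None = None
    theta_min: float | None = None
    theta_max: float | None = None

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValidationError(f"field {self.field_id}: area must be > 0")
        if self.ece_pred_dsm < 0:
            raise ValidationError(f"field {self.field_id}: EC_e must be >= 0")
        for lo, hi, name in (
            (self.b_min, self.b_max, "b"),
            (self.theta_min, self.theta_max, "theta"),
        ):
            if lo is not None and hi is not None and hi < lo:
                raise ValidationError(
                    f"field {self.field_id}: {name} bounds max < min"
                )

    def has_boron(self) -> bool:
        """Boron information exists: per-field PDF parameters or survey bounds."""
        return self.b_mean is not None or self.b_min is not None

    def has_lf(self) -> bool:
        return self.lf_mean is not None

    def has_theta(self) -> bool:
        return self.theta_mean is not None or self.theta_min is not None


class ResidualPDFTable:
    """Normal residual PDFs of the regional salinity prediction, by category.

    ``rows`` are (lower_limit, mean, sd, count) for half-open 1 dS/m bins,
    the last open above; ``dataset_row`` pools every category.
    """

    def __init__(self, rows=TABLE5_ROWS, dataset_row=TABLE5_DATASET_ROW):
        rows = tuple(tuple(r) for r in rows)
        lowers = [r[0] for r in rows]
        if lowers != sorted(lowers) or len(set(lowers)) != len(lowers):
            raise ValidationError("residual table bins must be ordered and disjoint")
        if any(r[2] <= 0 for r in rows) or dataset_row[1] <= 0:
            raise ValidationError("residual SDs must be positive")
        self.rows = rows
        self.dataset_row = tuple(dataset_row)
        self._lowers = np.array(lowers, dtype=float)

    def category_row(self, ece_pred: float) -> tuple[float, float] | None:
        """(mean, sd) of the matching category, or None if below every bin."""
        idx = np.searchsorted(self._lowers, ece_pred, side="right") - 1
        if idx < 0:
            return None
        row = self.rows[idx]
        # bins other than the last are half-open [k, k+1)
        if idx < len(self.rows) - 1 and ece_pred >= self._lowers[idx + 1]:
            return None  # unreachable with contiguous bins; defensive
        return row[1], row[2]

    def residual_params(self, ece_pred: float, mode: str = "dataset"):
        """(mean, sd) of the residual PDF to use for a predicted salinity."""
        if mode == "dataset":
            return self.dataset_row[0], self.dataset_row[1]
        if mode != "category":
            raise ValueError(f"mode must be 'dataset' or 'category', got {mode!r}")
        row = self.category_row(ece_pred)
        if row is None:
            warnings.warn(
                f"predicted EC_e {ece_pred} matches no residual category; "
                "falling back to the whole-dataset PDF",
                stacklevel=2,
            )
            return self.dataset_row[0], self.dataset_row[1]
        return row


def lf_from_em_ratio(em_h: float, em_v: float) -> float:
    """Leaching fraction from the horizontal/vertical EC_a reading ratio."""
    if em_v == 0:
        raise ZeroDivisionError("vertical EC_a reading is zero")
    return float(np.clip(em_h / em_v, 0.0, 1.0))


def lf_from_cl_ratio(cl_irrigation: float, cl_below_rootzone: float) -> float:
    """Leaching fraction from the irrigation/below-root-zone chloride ratio."""
    if cl_below_rootzone == 0:
        raise ZeroDivisionError("chloride concentration below the root zone is zero")
    return float(np.clip(cl_irrigation / cl_below_rootzone, 0.0, 1.0))


def reconcile_lf(
    lf_em: float, lf_cl: float, tolerance: float = 0.05
) -> tuple[bool, float | None]:
    """Accept a leaching fraction only if both estimates agree.

    Agreement is a relative difference (|a − b| / mean) at most ``tolerance``;
    the accepted value is the mean of the two.  Returns (accepted, value).
    """
    mean = 0.5 * (lf_em + lf_cl)
    if mean == 0:
        return True, 0.0  # both zero: trivially in agreement
    if abs(lf_em - lf_cl) / mean <= tolerance:
        return True, mean
    return False, None


def filter_salt_affected(fields, threshold: float = 4.0) -> list[FieldRecord]:
    """Keep salt-affected cropland: predicted EC_e >= threshold (inclusive),
    excluding orchards and vineyards.  Order-preserving and idempotent."""
    return [
        f
        for f in fields
        if f.ece_pred_dsm >= threshold and f.landcover not in ("orchard", "vineyard")
    ]


def draw_ece(
    field: FieldRecord,
    table: ResidualPDFTable,
    mode: str = "dataset",
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Sample root-zone EC_e for a field from its prediction and residual PDF.

    Residuals are predicted − observed, so the sampled value is
    ``predicted − residual draw``, truncated below at 0.
    """
    rng = rng or np.random.default_rng()
    mean, sd = table.residual_params(field.ece_pred_dsm, mode)
    residual = rng.normal(mean, sd, size=size)
    out = np.maximum(field.ece_pred_dsm - residual, 0.0)
    return float(out) if size is None else out


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given natural-scale mean and SD."""
    if mean <= 0 or sd < 0:
        raise ValueError("lognormal target mean must be > 0 and SD >= 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return float(mu), float(np.sqrt(sigma2))


def sample_lognormal(
    mean: float,
    sd: float,
    rng: np.random.Generator,
    size: int | None = None,
    bounds: tuple[float | None, float | None] | None = None,
    clip_upper: float | None = None,
    max_tries: int = 1000,
):
    """Lognormal draws moment-matched to (mean, sd) on the natural scale.

    ``bounds`` truncates by rejection resampling; ``clip_upper`` applies a
    hard physical ceiling (for fractions like LF, theta_g).  ``sd == 0``
    degenerates to the mean exactly.
    """
    lo, hi = bounds if bounds is not None else (None, None)
    if lo is not None and hi is not None and hi < lo:
        raise ValueError(f"infeasible bounds: max {hi} < min {lo}")
    n = 1 if size is None else size
    if sd == 0:
        out = np.full(n, float(mean))
    else:
        mu, sigma = lognormal_params(mean, sd)
        out = rng.lognormal(mu, sigma, size=n)
        if bounds is not None:
            for _ in range(max_tries):
                bad = np.zeros(n, dtype=bool)
                if lo is not None:
                    bad |= out < lo
                if hi is not None:
                    bad |= out > hi
                if not bad.any():
                    break
                out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
            else:
                raise ValueError(
                    "rejection sampling failed to satisfy bounds "
                    f"[{lo}, {hi}] for lognormal(mean={mean}, sd={sd})"
                )
    if clip_upper is not None:
        out = np.minimum(out, clip_upper)
    return float(out[0]) if size is None else out


@dataclass(frozen=True)
class LognormalSpec:
    """Target natural-scale mean/SD of one input PDF, with optional bounds."""

    mean: float
    sd: float
    bounds: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("mean must be > 0 and sd >= 0")


@dataclass(frozen=True)
class InputPDFs:
    """Region-level lognormal input PDFs for B, LF and theta_g.

    Defaults moment-match the field-trial marginals; these stand in for the
    unpublished long-term regional dataset the study drew on.
    """

    boron: LognormalSpec = LognormalSpec(10.03, 6.06)
    lf: LognormalSpec = LognormalSpec(0.27, 0.15)
    theta_g: LognormalSpec = LognormalSpec(0.19, 0.05)


def _field_spec(field: FieldRecord, pdfs: InputPDFs, var: str) -> LognormalSpec:
    """Per-field override of the regional PDF, truncated to field bounds."""
    if var == "boron":
        spec = pdfs.boron
        if field.b_mean is not None:
            spec = LognormalSpec(field.b_mean, field.b_sd or 0.0, spec.bounds)
        if field.b_min is not None or field.b_max is not None:
            spec = replace(spec, bounds=(field.b_min, field.b_max))
        return spec
    if var == "lf":
        spec = pdfs.lf
        if field.lf_mean is not None:
            spec = LognormalSpec(field.lf_mean, field.lf_sd or 0.0, spec.bounds)
        return spec
    spec = pdfs.theta_g
    if field.theta_mean is not None:
        spec = LognormalSpec(field.theta_mean, field.theta_sd or 0.0, spec.bounds)
    if field.theta_min is not None or field.theta_max is not None:
        spec = replace(spec, bounds=(field.theta_min, field.theta_max))
    return spec


def draw_inputs(
    field: FieldRecord,
    pdfs: InputPDFs | None = None,
    rng: np.random.Generator | None = None,
    size: int | None = None,
):
    """Draw (B, LF, theta_g) for a field; ``None`` where data are unavailable.

    Availability follows the field record (per-field parameters or bounds
    present); LF and theta_g are additionally capped at 1.
    """
    pdfs = pdfs or InputPDFs()
    rng = rng or np.random.default_rng()

    def _draw(var, available, clip_upper=None):
        if not available:
            return None
        spec = _field_spec(field, pdfs, var)
        return sample_lognormal(
            spec.mean, spec.sd, rng, size=size, bounds=spec.bounds,
            clip_upper=clip_upper,
        )

    b = _draw("boron", field.has_boron())
    lf = _draw("lf", field.has_lf(), clip_upper=1.0)
    theta = _draw("theta_g", field.has_theta(), clip_upper=1.0)
    return b, lf, theta
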