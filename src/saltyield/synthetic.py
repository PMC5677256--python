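"""Synthetic inputs: a field trial and a salt-affected region.

No raw data accompany the underlying field study, so these generators
produce statistically analogous stand-ins:

* :func:`generate_trial` emulates the 40-site trial (of which six sites
  yielded nothing): edaphic marginals are lognormal with the trial's
  composite-depth means and SDs, yields follow the full polynomial model
  plus Gaussian noise, and the zero-yield sites are placed at the highest
  generated salinities, where the real zero-yield sites sat.
* :func:`generate_region` emulates the regional salinity raster at field
  granularity: predicted salinities drawn from the residual-table salinity
  categories (mixture weights default to the table's data counts), lognormal
  areas rescaled to a configured total, texture/land-cover flags by
  configured fractions, and per-field input-PDF parameters attached to a
  configured fraction of fields.
* :func:`generate_gamma_reference_region` builds a region whose simulated
  production mean is known analytically, for end-to-end calibration checks
  that do not lean on the engine being tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from .field_inputs import (
    TABLE5_ROWS,
    FieldRecord,
    InputPDFs,
    LognormalSpec,
    ResidualPDFTable,
    sample_lognormal,
)
from .params import (
    TABLE2B_MEANS,
    TABLE2B_SDS,
    ConversionParams,
    YieldModelCoefficients,
)
from .yield_models import full_polynomial

__all__ = [
    "TrialGeneratorConfig",
    "RegionGeneratorConfig",
    "generate_trial",
    "generate_region",
    "generate_gamma_reference_region",
]

#: Nuisance covariates with no true effect on yield (trial marginals).
_NUISANCE = {"ph_e": (7.74, 0.33), "sp": (53.23, 4.01), "sar": (12.06, 4.02)}


@dataclass(frozen=True)
class TrialGeneratorConfig:
    """Configuration of the synthetic field trial."""

    n_sites: int = 40
    n_zero_yield: int = 6
    means: Mapping[str, float] = dc_field(default_factory=lambda: dict(TABLE2B_MEANS))
    sds: Mapping[str, float] = dc_field(default_factory=lambda: dict(TABLE2B_SDS))
    yield_noise_sd: float = 100.0
    spatial_range_m: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 8:
            raise ValueError("n_sites must be >= 8")
        if not 0 <= self.n_zero_yield < self.n_sites:
            raise ValueError("n_zero_yield must be in [0, n_sites)")


@dataclass(frozen=True)
class RegionGeneratorConfig:
    """Configuration of the synthetic salt-affected region."""

    n_fields: int = 1000
    total_area_ha: float = 9.7e4
    area_cv: float = 1.0
    category_weights: tuple[float, ...] | None = None  # over residual-table bins
    open_bin_width: float = 4.0  # width used for the top, open salinity bin
    fraction_coarse: float = 0.15
    fraction_orchard_vineyard: float = 0.05
    fraction_boron_available: float = 0.8
    fraction_lf_available: float = 0.8
    fraction_theta_available: float = 0.8
    input_pdfs: InputPDFs = dc_field(default_factory=InputPDFs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 1 or self.total_area_ha <= 0:
            raise ValueError("n_fields >= 1 and total_area_ha > 0 required")
        if self.category_weights is not None:
            w = np.asarray(self.category_weights, dtype=float)
            if len(w) != len(TABLE5_ROWS) or w.min() < 0 or not np.isclose(w.sum(), 1.0):
                raise ValueError(
                    "category_weights must be a simplex over the "
                    f"{len(TABLE5_ROWS)} salinity bins"
                )


def _lognormal_field(rng, mean, sd, size, spatial_range=None, coords=None):
    """Lognormal marginal draws, optionally spatially correlated."""
    if sd == 0:
        return np.full(size, mean)
    from .field_inputs import lognormal_params

    mu, sigma = lognormal_params(mean, sd)
    if spatial_range is None:
        z = rng.standard_normal(size)
    else:
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        cov = np.exp(-d / spatial_range)
        z = rng.multivariate_normal(np.zeros(size), cov, method="cholesky")
    return np.exp(mu + sigma * z)


def generate_trial(
    config: TrialGeneratorConfig | None = None,
    coeffs: YieldModelCoefficients | None = None,
) -> pd.DataFrame:
    """Generate a synthetic site-level field trial table.

    Columns match the trial CSV schema: site_id, x_m, y_m, yield_kg_ha,
    ece_dsm renamed to the analysis names (boron, ec_e, lf, theta_g) plus
    nuisance covariates ph_e, sp, sar and a zero_yield flag.
    """
    cfg = config or TrialGeneratorConfig()
    c = coeffs or YieldModelCoefficients()
    rng = np.random.default_rng(cfg.seed)

    # jittered grid of site coordinates on a ~400 m square block
    side = int(np.ceil(np.sqrt(cfg.n_sites)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    spacing = 400.0 / side
    coords = (
        np.c_[gx.ravel(), gy.ravel()][: cfg.n_sites] * spacing
        + rng.uniform(-0.25, 0.25, size=(cfg.n_sites, 2)) * spacing
    )

    values = {}
    for name in ("boron", "ec_e", "lf", "theta_g"):
        v = _lognormal_field(
            rng, cfg.means[name], cfg.sds[name], cfg.n_sites,
            cfg.spatial_range_m, coords,
        )
        if name in ("lf", "theta_g"):
            v = np.minimum(v, 1.0)
        values[name] = v

    raw = full_polynomial(
        values["boron"], values["ec_e"], values["lf"], values["theta_g"], c
    )
    noise = (
        rng.normal(0.0, cfg.yield_noise_sd, cfg.n_sites)
        if cfg.yield_noise_sd > 0
        else np.zeros(cfg.n_sites)
    )
    yields = np.maximum(raw + noise, 0.0)

    zero = np.zeros(cfg.n_sites, dtype=bool)
    if cfg.n_zero_yield:
        worst = np.argsort(values["ec_e"])[-cfg.n_zero_yield:]
        zero[worst] = True
        yields[worst] = 0.0

    df = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(cfg.n_sites)],
            "x_m": coords[:, 0],
            "y_m": coords[:, 1],
            "yield_kg_ha": yields,
            "boron": values["boron"],
            "ec_e": values["ec_e"],
            "lf": values["lf"],
            "theta_g": values["theta_g"],
            "zero_yield": zero,
        }
    )
    for name, (m, s) in _NUISANCE.items():
        df[name] = sample_lognormal(m, s, rng, size=cfg.n_sites)
    return df


def generate_region(config: RegionGeneratorConfig | None = None) -> list[FieldRecord]:
    """Generate a synthetic regional field table.

    Field areas sum exactly to the configured total; predicted salinities are
    uniform within each sampled residual-table category.
    """
    cfg = config or RegionGeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_fields

    counts = np.array([r[3] for r in TABLE5_ROWS], dtype=float)
    weights = (
        np.asarray(cfg.category_weights, dtype=float)
        if cfg.category_weights is not None
        else counts / counts.sum()
    )
    lowers = np.array([r[0] for r in TABLE5_ROWS], dtype=float)
    widths = np.append(np.diff(lowers), cfg.open_bin_width)

    cat = rng.choice(len(lowers), size=n, p=weights)
    ece = lowers[cat] + rng.uniform(0.0, 1.0, n) * widths[cat]

    mean_area = cfg.total_area_ha / n
    areas = sample_lognormal(mean_area, cfg.area_cv * mean_area, rng, size=n)
    areas *= cfg.total_area_ha / areas.sum()

    coarse = rng.uniform(size=n) < cfg.fraction_coarse
    orchard = rng.uniform(size=n) < cfg.fraction_orchard_vineyard
    orchard_kind = rng.uniform(size=n) < 0.5
    has_b = rng.uniform(size=n) < cfg.fraction_boron_available
    has_lf = rng.uniform(size=n) < cfg.fraction_lf_available
    has_th = rng.uniform(size=n) < cfg.fraction_theta_available

    p = cfg.input_pdfs
    fields = []
    for i in range(n):
        fields.append(
            FieldRecord(
                field_id=f"F{i:05d}",
                area_ha=float(areas[i]),
                ece_pred_dsm=float(ece[i]),
                texture="coarse" if coarse[i] else "fine",
                landcover=(
                    ("orchard" if orchard_kind[i] else "vineyard")
                    if orchard[i]
                    else "cropland"
                ),
                b_mean=p.boron.mean if has_b[i] else None,
                b_sd=p.boron.sd if has_b[i] else None,
                lf_mean=p.lf.mean if has_lf[i] else None,
                lf_sd=p.lf.sd if has_lf[i] else None,
                theta_mean=p.theta_g.mean if has_th[i] else None,
                theta_sd=p.theta_g.sd if has_th[i] else None,
            )
        )
    return fields


def generate_gamma_reference_region(
    target_fit,
    n_fields: int = 100,
    theta_sd: float = 0.05,
    coeffs: YieldModelCoefficients | None = None,
    conversion: ConversionParams | None = None,
):
    """Region with an analytically known simulated-production mean.

    Construction: every field uses the full yield model with boron, salinity
    and leaching fraction degenerate at yield-safe values, and only the water
    content stochastic.  The model is linear in theta_g and the polynomial
    stays strictly positive over the support, so truncation never binds and

        E[Q] = sum_i area_i * E[yield_i] * conversion / 1e6

    holds exactly.  Total area is chosen so that E[Q] equals the target
    distribution's mean, giving an end-to-end expectation check whose truth
    does not come from the engine under test.

    Returns (fields, residual_table, input_pdfs, coeffs, expected): the
    returned coefficients carry applicability ranges widened to the full
    support of the stochastic water-content draws, so the full model applies
    in every iteration and the linear expectation argument stays exact;
    ``expected`` has the analytic mean and SD of Q.
    """
    from dataclasses import replace as dc_replace

    base = coeffs or YieldModelCoefficients()
    c = dc_replace(
        base,
        ranges={
            "boron": (0.0, 100.0),
            "ec_e": (0.0, 100.0),
            "lf": (0.0, 1.0),
            "theta_g": (0.0, 1.0),
        },
    )
    conv = conversion or ConversionParams()
    b0, e0, lf0, th0 = 4.0, 6.8, 0.27, 0.19

    mean_yield = float(full_polynomial(b0, e0, lf0, th0, c))
    factor = (
        conv.oil_content_fraction
        * conv.extraction_efficiency
        * conv.liters_per_kg_biofuel
    )
    target_mean = target_fit.mean()
    total_area = target_mean * 1e6 / (mean_yield * factor)
    area = total_area / n_fields

    # degenerate residual PDF: predicted salinity is exact
    degenerate_rows = tuple((low, 0.0, 1e-12, cnt) for low, _, _, cnt in TABLE5_ROWS)
    table = ResidualPDFTable(degenerate_rows, (0.0, 1e-12, TABLE5_DATASET_COUNT))

    pdfs = InputPDFs(
        boron=LognormalSpec(b0, 0.0),
        lf=LognormalSpec(lf0, 0.0),
        theta_g=LognormalSpec(th0, theta_sd),
    )
    fields = [
        FieldRecord(
            field_id=f"R{i:04d}",
            area_ha=area,
            ece_pred_dsm=e0,
            texture="fine",
            landcover="cropland",
            b_mean=b0, b_sd=0.0,
            lf_mean=lf0, lf_sd=0.0,
            theta_mean=th0, theta_sd=theta_sd,
        )
        for i in range(n_fields)
    ]
    # theta draws are independent across fields: Var(Q) sums over fields
    per_field_sd = c.beta6 * theta_sd * area * factor / 1e6
    expected = {
        "mean": target_mean,
        "sd": float(np.sqrt(n_fields) * per_field_sd),
        "mean_yield_kg_ha": mean_yield,
        "total_area_ha": total_area,
    }
    return fields, table, pdfs, c, expected


TABLE5_DATASET_COUNT = 4311
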