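"""File round-tripping: trial and field tables as CSV, configs as YAML/JSON.

The tolerant-reader policy applies throughout: unknown extra columns are
preserved with a warning, missing required columns raise
:class:`~saltyield.exceptions.SchemaError` naming the file and column, and
physically impossible values raise
:class:`~saltyield.exceptions.ValidationError` before any computation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError
from .field_inputs import (
    TABLE5_DATASET_ROW,
    TABLE5_ROWS,
    FieldRecord,
    ResidualPDFTable,
)
from .params import (
    TABLE2B_MEANS,
    TABLE2B_RANGES,
    TABLE2B_SDS,
    TARGET_PRODUCTION_ML,
    Y_MAX_DEFAULT,
    BoronToleranceParams,
    ConversionParams,
    QuadraticToleranceParams,
    SaltToleranceParams,
    YieldModelCoefficients,
)

__all__ = [
    "read_trial",
    "write_trial",
    "read_field_table",
    "write_field_table",
    "read_residual_table",
    "write_residual_table",
    "read_config",
    "write_config",
    "default_config",
    "objects_from_config",
    "RunManifest",
]

TRIAL_COLUMNS = (
    "site_id", "x_m", "y_m", "yield_kg_ha", "boron", "ec_e", "lf", "theta_g",
)
FIELD_COLUMNS = ("field_id", "area_ha", "ece_pred_dsm", "texture", "landcover")
FIELD_OPTIONAL = (
    "b_mean", "b_sd", "lf_mean", "lf_sd", "theta_mean", "theta_sd",
    "b_min", "b_max", "theta_min", "theta_max",
)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _warn_extras(df: pd.DataFrame, known, path) -> None:
    extras = [c for c in df.columns if c not in known]
    if extras:
        warnings.warn(f"{path}: unknown columns preserved: {extras}", stacklevel=3)


def read_trial(path) -> pd.DataFrame:
    """Read a site-level trial table, validating schema and value ranges."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRIAL_COLUMNS, path)
    _warn_extras(df, TRIAL_COLUMNS + ("zero_yield", "ph_e", "sp", "sar"), path)
    bad = df.index[df["yield_kg_ha"] < 0]
    if len(bad):
        raise ValidationError(
            f"{path}: negative yield at row {int(bad[0])}, column 'yield_kg_ha'"
        )
    for col in ("boron", "ec_e", "lf", "theta_g"):
        bad = df.index[df[col].dropna() < 0]
        if len(bad):
            raise ValidationError(
                f"{path}: negative value at row {int(bad[0])}, column {col!r}"
            )
    return df


def write_trial(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _opt(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_field_table(path) -> list[FieldRecord]:
    """Read a regional field table into FieldRecord objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, FIELD_COLUMNS, path)
    _warn_extras(df, FIELD_COLUMNS + FIELD_OPTIONAL, path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                FieldRecord(
                    field_id=str(row["field_id"]),
                    area_ha=float(row["area_ha"]),
                    ece_pred_dsm=float(row["ece_pred_dsm"]),
                    texture=str(row["texture"]),
                    landcover=str(row["landcover"]),
                    **{
                        k: _opt(row[k]) if k in df.columns else None
                        for k in FIELD_OPTIONAL
                    },
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_field_table(fields, path) -> None:
    rows = [dataclasses.asdict(f) for f in fields]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_residual_table(path) -> ResidualPDFTable:
    """Read a salinity residual table (CSV mirroring the category summary)."""
    df = pd.read_csv(path)
    _require_columns(df, ("lower_limit", "mean_residual", "sd_residual", "count"), path)
    rows = []
    dataset = None
    for _, row in df.iterrows():
        if str(row["lower_limit"]).strip().lower() == "all":
            dataset = (
                float(row["mean_residual"]),
                float(row["sd_residual"]),
                int(row["count"]),
            )
        else:
            rows.append(
                (
                    float(row["lower_limit"]),
                    float(row["mean_residual"]),
                    float(row["sd_residual"]),
                    int(row["count"]),
                )
            )
    if dataset is None:
        raise SchemaError(f"{path}: missing whole-dataset row (lower_limit = 'all')")
    return ResidualPDFTable(tuple(rows), dataset)


def write_residual_table(table: ResidualPDFTable, path) -> None:
    rows = [
        {"lower_limit": low, "mean_residual": m, "sd_residual": s, "count": n}
        for low, m, s, n in table.rows
    ]
    m, s, n = table.dataset_row
    rows.append(
        {"lower_limit": "all", "mean_residual": m, "sd_residual": s, "count": n}
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def default_config() -> dict:
    """Every model constant in one nested dict, the pinning point for runs."""
    return {
        "yield_model": {
            "coefficients": list(YieldModelCoefficients().as_tuple()),
            "ranges": {k: list(v) for k, v in TABLE2B_RANGES.items()},
        },
        "trial_marginals": {
            "means": dict(TABLE2B_MEANS),
            "sds": dict(TABLE2B_SDS),
        },
        "salt_tolerance": {"threshold_a": 8.3, "slope_b": 17.0},
        "boron_tolerance": {
            "deficiency_threshold": 4.2,
            "toxicity_threshold": 8.0,
            "toxicity_slope": 28.0,
            "deficiency_slope": 100.0 / 4.2,
        },
        "quadratic_salt": [74.0, 254.6, -18.8],
        "quadratic_boron": [-418.0, 555.2, -42.4],
        "conversion": {
            "oil_content_fraction": 0.26,
            "extraction_efficiency": 0.64,
            "liters_per_kg_biofuel": 175.3 / 166.4,
        },
        "residual_table": {
            "rows": [list(r) for r in TABLE5_ROWS],
            "dataset_row": list(TABLE5_DATASET_ROW),
        },
        "simulation": {
            "n_iterations": 10_000,
            "target_ml": TARGET_PRODUCTION_ML,
            "y_max": Y_MAX_DEFAULT,
        },
    }


def objects_from_config(cfg: dict) -> dict:
    """Materialise typed parameter objects from a (possibly partial) config."""
    full = default_config()
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(full.get(key), dict):
            full[key].update(val)
        else:
            full[key] = val
    b = full["yield_model"]["coefficients"]
    coeffs = YieldModelCoefficients(
        *b, ranges={k: tuple(v) for k, v in full["yield_model"]["ranges"].items()}
    )
    return {
        "coeffs": coeffs,
        "salt_params": SaltToleranceParams(**full["salt_tolerance"]),
        "boron_params": BoronToleranceParams(**full["boron_tolerance"]),
        "quad_salt": QuadraticToleranceParams(*full["quadratic_salt"]),
        "quad_boron": QuadraticToleranceParams(*full["quadratic_boron"]),
        "conversion": ConversionParams(**full["conversion"]),
        "residual_table": ResidualPDFTable(
            tuple(tuple(r) for r in full["residual_table"]["rows"]),
            tuple(full["residual_table"]["dataset_row"]),
        ),
        "simulation": dict(full["simulation"]),
        "trial_marginals": full["trial_marginals"],
    }


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(text) or {}
        return json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise SchemaError(f"{path}: malformed config file: {exc}") from exc


def write_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance of one CLI run: identical manifests imply identical outputs
    along every deterministic path."""

    seed: int | None
    config_hash: str
    package_version: str
    input_digests: dict
    created_at: str

    @classmethod
    def create(cls, seed, cfg: dict, input_paths=()) -> "RunManifest":
        from . import __version__

        digests = {}
        for p in input_paths:
            p = Path(p)
            digests[str(p)] = _digest(p.read_bytes())
        return cls(
            seed=seed,
            config_hash=_digest(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ),
            package_version=__version__,
            input_digests=digests,
            created_at=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
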