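"""Dataset CSV reading/writing and TOML configuration parsing.

CSV dialect: comma separator, UTF-8, header row required, '.' decimal point
regardless of locale.  Concentrations are mmol/L and pCO2 is kPa in every
file; unit conversion (e.g. mmHg) happens only at display time.

Dataset schema (one blood-gas record per row):

======== ======================================== =========
column   meaning                                  unit
======== ======================================== =========
id       record identifier                        text
na k ca mg cl lactate   electrolyte panel         mmol/L
albumin  albumin                                  g/L scale
phosphate inorganic phosphate                     mmol/L
ph       measured pH                              —
pco2_kpa measured pCO2                            kPa
hco3     measured bicarbonate (optional)          mmol/L
tco2     total CO2                                mmol/L
sid_app  precomputed SID (optional, replaces panel) mEq/L
u_minus  unmeasured anions (optional)             mEq/L
======== ======================================== =========

Unknown columns are ignored on read and can be passed through by the caller.
"""

from __future__ import annotations

import math
import tomllib
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from .chemistry import DissociationConstants, ElectrolytePanel
from .solver import SolverSettings
from .synthetic import DEFAULT_RANGES, GeneratorConfig
from .verification import AgreementSummary, BloodGasRecord, VerificationResult

__all__ = [
    "SchemaError",
    "RowError",
    "REQUIRED_COLUMNS",
    "PANEL_COLUMNS",
    "read_dataset",
    "records_from_dataframe",
    "dataset_to_dataframe",
    "write_dataset",
    "write_results",
    "load_config",
    "constants_from_config",
    "settings_from_config",
    "generator_config_from_config",
]


class SchemaError(ValueError):
    """The file's columns do not match the dataset schema."""


class RowError(ValueError):
    """A row holds an unparsable or invalid value; carries the row number."""


#: Always required.
REQUIRED_COLUMNS = ("id", "albumin", "phosphate", "ph", "pco2_kpa", "tco2")
#: The electrolyte panel; required unless a precomputed sid_app is present.
PANEL_COLUMNS = ("na", "k", "ca", "mg", "cl", "lactate")
_OPTIONAL_COLUMNS = ("hco3", "sid_app", "u_minus")


def _cell(row: Mapping[str, Any], column: str, row_number: int) -> float | None:
    """Numeric cell value, or None for an absent/empty optional cell."""
    if column not in row:
        return None
    value = row[column]
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(
            f"row {row_number}: column {column!r} has non-numeric value {value!r}"
        ) from None


def records_from_dataframe(df: pd.DataFrame) -> list[BloodGasRecord]:
    """Build blood-gas records from a dataframe following the dataset schema.

    Row numbers (1-based, excluding the header) are carried into every error
    message.  An electrolyte panel row missing any panel cell falls back to
    ``sid_app``; rows with neither raise a schema error.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset is missing required column(s): {missing}")
    has_panel_cols = all(c in df.columns for c in PANEL_COLUMNS)
    if not has_panel_cols and "sid_app" not in df.columns:
        raise SchemaError(
            "dataset needs either the electrolyte panel columns "
            f"{list(PANEL_COLUMNS)} or a precomputed 'sid_app' column"
        )

    records: list[BloodGasRecord] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        panel = None
        if has_panel_cols:
            cells = {c: _cell(row, c, i) for c in PANEL_COLUMNS}
            if all(v is not None for v in cells.values()):
                panel = ElectrolytePanel(
                    na=cells["na"], k=cells["k"], ca=cells["ca"],
                    mg=cells["mg"], cl=cells["cl"], la=cells["lactate"],
                )
        sid_app = _cell(row, "sid_app", i)
        if panel is None and sid_app is None:
            raise RowError(
                f"row {i}: neither a complete electrolyte panel nor sid_app"
            )

        def required(column: str) -> float:
            value = _cell(row, column, i)
            if value is None:
                raise RowError(f"row {i}: required column {column!r} is empty")
            return value

        try:
            records.append(
                BloodGasRecord(
                    identifier=str(row["id"]),
                    panel=panel,
                    sid_app=sid_app,
                    albumin=required("albumin"),
                    phosphate=required("phosphate"),
                    measured_ph=required("ph"),
                    measured_pco2=required("pco2_kpa"),
                    measured_hco3=_cell(row, "hco3", i),
                    total_co2=required("tco2"),
                    u_minus=_cell(row, "u_minus", i),
                )
            )
        except ValueError as exc:
            if isinstance(exc, RowError):
                raise
            raise RowError(f"row {i}: {exc}") from None
    return records


def read_dataset(path: str | Path) -> list[BloodGasRecord]:
    """Read a dataset CSV into blood-gas records."""
    df = pd.read_csv(path)
    return records_from_dataframe(df)


def dataset_to_dataframe(records: Iterable[BloodGasRecord]) -> pd.DataFrame:
    """Serialize records to the dataset schema (panel columns when present)."""
    rows = []
    for r in records:
        row: dict[str, Any] = {"id": r.identifier}
        if r.panel is not None:
            row.update(
                na=r.panel.na, k=r.panel.k, ca=r.panel.ca,
                mg=r.panel.mg, cl=r.panel.cl, lactate=r.panel.la,
            )
        row.update(
            albumin=r.albumin,
            phosphate=r.phosphate,
            ph=r.measured_ph,
            pco2_kpa=r.measured_pco2,
            hco3=r.measured_hco3,
            tco2=r.total_co2,
        )
        if r.sid_app is not None:
            row["sid_app"] = r.sid_app
        if r.u_minus is not None:
            row["u_minus"] = r.u_minus
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(path: str | Path, records: Iterable[BloodGasRecord]) -> None:
    """Write records as a dataset CSV (full float precision)."""
    dataset_to_dataframe(records).to_csv(path, index=False)


def _summary_frame(summaries: Mapping[str, AgreementSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": s.variable,
                "n": s.n,
                "mean_bias": s.mean_bias,
                "sd_of_differences": s.sd_of_differences,
                "loa_low": s.loa_low,
                "loa_high": s.loa_high,
            }
            for s in summaries.values()
        ]
    )


def write_results(outdir: str | Path, result: VerificationResult) -> dict[str, Path]:
    """Write the verification outputs: per-record and summary CSVs.

    Numbers are written at full precision; display rounding belongs to the
    human-readable report, not the files.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    predictions_path = outdir / "predictions.csv"
    summary_path = outdir / "summary.csv"
    result.predictions.to_csv(predictions_path, index=False)
    _summary_frame(result.summaries).to_csv(summary_path, index=False)
    paths = {"predictions": predictions_path, "summary": summary_path}
    if result.failed_records:
        failed_path = outdir / "failed_records.csv"
        pd.DataFrame({"id": list(result.failed_records)}).to_csv(
            failed_path, index=False
        )
        paths["failed"] = failed_path
    return paths


def load_config(path: str | Path) -> dict:
    """Parse a TOML configuration file."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def constants_from_config(config: Mapping[str, Any]) -> DissociationConstants:
    """Dissociation constants with ``[constants]`` overrides applied.

    Recognized keys: ``kc``, ``kd``, ``kw_prime``, ``alpha`` (values on the
    package's mmol/L scale).
    """
    section = dict(config.get("constants", {}))
    unknown = set(section) - {"kc", "kd", "kw_prime", "alpha"}
    if unknown:
        raise SchemaError(f"unknown [constants] keys: {sorted(unknown)}")
    return DissociationConstants(**section)


def settings_from_config(config: Mapping[str, Any]) -> SolverSettings:
    """Solver settings with ``[solver]`` overrides applied."""
    section = dict(config.get("solver", {}))
    unknown = set(section) - {"ph_min", "ph_max", "delta", "max_iterations"}
    if unknown:
        raise SchemaError(f"unknown [solver] keys: {sorted(unknown)}")
    return SolverSettings(**section)


def generator_config_from_config(
    config: Mapping[str, Any],
    n: int,
    seed: int,
    dialect: str = "model-consistent",
) -> GeneratorConfig:
    """Generator configuration with ``[generator]`` overrides applied."""
    section = dict(config.get("generator", {}))
    ranges = dict(DEFAULT_RANGES)
    for key, bounds in dict(section.pop("ranges", {})).items():
        if key not in ranges:
            raise SchemaError(f"unknown [generator.ranges] key: {key!r}")
        ranges[key] = (float(bounds[0]), float(bounds[1]))
    allowed = {
        "analyzer_pk", "analyzer_alpha",
        "round_ph_decimals", "round_pco2_step", "round_conc_step",
    }
    unknown = set(section) - allowed
    if unknown:
        raise SchemaError(f"unknown [generator] keys: {sorted(unknown)}")
    return GeneratorConfig(n=n, seed=seed, dialect=dialect, ranges=ranges, **section)
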