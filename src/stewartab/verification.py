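"""Method-agreement pipeline: measured blood gases vs. model predictions.

Each record of a blood-gas dataset carries the measured pH, pCO2 and the
quantities the model takes as inputs.  Preparation closes the charge balance
for the unmeasured anions; the forward solve then predicts pH, pCO2 and
bicarbonate from total CO2 alone, and Bland-Altman statistics summarize the
agreement per variable.  When the records were generated by this very model
(no rounding, same constants, same back-calculation route) the bias and
limits of agreement are identically zero up to solver tolerance — the
pipeline's self-consistency oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    DEFAULT_CONSTANTS,
    DissociationConstants,
    ElectrolytePanel,
    PlasmaSample,
    apparent_sid,
)
from .solver import (
    DEFAULT_SETTINGS,
    BracketingError,
    SolverSettings,
    solve_acid_base,
    unmeasured_anions,
)

__all__ = [
    "BloodGasRecord",
    "AgreementSummary",
    "VerificationResult",
    "InsufficientDataError",
    "prepare_record",
    "run_verification",
    "bland_altman",
    "bland_altman_plot",
]

#: Variables compared between measurement and prediction.
AGREEMENT_VARIABLES = ("ph", "pco2", "hco3")


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""


@dataclass(frozen=True)
class BloodGasRecord:
    """One measured blood gas with the covariates the model needs.

    ``panel`` may be omitted when a precomputed ``sid_app`` is supplied;
    ``measured_hco3`` is optional (analyzers derive it rather than measure
    it).  Units: concentrations mmol/L, pCO2 kPa.
    """

    identifier: str
    albumin: float
    phosphate: float
    measured_ph: float
    measured_pco2: float
    total_co2: float
    panel: ElectrolytePanel | None = None
    sid_app: float | None = None
    measured_hco3: float | None = None
    u_minus: float | None = None

    def __post_init__(self) -> None:
        if not self.total_co2 > 0.0:
            raise ValueError(f"record {self.identifier}: total_co2 must be > 0")
        if not 6.0 <= self.measured_ph <= 8.0:
            raise ValueError(
                f"record {self.identifier}: measured_ph must lie in [6.0, 8.0]"
            )

    def effective_sid(self) -> float:
        """SID_app from the panel, or the precomputed value."""
        if self.panel is not None:
            return apparent_sid(self.panel)
        if self.sid_app is not None:
            return self.sid_app
        raise ValueError(
            f"record {self.identifier}: needs an electrolyte panel or sid_app"
        )


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman agreement for one variable.

    ``mean_bias`` is the mean of (predicted - measured); the limits of
    agreement are ``mean_bias +/- 1.96 * sd`` with the sample (n-1) standard
    deviation.
    """

    variable: str
    n: int
    mean_bias: float
    sd_of_differences: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class VerificationResult:
    """Per-record predictions and per-variable agreement summaries."""

    predictions: pd.DataFrame
    summaries: dict[str, AgreementSummary]
    failed_records: tuple[str, ...]

    @property
    def n_failed(self) -> int:
        return len(self.failed_records)


def prepare_record(
    record: BloodGasRecord,
    constants: DissociationConstants = DEFAULT_CONSTANTS,
    route: str = "total_co2",
) -> PlasmaSample:
    """Turn a measured record into the sample whose forward solve is scored.

    The strong ion difference comes from the electrolyte panel when one is
    present; the unmeasured anions close the charge balance at the measured
    pH, using either the record's total CO2 (``route="total_co2"``, exactly
    invertible against this model) or the measured pCO2 (``route="pco2"``,
    the quantity an analyzer actually measures).
    """
    if route not in ("total_co2", "pco2"):
        raise ValueError(f"unknown route {route!r}")
    sid = record.effective_sid()
    co2_kwargs = (
        {"total_co2": record.total_co2}
        if route == "total_co2"
        else {"pco2": record.measured_pco2}
    )
    u_minus = unmeasured_anions(
        record.measured_ph,
        albumin=record.albumin,
        phosphate=record.phosphate,
        sid_app=sid,
        constants=constants,
        **co2_kwargs,
    )
    return PlasmaSample(
        total_co2=record.total_co2,
        albumin=record.albumin,
        phosphate=record.phosphate,
        sid_app=sid,
        u_minus=u_minus,
    )


def bland_altman(differences: Sequence[float], variable: str = "") -> AgreementSummary:
    """Bland-Altman summary of a set of paired differences.

    Mean bias, sample standard deviation (n-1 denominator), and the 95%
    limits of agreement ``bias +/- 1.96 * sd``.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size < 2:
        raise InsufficientDataError(
            "Bland-Altman statistics need at least two differences"
        )
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return AgreementSummary(
        variable=variable,
        n=int(diffs.size),
        mean_bias=bias,
        sd_of_differences=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def run_verification(
    records: Iterable[BloodGasRecord],
    constants: DissociationConstants = DEFAULT_CONSTANTS,
    settings: SolverSettings = DEFAULT_SETTINGS,
    route: str = "total_co2",
) -> VerificationResult:
    """Prepare, solve and score every record; summarize agreement per variable.

    Records whose composition fails to bracket an electroneutral pH are
    excluded from the statistics and reported in ``failed_records`` (never
    silently dropped).  Differences are predicted - measured; for hco3 the
    measured value falls back on the record's ``measured_hco3`` and is
    skipped for that record when absent.
    """
    records = list(records)
    if len(records) < 2:
        raise InsufficientDataError("verification needs at least two records")

    rows = []
    failed: list[str] = []
    for record in records:
        sample = prepare_record(record, constants, route)
        try:
            result = solve_acid_base(sample, settings, constants)
        except BracketingError:
            failed.append(record.identifier)
            continue
        row = {
            "id": record.identifier,
            "u_minus": sample.u_minus,
            "sid_app": sample.sid_app,
            "predicted_ph": result.ph,
            "predicted_pco2": result.pco2,
            "predicted_hco3": result.hco3,
            "measured_ph": record.measured_ph,
            "measured_pco2": record.measured_pco2,
            "measured_hco3": record.measured_hco3,
            "iterations": result.iterations,
        }
        row["diff_ph"] = result.ph - record.measured_ph
        row["diff_pco2"] = result.pco2 - record.measured_pco2
        row["diff_hco3"] = (
            result.hco3 - record.measured_hco3
            if record.measured_hco3 is not None
            else math.nan
        )
        row["mean_ph"] = 0.5 * (result.ph + record.measured_ph)
        row["mean_pco2"] = 0.5 * (result.pco2 + record.measured_pco2)
        row["mean_hco3"] = (
            0.5 * (result.hco3 + record.measured_hco3)
            if record.measured_hco3 is not None
            else math.nan
        )
        rows.append(row)

    predictions = pd.DataFrame(rows)
    summaries: dict[str, AgreementSummary] = {}
    for variable in AGREEMENT_VARIABLES:
        diffs = predictions[f"diff_{variable}"].dropna() if len(rows) else pd.Series(dtype=float)
        if diffs.size >= 2:
            summaries[variable] = bland_altman(diffs.to_numpy(), variable)
    return VerificationResult(
        predictions=predictions,
        summaries=summaries,
        failed_records=tuple(failed),
    )


def bland_altman_plot(
    means: Sequence[float],
    differences: Sequence[float],
    summary: AgreementSummary,
    path: str,
    unit: str = "",
) -> None:
    """Scatter of differences against means with bias and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.scatter(means, differences, s=8, alpha=0.5, edgecolors="none")
    ax.axhline(summary.mean_bias, color="k", lw=1.2, label="bias")
    for y in (summary.loa_low, summary.loa_high):
        ax.axhline(y, color="k", lw=0.9, ls="--")
    label = f"{summary.variable} ({unit})" if unit else summary.variable
    ax.set_xlabel(f"mean of measured and predicted {label}")
    ax.set_ylabel(f"predicted - measured {label}")
    ax.set_title(
        f"{summary.variable}: bias {summary.mean_bias:+.4g}, "
        f"LoA [{summary.loa_low:.4g}, {summary.loa_high:.4g}] (n={summary.n})"
    )
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
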