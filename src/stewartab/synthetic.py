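"""Seeded generator of neonatal-like blood-gas records.

Clinical blood-gas datasets are rarely shareable, so the verification
pipeline is exercised on synthetic records instead.  Electrolyte panels,
weak acids, unmeasured anions and total CO2 are drawn independently and
uniformly from neonatal reference ranges; the blood-gas fields are then
filled by the forward model in one of two dialects:

``model-consistent``
    Measured pH, pCO2 and HCO3 are exactly the model's own forward solve,
    at full precision.  Feeding these records back through the verification
    pipeline must give zero bias and zero-width limits of agreement — the
    pipeline's round-trip oracle.

``analyzer-like``
    Emulates a clinical analyzer: it measures pH and pCO2 and *derives*
    bicarbonate and total CO2 from its own Henderson-Hasselbalch constants
    (effective carbonic-acid pK and CO2 solubility that differ slightly
    from the model's), then reports everything on a clinical rounding grid
    (pH to 2 decimals, pCO2 to 0.1 kPa, concentrations to 0.1 mmol/L).

What the generator deliberately does not emulate: the joint distribution
of a real cohort (marginals are independent and uniform), longitudinal
structure within patients, or disease-class mixtures.

Randomness comes from numpy's ``default_rng`` (PCG64); the same seed and
configuration always reproduce the same records bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .chemistry import (
    DEFAULT_CONSTANTS,
    DissociationConstants,
    ElectrolytePanel,
    PlasmaSample,
    apparent_sid,
)
from .solver import DEFAULT_SETTINGS, BracketingError, SolverSettings, solve_acid_base
from .verification import BloodGasRecord

__all__ = [
    "GeneratorConfig",
    "RejectionRateError",
    "RNG_ALGORITHM",
    "DEFAULT_RANGES",
    "generate",
    "generation_metadata",
    "Table2Fixture",
    "table2_fixtures",
]

#: Pseudo-random generator algorithm, recorded in output metadata so another
#: implementation can reproduce the stream.
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"

#: Uniform sampling ranges (lo, hi): neonatal reference intervals, mmol/L
#: except u_minus (mEq/L).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "na": (130.0, 150.0),
    "k": (3.0, 6.0),
    "ca": (1.0, 1.5),
    "mg": (0.7, 1.1),
    "cl": (95.0, 115.0),
    "la": (0.5, 10.0),
    "albumin": (10.0, 30.0),
    "phosphate": (1.0, 2.8),
    "u_minus": (0.0, 15.0),
    "total_co2": (10.0, 35.0),
}


class RejectionRateError(RuntimeError):
    """Too many sampled compositions fail to bracket an electroneutral pH."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic dataset.

    ``dialect`` is ``"model-consistent"`` or ``"analyzer-like"``; the
    analyzer constants and the rounding grid only matter for the latter.
    Setting the analyzer pK/solubility equal to the model's and the rounding
    steps to 0 reduces the analyzer dialect to the model-consistent one.
    """

    n: int
    seed: int
    dialect: str = "model-consistent"
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    analyzer_pk: float = 6.105
    analyzer_alpha: float = 0.225  # mmol/(L*kPa)
    round_ph_decimals: int = 2
    round_pco2_step: float = 0.1  # kPa
    round_conc_step: float = 0.1  # mmol/L
    #: Abort threshold for the bracket-rejection safeguard.  Independent
    #: uniform draws over the full neonatal reference ranges produce strong
    #: ion / buffer combinations with no physiological root about two thirds
    #: of the time (real panels are correlated; these marginals are not), so
    #: the guard is set above that baseline and trips only when the ranges
    #: are genuinely misconfigured.
    max_rejection_rate: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.dialect not in ("model-consistent", "analyzer-like"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        missing = set(DEFAULT_RANGES) - set(self.ranges)
        if missing:
            raise ValueError(f"ranges missing keys: {sorted(missing)}")
        for key, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"range for {key!r} is degenerate: ({lo}, {hi})")
            if lo < 0.0 and key != "u_minus":
                raise ValueError(f"range for {key!r} must be non-negative")


def _round_step(value: float, step: float) -> float:
    if step <= 0.0:
        return value
    return round(value / step) * step


def generate(
    config: GeneratorConfig,
    constants: DissociationConstants = DEFAULT_CONSTANTS,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> list[BloodGasRecord]:
    """Draw ``config.n`` records; deterministic for a fixed config and seed.

    Compositions that admit no electroneutral pH in the solver bracket are
    discarded and redrawn.  If, after at least 50 attempts, more than half
    of all attempts have been rejected, generation aborts with a diagnosis
    pointing at the configured ranges.
    """
    rng = np.random.default_rng(config.seed)
    records: list[BloodGasRecord] = []
    attempts = 0
    rejected = 0

    def draw(key: str) -> float:
        lo, hi = config.ranges[key]
        return float(rng.uniform(lo, hi))

    while len(records) < config.n:
        attempts += 1
        if attempts >= 50 and rejected / attempts > config.max_rejection_rate:
            raise RejectionRateError(
                f"{rejected}/{attempts} sampled compositions failed to bracket "
                f"an electroneutral pH in [{settings.ph_min}, {settings.ph_max}]; "
                "the configured ranges produce a strong-ion/buffer mismatch "
                "(check sid-related ranges against total_co2 and u_minus)"
            )
        panel = ElectrolytePanel(
            na=draw("na"), k=draw("k"), ca=draw("ca"),
            mg=draw("mg"), cl=draw("cl"), la=draw("la"),
        )
        albumin = draw("albumin")
        phosphate = draw("phosphate")
        u_minus = draw("u_minus")
        total_co2 = draw("total_co2")
        sample = PlasmaSample(
            total_co2=total_co2,
            albumin=albumin,
            phosphate=phosphate,
            sid_app=apparent_sid(panel),
            u_minus=u_minus,
        )
        try:
            solved = solve_acid_base(sample, settings, constants)
        except BracketingError:
            rejected += 1
            continue

        if config.dialect == "model-consistent":
            record = BloodGasRecord(
                identifier=f"syn-{len(records):05d}",
                panel=panel,
                albumin=albumin,
                phosphate=phosphate,
                measured_ph=solved.ph,
                measured_pco2=solved.pco2,
                measured_hco3=solved.hco3,
                total_co2=total_co2,
                u_minus=u_minus,
            )
        else:
            # The analyzer derives HCO3 and total CO2 from its own effective
            # carbonic-acid pK and solubility; the (small) carbonate term
            # keeps the dialect exactly degenerate with the model-consistent
            # one when the analyzer constants match the model's.
            co2_dissolved = config.analyzer_alpha * solved.pco2
            hco3 = co2_dissolved * 10.0 ** (solved.ph - config.analyzer_pk)
            h = 1000.0 * 10.0 ** (-solved.ph)
            co3 = constants.kd * hco3 / h
            tco2 = co2_dissolved + hco3 + co3
            # ... and reports everything on the clinical rounding grid.
            grid = config.round_conc_step
            record = BloodGasRecord(
                identifier=f"syn-{len(records):05d}",
                panel=ElectrolytePanel(
                    na=_round_step(panel.na, grid),
                    k=_round_step(panel.k, grid),
                    ca=_round_step(panel.ca, grid),
                    mg=_round_step(panel.mg, grid),
                    cl=_round_step(panel.cl, grid),
                    la=_round_step(panel.la, grid),
                ),
                albumin=_round_step(albumin, grid),
                phosphate=_round_step(phosphate, grid),
                measured_ph=round(solved.ph, config.round_ph_decimals)
                if config.round_ph_decimals > 0
                else solved.ph,
                measured_pco2=_round_step(solved.pco2, config.round_pco2_step),
                measured_hco3=_round_step(hco3, grid),
                total_co2=_round_step(tco2, grid),
                u_minus=u_minus,
            )
        records.append(record)
    return records


def generation_metadata(config: GeneratorConfig) -> dict:
    """Provenance block for a generated dataset (written alongside the CSV)."""
    return {
        "generator": "stewartab.synthetic.generate",
        "algorithm": RNG_ALGORITHM,
        "seed": config.seed,
        "n": config.n,
        "dialect": config.dialect,
        "ranges": {k: list(v) for k, v in config.ranges.items()},
        "analyzer_pk": config.analyzer_pk,
        "analyzer_alpha": config.analyzer_alpha,
        "rounding": {
            "ph_decimals": config.round_ph_decimals,
            "pco2_step": config.round_pco2_step,
            "conc_step": config.round_conc_step,
        },
    }


@dataclass(frozen=True)
class Table2Fixture:
    """One reference acid-base disturbance: inputs plus published outputs.

    ``target`` holds the measured blood gas of the index patient;
    ``simulated`` the solver outputs as printed alongside them.  Each triple
    is (ph, pco2 [kPa], hco3 [mmol/L]).
    """

    name: str
    sample: PlasmaSample
    target: tuple[float, float, float]
    simulated: tuple[float, float, float]


_TABLE2_ROWS = (
    # name, total_co2, albumin, phosphate, sid_app, u_minus,
    #   (target ph, pco2, hco3), (simulated ph, pco2, hco3)
    ("Normal", 26.4, 25.0, 1.64, 35.9, 0.0,
     (7.40, 5.60, 25.1), (7.38, 5.36, 25.1)),
    ("Respiratory acidosis", 22.2, 25.0, 1.75, 29.7, -0.4,
     (7.15, 8.00, 20.4), (7.14, 7.67, 20.4)),
    ("Hyperchloremia", 12.9, 20.0, 1.42, 25.5, 6.0,
     (7.16, 4.50, 11.9), (7.15, 4.33, 11.9)),
    ("Hypoalbuminemia", 32.9, 15.0, 2.40, 42.1, 0.8,
     (7.49, 5.70, 31.6), (7.47, 5.54, 31.5)),
    ("Hyperlactatemia", 16.9, 17.0, 1.80, 28.1, 4.6,
     (7.19, 5.60, 15.6), (7.18, 5.36, 15.6)),
    ("Metabolic acidosis", 17.6, 16.0, 2.26, 38.6, 14.1,
     (7.16, 6.20, 16.2), (7.15, 5.95, 16.2)),
)


def table2_fixtures() -> dict[str, Table2Fixture]:
    """The six published reference disturbances, keyed by condition name.

    Single blood gas samples representing a normal neonate and five
    clinically relevant acid-base disturbances, with both the measured
    (target) blood gas and the published simulation outputs.  Values are
    printed at clinical precision, so the inputs carry rounding residue of
    order 0.05 mmol/L — worth remembering when comparing fresh solves
    against the printed outputs.
    """
    return {
        name: Table2Fixture(
            name=name,
            sample=PlasmaSample(
                total_co2=tco2, albumin=alb, phosphate=pi,
                sid_app=sid, u_minus=u,
            ),
            target=target,
            simulated=simulated,
        )
        for name, tco2, alb, pi, sid, u, target, simulated in _TABLE2_ROWS
    }
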