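"""Equilibrium chemistry of CO2 and weak acids in blood plasma.

Pure functions implementing the physicochemical (Stewart) description of
plasma acid-base state: CO2 speciation into dissolved gas, bicarbonate and
carbonate; water dissociation; the Figge linearization of albumin and
phosphate charge; strong-ion accounting; and the net-charge balance whose
root defines the plasma pH.

Unit convention
---------------
All concentrations are mmol/L, all charges mEq/L, and pCO2 is in kPa, so
``[H+] = 1000 * 10**(-pH)``.  The dissociation constants are stored on the
same scale: with ``kc = 10**-3.10`` mmol/L the bicarbonate-to-dissolved-CO2
ratio is ``kc/[H+] = 10**(pH - 6.10)``, i.e. the familiar mol/L pK values
(6.10, 10.2, 13.6 at 37 degC) are preserved.  Storing the printed mol/L
magnitudes unscaled alongside mmol/L concentrations would shift the
effective carbonic-acid pK to 9.10 and admit no electroneutral root in the
physiological pH range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InvalidConcentrationError",
    "DissociationConstants",
    "DEFAULT_CONSTANTS",
    "PlasmaSample",
    "ElectrolytePanel",
    "SpeciationState",
    "h_from_ph",
    "ph_from_h",
    "dissolved_co2_from_total",
    "bicarbonate_from_dissolved",
    "carbonate_from_bicarbonate",
    "hydroxide",
    "weak_acid_anions",
    "apparent_sid",
    "acid_charge",
    "net_charge",
    "speciate_at_ph",
    "pco2_from_dissolved",
    "dissolved_from_pco2",
]


class InvalidConcentrationError(ValueError):
    """A concentration argument is outside its physical domain."""


@dataclass(frozen=True)
class DissociationConstants:
    """Equilibrium constants at 37 degC, on the mmol/L concentration scale.

    Attributes
    ----------
    kc : float
        Carbonic-acid dissociation constant (mmol/L).  Default 10**-3.10,
        equivalent to pKc = 6.10 on the mol/L scale.
    kd : float
        Bicarbonate dissociation constant (mmol/L); pKd = 10.2 (mol/L).
    kw_prime : float
        Composite water dissociation constant ((mmol/L)**2), the water ion
        product folded with the molar water concentration; pKw' = 13.6.
    alpha : float
        CO2 solubility coefficient (mmol/(L*kPa)).
    """

    kc: float = 10.0 ** -3.10
    kd: float = 10.0 ** -7.20
    kw_prime: float = 10.0 ** -7.60
    alpha: float = 0.23

    def __post_init__(self) -> None:
        for name in ("kc", "kd", "kw_prime", "alpha"):
            if not getattr(self, name) > 0.0:
                raise InvalidConcentrationError(
                    f"dissociation constant {name!r} must be strictly positive"
                )


#: Module-level defaults; bit-stable so overriding one constant in a study
#: leaves the rest exactly reproducible.
DEFAULT_CONSTANTS = DissociationConstants()


@dataclass(frozen=True)
class PlasmaSample:
    """Independent quantities of one acid-base solve.

    Parameters
    ----------
    total_co2 : float
        Total CO2 concentration (dissolved + bicarbonate + carbonate), mmol/L.
    albumin : float
        Albumin concentration as used by the Figge charge linearization
        (numerically the g/L scale common in clinical chemistry).
    phosphate : float
        Inorganic phosphate, mmol/L.
    sid_app : float
        Apparent strong ion difference, mEq/L.  May be negative.
    u_minus : float
        Unmeasured anion concentration, mEq/L.  May be negative.
    """

    total_co2: float
    albumin: float
    phosphate: float
    sid_app: float
    u_minus: float = 0.0

    def __post_init__(self) -> None:
        if self.total_co2 < 0.0:
            raise InvalidConcentrationError("total_co2 must be >= 0")
        if self.albumin < 0.0:
            raise InvalidConcentrationError("albumin must be >= 0")
        if self.phosphate < 0.0:
            raise InvalidConcentrationError("phosphate must be >= 0")


@dataclass(frozen=True)
class ElectrolytePanel:
    """Measured strong-ion concentrations (mmol/L).

    ``na``, ``k``, ``cl``, ``la`` are monovalent; ``ca`` and ``mg`` are the
    divalent (ionized) fractions and enter the charge balance with valence 2.
    """

    na: float
    k: float
    ca: float
    mg: float
    cl: float
    la: float

    def __post_init__(self) -> None:
        for name in ("na", "k", "ca", "mg", "cl", "la"):
            if getattr(self, name) < 0.0:
                raise InvalidConcentrationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SpeciationState:
    """All ion concentrations and charges evaluated at one candidate pH.

    Concentrations in mmol/L, charges in mEq/L.  ``acid_charge`` is the net
    charge from dissociation products alone; ``net_charge`` adds the strong
    ion difference and subtracts unmeasured anions, and vanishes at the
    electroneutral pH.
    """

    h: float
    ph: float
    co2_dissolved: float
    hco3: float
    co3: float
    oh: float
    a_minus: float
    acid_charge: float
    net_charge: float


def h_from_ph(ph: float) -> float:
    """Hydrogen ion concentration (mmol/L) at a given pH.

    The factor 1000 converts the mol/L-based pH definition to mmol/L.
    """
    if not math.isfinite(ph):
        raise InvalidConcentrationError("ph must be finite")
    return 1000.0 * 10.0 ** (-ph)


def ph_from_h(h: float) -> float:
    """pH from hydrogen ion concentration in mmol/L."""
    if not h > 0.0:
        raise InvalidConcentrationError("h must be > 0")
    return -math.log10(h / 1000.0)


def dissolved_co2_from_total(
    total_co2: float, h: float, constants: DissociationConstants = DEFAULT_CONSTANTS
) -> float:
    """Dissolved CO2 (mmol/L) from total CO2 and [H+].

    Inverts the total-CO2 conservation relation: dividing the pool among
    dissolved gas, bicarbonate (ratio kc/h) and carbonate (ratio kc*kd/h**2).
    """
    if not h > 0.0:
        raise InvalidConcentrationError("h must be > 0")
    if total_co2 < 0.0:
        raise InvalidConcentrationError("total_co2 must be >= 0")
    return total_co2 / (1.0 + constants.kc / h + constants.kc * constants.kd / h**2)


def bicarbonate_from_dissolved(
    co2_dissolved: float, h: float, constants: DissociationConstants = DEFAULT_CONSTANTS
) -> float:
    """[HCO3-] (mmol/L) by mass action of carbonic acid: kc*[CO2]di/[H+]."""
    if not h > 0.0:
        raise InvalidConcentrationError("h must be > 0")
    if co2_dissolved < 0.0:
        raise InvalidConcentrationError("co2_dissolved must be >= 0")
    return constants.kc * co2_dissolved / h


def carbonate_from_bicarbonate(
    hco3: float, h: float, constants: DissociationConstants = DEFAULT_CONSTANTS
) -> float:
    """[CO3 2-] (mmol/L) by mass action of bicarbonate: kd*[HCO3-]/[H+]."""
    if not h > 0.0:
        raise InvalidConcentrationError("h must be > 0")
    if hco3 < 0.0:
        raise InvalidConcentrationError("hco3 must be >= 0")
    return constants.kd * hco3 / h


def hydroxide(h: float, constants: DissociationConstants = DEFAULT_CONSTANTS) -> float:
    """[OH-] (mmol/L) from the composite water dissociation: kw'/[H+]."""
    if not h > 0.0:
        raise InvalidConcentrationError("h must be > 0")
    return constants.kw_prime / h


def weak_acid_anions(albumin: float, phosphate: float, ph: float) -> float:
    """Weak-acid anion charge [A-] (mEq/L): Figge linearization.

    ``albumin*(0.123*pH - 0.631) + phosphate*(0.309*pH - 0.469)``.  An
    empirical linear fit; it can go negative at extreme (sub-physiological)
    pH, and that value is passed through rather than clamped so the charge
    balance stays exact.
    """
    if albumin < 0.0 or phosphate < 0.0:
        raise InvalidConcentrationError("albumin and phosphate must be >= 0")
    return albumin * (0.123 * ph - 0.631) + phosphate * (0.309 * ph - 0.469)


def apparent_sid(panel: ElectrolytePanel) -> float:
    """Apparent strong ion difference (mEq/L) from a measured panel.

    Na+ + K+ + 2*Ca2+ + 2*Mg2+ - Cl- - La-.
    """
    return panel.na + panel.k + 2.0 * panel.ca + 2.0 * panel.mg - panel.cl - panel.la


def acid_charge(h: float, hco3: float, a_minus: float, oh: float, co3: float) -> float:
    """Net charge from dissociation products (mEq/L).

    [H+] - [HCO3-] - [A-] - [OH-] - 2*[CO3 2-].
    """
    return h - hco3 - a_minus - oh - 2.0 * co3


def net_charge(acid_charge_: float, sid_app: float, u_minus: float) -> float:
    """Total net charge of the solution (mEq/L): [AC] + SID_app - [U-]."""
    return acid_charge_ + sid_app - u_minus


def speciate_at_ph(
    sample: PlasmaSample,
    ph: float,
    constants: DissociationConstants = DEFAULT_CONSTANTS,
) -> SpeciationState:
    """Evaluate the full speciation chain at a candidate pH.

    Computes [H+], partitions total CO2 into dissolved/bicarbonate/carbonate,
    evaluates hydroxide and weak-acid charge, and assembles the acid charge
    and net charge.  The solver drives ``net_charge`` to zero over pH.
    """
    h = h_from_ph(ph)
    co2_dissolved = dissolved_co2_from_total(sample.total_co2, h, constants)
    hco3 = bicarbonate_from_dissolved(co2_dissolved, h, constants)
    co3 = carbonate_from_bicarbonate(hco3, h, constants)
    oh = hydroxide(h, constants)
    a_minus = weak_acid_anions(sample.albumin, sample.phosphate, ph)
    ac = acid_charge(h, hco3, a_minus, oh, co3)
    nc = net_charge(ac, sample.sid_app, sample.u_minus)
    return SpeciationState(
        h=h,
        ph=ph,
        co2_dissolved=co2_dissolved,
        hco3=hco3,
        co3=co3,
        oh=oh,
        a_minus=a_minus,
        acid_charge=ac,
        net_charge=nc,
    )


def pco2_from_dissolved(
    co2_dissolved: float, constants: DissociationConstants = DEFAULT_CONSTANTS
) -> float:
    """Partial pressure of CO2 (kPa) from dissolved CO2 via Henry's law."""
    if co2_dissolved < 0.0:
        raise InvalidConcentrationError("co2_dissolved must be >= 0")
    return co2_dissolved / constants.alpha


def dissolved_from_pco2(
    pco2: float, constants: DissociationConstants = DEFAULT_CONSTANTS
) -> float:
    """Dissolved CO2 (mmol/L) from partial pressure: alpha * pCO2."""
    if pco2 < 0.0:
        raise InvalidConcentrationError("pco2 must be >= 0")
    return constants.alpha * pco2
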