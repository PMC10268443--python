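"""Single-compartment total-CO2 mass balance with quasi-static blood gases.

A well-mixed compartment of volume ``v`` (L) receives inflow at rate
``f_in`` (L/min) carrying total CO2 ``[CO2]in`` (mmol/L) and produces CO2
metabolically at ``V_CO2`` (mmol/min):

    d[CO2]S/dt = (f_in * ([CO2]in - [CO2]S) + V_CO2) / v

Total CO2 is the only dynamic state; the equilibrium acid-base solve is a
pure output map evaluated from the current pool at each reporting step
(quasi-static coupling) and never feeds back on it.  Time is in minutes
throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .chemistry import DEFAULT_CONSTANTS, DissociationConstants, PlasmaSample
from .solver import DEFAULT_SETTINGS, AcidBaseResult, BracketingError, SolverSettings, solve_acid_base

__all__ = [
    "CompartmentState",
    "InvalidStateError",
    "NoSteadyStateError",
    "co2_balance_derivative",
    "steady_state_total_co2",
    "simulate",
]


class InvalidStateError(ValueError):
    """A compartment state violates its physical constraints."""


class NoSteadyStateError(ValueError):
    """The compartment has no finite steady state (no flow to carry CO2 out)."""


@dataclass(frozen=True)
class CompartmentState:
    """Total-CO2 pool of one well-mixed compartment at time ``time`` (min)."""

    total_co2: float  # mmol/L
    volume: float  # L
    inflow_rate: float  # L/min
    inflow_total_co2: float  # mmol/L
    co2_production: float = 0.0  # mmol/min
    time: float = 0.0  # min

    def __post_init__(self) -> None:
        if not self.volume > 0.0:
            raise InvalidStateError("volume must be > 0")
        if self.inflow_rate < 0.0:
            raise InvalidStateError("inflow_rate must be >= 0")
        if self.total_co2 < 0.0:
            raise InvalidStateError("total_co2 must be >= 0")


def co2_balance_derivative(
    state: CompartmentState,
    extra_inflows: Iterable[tuple[float, float]] = (),
) -> float:
    """d[CO2]S/dt (mmol/L/min) of the compartment mass balance.

    ``extra_inflows`` is an optional list of additional ``(rate, total_co2)``
    streams; each contributes ``rate * (conc - [CO2]S)`` to the balance, the
    matched outflow keeping the volume constant.
    """
    if not state.volume > 0.0:  # defensive: dataclass already validates
        raise InvalidStateError("volume must be > 0")
    transport = state.inflow_rate * (state.inflow_total_co2 - state.total_co2)
    for rate, conc in extra_inflows:
        if rate < 0.0:
            raise InvalidStateError("inflow rates must be >= 0")
        transport += rate * (conc - state.total_co2)
    return (transport + state.co2_production) / state.volume


def steady_state_total_co2(
    inflow_total_co2: float, inflow_rate: float, co2_production: float
) -> float:
    """Closed-form equilibrium pool: [CO2]in + V_CO2 / f_in (mmol/L)."""
    if not inflow_rate > 0.0:
        raise NoSteadyStateError(
            "inflow_rate must be > 0 for a steady state to exist"
        )
    return inflow_total_co2 + co2_production / inflow_rate


ParameterSchedule = Callable[[float], Mapping[str, float]]


def _apply_schedule(state: CompartmentState, schedule: ParameterSchedule | None,
                    t: float) -> CompartmentState:
    if schedule is None:
        return state
    overrides = dict(schedule(t))
    allowed = {"volume", "inflow_rate", "inflow_total_co2", "co2_production"}
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"schedule returned unknown parameters: {sorted(unknown)}")
    return dataclasses.replace(state, **overrides) if overrides else state


def _derivative_at(total_co2: float, base: CompartmentState) -> float:
    probe = dataclasses.replace(base, total_co2=max(total_co2, 0.0))
    return co2_balance_derivative(probe)


def simulate(
    initial: CompartmentState,
    duration: float,
    time_step: float,
    sample_template: PlasmaSample,
    settings: SolverSettings = DEFAULT_SETTINGS,
    constants: DissociationConstants = DEFAULT_CONSTANTS,
    schedule: ParameterSchedule | None = None,
    method: str = "rk4",
) -> pd.DataFrame:
    """Integrate the compartment CO2 balance and read out blood gases.

    The pool is advanced with a fixed-step classical 4th-order Runge-Kutta
    scheme (``method="euler"`` substitutes forward Euler for real-time
    applications).  At every step, including t=0, the current total CO2 is
    inserted into ``sample_template`` and the equilibrium acid-base model is
    solved; the readout never mutates the compartment state.

    ``schedule``, if given, maps time (min) to parameter overrides
    (``volume``, ``inflow_rate``, ``inflow_total_co2``, ``co2_production``)
    applied from that time on; parameters are held constant within a step.

    Returns a DataFrame with columns
    ``time_min, total_co2, ph, pco2_kpa, hco3``.

    Raises
    ------
    BracketingError
        If the acid-base solve fails at some step; the message carries the
        failing time stamp.
    """
    if not time_step > 0.0:
        raise ValueError("time_step must be > 0")
    if duration < time_step:
        raise ValueError("duration must be >= time_step")
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown integration method {method!r}")

    n_steps = round(duration / time_step)
    state = initial
    rows = []

    def readout(state: CompartmentState) -> AcidBaseResult:
        sample = dataclasses.replace(sample_template, total_co2=state.total_co2)
        try:
            return solve_acid_base(sample, settings, constants)
        except BracketingError as exc:
            raise BracketingError(
                f"acid-base solve failed at t={state.time:g} min: {exc}"
            ) from None

    for i in range(n_steps + 1):
        t = initial.time + i * time_step
        state = _apply_schedule(dataclasses.replace(state, time=t), schedule, t)
        result = readout(state)
        rows.append(
            (t, state.total_co2, result.ph, result.pco2, result.hco3)
        )
        if i == n_steps:
            break
        c = state.total_co2
        h = time_step
        if method == "euler":
            c_next = c + h * _derivative_at(c, state)
        else:
            k1 = _derivative_at(c, state)
            k2 = _derivative_at(c + 0.5 * h * k1, state)
            k3 = _derivative_at(c + 0.5 * h * k2, state)
            k4 = _derivative_at(c + h * k3, state)
            c_next = c + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        state = dataclasses.replace(state, total_co2=max(c_next, 0.0))

    return pd.DataFrame(
        rows, columns=["time_min", "total_co2", "ph", "pco2_kpa", "hco3"]
    )
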