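"""Electroneutral pH solver and unmeasured-anion back-calculation.

The plasma pH is the root of the net-charge function over a physiological
bracket.  The root is found with an explicitly coded Brent method
(bisection / secant / inverse quadratic interpolation with the classical
acceptance guards); the stopping criterion is the charge-balance residual
``|NC| <= delta`` rather than bracket width, so every converged solve is
electroneutral to the stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .chemistry import (
    DEFAULT_CONSTANTS,
    DissociationConstants,
    InvalidConcentrationError,
    PlasmaSample,
    SpeciationState,
    bicarbonate_from_dissolved,
    carbonate_from_bicarbonate,
    dissolved_co2_from_total,
    dissolved_from_pco2,
    h_from_ph,
    hydroxide,
    pco2_from_dissolved,
    speciate_at_ph,
    weak_acid_anions,
)

__all__ = [
    "SolverSettings",
    "DEFAULT_SETTINGS",
    "AcidBaseResult",
    "BracketingError",
    "ConvergenceError",
    "brent_root",
    "solve_acid_base",
    "unmeasured_anions",
]

# |NC| threshold under which a machine-precision bracket collapse still
# counts as converged; looser than the primary delta, far below anything
# clinically resolvable.
_COLLAPSE_NC_TOL = 1e-6

_EPS = 2.220446049250313e-16  # float64 machine epsilon


class BracketingError(ValueError):
    """The objective does not change sign across the given bracket."""


class ConvergenceError(RuntimeError):
    """The iteration cap was reached before the residual tolerance."""


@dataclass(frozen=True)
class SolverSettings:
    """Root-finding configuration.

    ``ph_min``/``ph_max`` bound the search to a wide physiological range;
    ``delta`` is the upper limit on the absolute net charge (mEq/L) at an
    accepted root; ``max_iterations`` caps the Brent loop.
    """

    ph_min: float = 6.5
    ph_max: float = 7.8
    delta: float = 1e-8
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not self.ph_min < self.ph_max:
            raise ValueError("ph_min must be < ph_max")
        if not self.delta > 0.0:
            raise ValueError("delta must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


DEFAULT_SETTINGS = SolverSettings()


@dataclass(frozen=True)
class AcidBaseResult:
    """A solved blood gas: pH, pCO2 (kPa), [HCO3-] (mmol/L) plus diagnostics."""

    ph: float
    pco2: float
    hco3: float
    speciation: SpeciationState
    iterations: int
    converged: bool


def brent_root(
    objective: Callable[[float], float],
    lo: float,
    hi: float,
    f_tolerance: float,
    max_iterations: int = 100,
) -> tuple[float, int, bool]:
    """Find a root of ``objective`` in [lo, hi] by Brent's method.

    Accepts a point as the root when ``|objective(x)| <= f_tolerance``.  If
    the bracket collapses to machine-precision width while the residual is
    still above tolerance, the current best point is returned with
    ``converged=False`` so the caller can decide whether the residual is
    acceptable.

    Returns
    -------
    (root, iterations, converged)

    Raises
    ------
    BracketingError
        If the objective has the same sign at both endpoints (and neither
        endpoint is already within tolerance).
    ConvergenceError
        If ``max_iterations`` function-update cycles pass without meeting
        either stopping condition.
    """
    a, b = float(lo), float(hi)
    fa, fb = objective(a), objective(b)

    # Endpoint grace: an endpoint already at the root needs no iteration.
    if abs(fa) <= f_tolerance:
        return a, 0, True
    if abs(fb) <= f_tolerance:
        return b, 0, True
    if fa * fb > 0.0:
        raise BracketingError(
            f"objective does not change sign on [{lo}, {hi}]: "
            f"f(lo)={fa:.6g}, f(hi)={fb:.6g}"
        )

    # b is the best estimate, a the previous one, c the counterpoint.
    if abs(fa) < abs(fb):
        a, b, fa, fb = b, a, fb, fa
    c, fc = a, fa
    d = e = b - a

    for iteration in range(1, max_iterations + 1):
        if fb * fc > 0.0:
            c, fc = a, fa
            d = e = b - a
        if abs(fc) < abs(fb):
            a, b, c = b, c, b
            fa, fb, fc = fb, fc, fb

        tol = 2.0 * _EPS * abs(b) + 1e-300  # bracket-width floor
        m = 0.5 * (c - b)

        if abs(fb) <= f_tolerance:
            # One free secant polish: the residual tolerance is met, but a
            # last superlinear step typically gains several more digits,
            # making the root as accurate as the bracket allows.
            if fb != 0.0 and fa != fb:
                x = b - fb * (b - a) / (fb - fa)
                if min(b, c) <= x <= max(b, c):
                    fx = objective(x)
                    if abs(fx) < abs(fb):
                        return x, iteration, True
            return b, iteration - 1, True
        if abs(m) <= tol:
            # Bracket exhausted at machine precision with |f| > tolerance.
            return b, iteration - 1, False

        if abs(e) < tol or abs(fa) <= abs(fb):
            d = e = m  # forced bisection
        else:
            s = fb / fa
            if a == c:
                # secant step
                p = 2.0 * m * s
                q = 1.0 - s
            else:
                # inverse quadratic interpolation
                q = fa / fc
                r = fb / fc
                p = s * (2.0 * m * q * (q - r) - (b - a) * (r - 1.0))
                q = (q - 1.0) * (r - 1.0) * (s - 1.0)
            if p > 0.0:
                q = -q
            p = abs(p)
            # Accept interpolation only if it stays inside the bracket and
            # converges faster than bisection would.
            if 2.0 * p < min(3.0 * m * q - abs(tol * q), abs(e * q)):
                e = d
                d = p / q
            else:
                d = e = m

        a, fa = b, fb
        b += d if abs(d) > tol else (tol if m > 0.0 else -tol)
        fb = objective(b)

    raise ConvergenceError(
        f"no root to tolerance {f_tolerance:g} within {max_iterations} iterations"
    )


def solve_acid_base(
    sample: PlasmaSample,
    settings: SolverSettings = DEFAULT_SETTINGS,
    constants: DissociationConstants = DEFAULT_CONSTANTS,
) -> AcidBaseResult:
    """Solve the electroneutral pH of a plasma sample and report the blood gas.

    Given total CO2, the weak acids (albumin, phosphate), the apparent
    strong ion difference and unmeasured anions, finds the pH in
    ``[settings.ph_min, settings.ph_max]`` at which the plasma net charge
    vanishes, then reads pCO2 and bicarbonate off the root's speciation.

    Raises
    ------
    BracketingError
        When the composition admits no electroneutral pH in the bracket
        (for example SID minus unmeasured anions exceeding the total
        buffering capacity); the message reports the net charge at both
        endpoints.
    ConvergenceError
        If the iteration cap is hit (never silently returned).
    """

    def nc(ph: float) -> float:
        return speciate_at_ph(sample, ph, constants).net_charge

    try:
        root, iterations, brent_ok = brent_root(
            nc, settings.ph_min, settings.ph_max, settings.delta,
            settings.max_iterations,
        )
    except BracketingError:
        nc_lo = nc(settings.ph_min)
        nc_hi = nc(settings.ph_max)
        raise BracketingError(
            "no electroneutral pH in "
            f"[{settings.ph_min}, {settings.ph_max}]: net charge "
            f"{nc_lo:+.6g} mEq/L at pH {settings.ph_min}, "
            f"{nc_hi:+.6g} mEq/L at pH {settings.ph_max}"
        ) from None

    state = speciate_at_ph(sample, root, constants)
    # Bracket collapse before |NC| <= delta: accept only a near-zero residual.
    converged = brent_ok or abs(state.net_charge) <= _COLLAPSE_NC_TOL
    return AcidBaseResult(
        ph=root,
        pco2=pco2_from_dissolved(state.co2_dissolved, constants),
        hco3=state.hco3,
        speciation=state,
        iterations=iterations,
        converged=converged,
    )


def unmeasured_anions(
    ph: float,
    *,
    total_co2: float | None = None,
    pco2: float | None = None,
    albumin: float,
    phosphate: float,
    sid_app: float,
    constants: DissociationConstants = DEFAULT_CONSTANTS,
) -> float:
    """Back-calculate the unmeasured anion concentration [U-] (mEq/L).

    Electroneutrality of a measured blood gas closes the charge balance for
    the one quantity no analyzer reports:

        [U-] = [H+] - [HCO3-] - [A-] - [OH-] - 2[CO3 2-] + SID_app

    The CO2 speciation is taken either from ``total_co2`` (default route;
    exactly inverts this model's own forward solve) or from ``pco2`` via the
    solubility coefficient (what a clinical analyzer actually measures).
    Exactly one of the two must be supplied.
    """
    if (total_co2 is None) == (pco2 is None):
        raise ValueError("supply exactly one of total_co2 or pco2")
    h = h_from_ph(ph)
    if total_co2 is not None:
        co2_dissolved = dissolved_co2_from_total(total_co2, h, constants)
    else:
        assert pco2 is not None
        co2_dissolved = dissolved_from_pco2(pco2, constants)
    hco3 = bicarbonate_from_dissolved(co2_dissolved, h, constants)
    co3 = carbonate_from_bicarbonate(hco3, h, constants)
    oh = hydroxide(h, constants)
    a_minus = weak_acid_anions(albumin, phosphate, ph)
    return h - hco3 - a_minus - oh - 2.0 * co3 + sid_app
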