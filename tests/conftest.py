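"""Shared fixtures and sample-generation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from stewartab.chemistry import PlasmaSample, speciate_at_ph
from stewartab.solver import DEFAULT_SETTINGS


def bracketing_samples(n: int, seed: int) -> list[PlasmaSample]:
    """Random plasma samples guaranteed to bracket an electroneutral pH.

    Weak acids and total CO2 are drawn uniformly from neonatal ranges; the
    effective strong-ion charge (sid_app - u_minus) is then drawn inside the
    open interval for which the net charge changes sign across the default
    pH bracket, shrunk 2% at each end to stay clear of degenerate endpoints.
    """
    rng = np.random.default_rng(seed)
    samples = []
    while len(samples) < n:
        tco2 = rng.uniform(10.0, 35.0)
        alb = rng.uniform(10.0, 30.0)
        pi = rng.uniform(1.0, 2.8)
        probe = PlasmaSample(total_co2=tco2, albumin=alb, phosphate=pi,
                             sid_app=0.0, u_minus=0.0)
        ac_lo = speciate_at_ph(probe, DEFAULT_SETTINGS.ph_min).acid_charge
        ac_hi = speciate_at_ph(probe, DEFAULT_SETTINGS.ph_max).acid_charge
        # bracket iff sid_eff in (-ac_lo, -ac_hi); ac is decreasing in pH
        lo, hi = -ac_lo, -ac_hi
        width = hi - lo
        sid_eff = rng.uniform(lo + 0.02 * width, hi - 0.02 * width)
        u = rng.uniform(0.0, 10.0)
        samples.append(
            PlasmaSample(total_co2=tco2, albumin=alb, phosphate=pi,
                         sid_app=sid_eff + u, u_minus=u)
        )
    return samples


@pytest.fixture(scope="session")
def random_samples() -> list[PlasmaSample]:
    return bracketing_samples(200, seed=20240917)


@pytest.fixture
def normal_sample() -> PlasmaSample:
    """A normal neonatal plasma composition."""
    return PlasmaSample(total_co2=26.4, albumin=25.0, phosphate=1.64,
                        sid_app=35.9, u_minus=0.0)
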