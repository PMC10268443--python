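"""Speciation chemistry: closed-form values, conservation and monotonicity.

Expected numbers marked as frozen were computed with an independent
plain-math oracle (direct formula evaluation, long division kept symbolic
until the final step) before the implementation existed.
"""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stewartab.chemistry import (
    DEFAULT_CONSTANTS,
    DissociationConstants,
    ElectrolytePanel,
    InvalidConcentrationError,
    PlasmaSample,
    acid_charge,
    apparent_sid,
    bicarbonate_from_dissolved,
    carbonate_from_bicarbonate,
    dissolved_co2_from_total,
    dissolved_from_pco2,
    h_from_ph,
    hydroxide,
    net_charge,
    pco2_from_dissolved,
    ph_from_h,
    speciate_at_ph,
    weak_acid_anions,
)

approx = pytest.approx


class TestPhConversion:
    @pytest.mark.parametrize(
        "ph, h",
        [
            (7.40, 1000.0 * 10**-7.40),
            (7.0, 1.0e-4),
            (6.5, 10**-3.5),
        ],
    )
    def test_h_from_ph_closed_form(self, ph, h):
        assert h_from_ph(ph) == approx(h, rel=1e-14)

    def test_ph_from_h_inverts_definition(self):
        # [H+] = 10**-4.4 mmol/L corresponds to pH 7.4
        assert ph_from_h(10**-4.4) == approx(7.4, abs=1e-12)

    @given(st.floats(min_value=5.0, max_value=9.0))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, ph):
        assert ph_from_h(h_from_ph(ph)) == approx(ph, abs=1e-12)

    def test_nonpositive_h_rejected(self):
        with pytest.raises(InvalidConcentrationError):
            ph_from_h(0.0)


class TestCo2Speciation:
    @pytest.mark.parametrize(
        "total, ph, expected",
        [
            (26.4, 7.40, 1.2580866661939125),  # frozen oracle value
            (0.0, 7.0, 0.0),
            (25.0, 6.5, 7.117665449733431),  # frozen oracle value
        ],
    )
    def test_dissolved_from_total(self, total, ph, expected):
        assert dissolved_co2_from_total(total, h_from_ph(ph)) == approx(
            expected, rel=1e-12, abs=1e-15
        )

    @pytest.mark.parametrize(
        "di, ph, expected",
        [
            (1.2581, 7.40, 25.10239518462349),
            (0.0, 7.0, 0.0),
            (1.0, 6.10, 1.0),  # at pH = pKc the ratio is 1
        ],
    )
    def test_bicarbonate(self, di, ph, expected):
        assert bicarbonate_from_dissolved(di, h_from_ph(ph)) == approx(
            expected, rel=1e-12, abs=1e-15
        )

    @pytest.mark.parametrize(
        "hco3, ph, expected",
        [
            (25.10, 7.40, 0.03978081913077397),
            (0.0, 7.0, 0.0),
            (10.0, 10.2, 10.0),  # at pH = pKd the ratio is 1
        ],
    )
    def test_carbonate(self, hco3, ph, expected):
        assert carbonate_from_bicarbonate(hco3, h_from_ph(ph)) == approx(
            expected, rel=1e-12, abs=1e-15
        )

    def test_hydroxide_values_and_reciprocal_law(self):
        assert hydroxide(h_from_ph(7.40)) == approx(6.309573444801943e-4, rel=1e-12)
        assert hydroxide(h_from_ph(6.80)) == approx(1.584893192461114e-4, rel=1e-12)
        h = h_from_ph(7.1)
        assert hydroxide(10.0 * h) == approx(hydroxide(h) / 10.0, rel=1e-14)

    def test_invalid_h_rejected(self):
        for fn in (
            lambda h: dissolved_co2_from_total(10.0, h),
            lambda h: bicarbonate_from_dissolved(1.0, h),
            lambda h: carbonate_from_bicarbonate(1.0, h),
            hydroxide,
        ):
            with pytest.raises(InvalidConcentrationError):
                fn(0.0)
            with pytest.raises(InvalidConcentrationError):
                fn(-1.0)


class TestWeakAcids:
    @pytest.mark.parametrize(
        "alb, pi, ph, expected",
        [
            (25.0, 1.64, 7.40, 9.960864),
            (0.0, 0.0, 7.2, 0.0),
            (25.0, 1.64, 7.38, 9.8892288),
        ],
    )
    def test_figge_linearization(self, alb, pi, ph, expected):
        assert weak_acid_anions(alb, pi, ph) == approx(expected, rel=1e-12, abs=1e-15)

    @given(
        st.floats(min_value=0.0, max_value=40.0),
        st.floats(min_value=0.0, max_value=4.0),
        st.floats(min_value=6.0, max_value=8.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_doubling_buffers_doubles_charge(self, alb, pi, ph):
        assert weak_acid_anions(2 * alb, 2 * pi, ph) == approx(
            2 * weak_acid_anions(alb, pi, ph), rel=1e-12, abs=1e-12
        )

    def test_negative_at_extreme_low_ph_passes_through(self):
        # empirical linearization goes negative below its validity range;
        # value must not be clamped or the charge balance breaks
        assert weak_acid_anions(10.0, 0.0, 4.0) < 0.0


class TestStrongIons:
    def test_apparent_sid_values(self):
        assert apparent_sid(ElectrolytePanel(140, 4, 1.2, 0.4, 105, 1)) == approx(41.2)
        assert apparent_sid(ElectrolytePanel(0, 0, 0, 0, 0, 0)) == 0.0
        assert apparent_sid(ElectrolytePanel(137, 4.5, 1.3, 0.5, 110, 5.5)) == approx(
            29.6
        )

    def test_cation_anion_permutation_invariance(self):
        # swapping the two monovalent cations, the two divalents, or the two
        # anions leaves the signed sum unchanged
        a = apparent_sid(ElectrolytePanel(140, 4, 1.2, 0.4, 105, 1))
        assert apparent_sid(ElectrolytePanel(4, 140, 0.4, 1.2, 1, 105)) == approx(a)

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(derandomize=True, max_examples=25)
    def test_linear_in_each_ion(self, x):
        base = apparent_sid(ElectrolytePanel(140, 4, 1.2, 0.4, 105, 1))
        assert apparent_sid(ElectrolytePanel(140 + x, 4, 1.2, 0.4, 105, 1)) == approx(
            base + x, rel=1e-12
        )
        assert apparent_sid(ElectrolytePanel(140, 4, 1.2 + x, 0.4, 105, 1)) == approx(
            base + 2 * x, rel=1e-12
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidConcentrationError):
            ElectrolytePanel(-1, 4, 1.2, 0.4, 105, 1)


class TestChargeBookkeeping:
    def test_acid_charge_values(self):
        assert acid_charge(
            h_from_ph(7.40), 25.103, 9.961, 6.31e-4, 0.0398
        ) == approx(-35.14419118928294, rel=1e-12)
        assert acid_charge(0, 0, 0, 0, 0) == 0.0
        assert acid_charge(1, 0, 0, 0, 0) == 1.0

    def test_net_charge_values(self):
        assert net_charge(-10, 10, 0) == 0.0
        assert net_charge(-10, 12, 2) == 0.0

    def test_normal_sample_residual_at_measured_ph(self, normal_sample):
        # printed clinical inputs carry rounding residue: at the measured pH
        # 7.40 the charge balance does not quite close
        state = speciate_at_ph(normal_sample, 7.40)
        assert state.hco3 == approx(25.10, abs=5e-3)
        assert state.net_charge == approx(0.7568473259758903, rel=1e-10)


class TestSpeciateAtPh:
    def test_zero_total_co2_zeroes_carbon_species(self):
        sample = PlasmaSample(total_co2=0.0, albumin=10.0, phosphate=1.0,
                              sid_app=5.0, u_minus=0.0)
        state = speciate_at_ph(sample, 7.3)
        assert state.co2_dissolved == state.hco3 == state.co3 == 0.0

    @given(
        st.floats(min_value=5.0, max_value=40.0),
        st.floats(min_value=0.0, max_value=40.0),
        st.floats(min_value=0.0, max_value=4.0),
        st.floats(min_value=6.0, max_value=8.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_total_co2_conserved(self, tco2, alb, pi, ph):
        sample = PlasmaSample(total_co2=tco2, albumin=alb, phosphate=pi,
                              sid_app=20.0, u_minus=0.0)
        state = speciate_at_ph(sample, ph)
        total = state.co2_dissolved + state.hco3 + state.co3
        assert total == approx(tco2, rel=1e-12)

    @given(
        st.floats(min_value=6.0, max_value=8.0),
        st.floats(min_value=1.0, max_value=40.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_henderson_hasselbalch_identity(self, ph, tco2):
        """hco3 / co2_dissolved = 10**(pH - 6.10): the unit-convention check."""
        sample = PlasmaSample(total_co2=tco2, albumin=0.0, phosphate=0.0,
                              sid_app=0.0, u_minus=0.0)
        state = speciate_at_ph(sample, ph)
        assert state.hco3 / state.co2_dissolved == approx(
            10.0 ** (ph - 6.10), rel=1e-10
        )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=30)
    def test_net_charge_strictly_decreasing_in_ph(self, idx):
        """Dense-grid check of the monotonicity that guarantees a unique root."""
        import numpy as np

        rng = np.random.default_rng(idx)
        sample = PlasmaSample(
            total_co2=rng.uniform(1.0, 40.0),
            albumin=rng.uniform(0.0, 40.0),
            phosphate=rng.uniform(0.0, 4.0),
            sid_app=rng.uniform(-10.0, 60.0),
            u_minus=rng.uniform(-5.0, 20.0),
        )
        grid = np.linspace(6.5, 7.8, 80)
        values = [speciate_at_ph(sample, ph).net_charge for ph in grid]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestPartialPressure:
    def test_values(self):
        assert pco2_from_dissolved(1.2328) == approx(1.2328 / 0.23, rel=1e-12)
        assert pco2_from_dissolved(1.2328) == approx(5.36, abs=5e-3)
        assert pco2_from_dissolved(0.0) == 0.0
        assert dissolved_from_pco2(10.0) == approx(2.3, rel=1e-12)

    @given(st.floats(min_value=0.0, max_value=20.0))
    @settings(derandomize=True, max_examples=50)
    def test_round_trip(self, di):
        assert dissolved_from_pco2(pco2_from_dissolved(di)) == approx(
            di, rel=1e-12, abs=1e-15
        )


class TestConstants:
    def test_defaults_pin_the_mol_per_l_pk_scale(self):
        c = DEFAULT_CONSTANTS
        h = h_from_ph(7.0)
        assert c.kc / h == approx(10.0 ** (7.0 - 6.10), rel=1e-12)
        assert c.kd / h == approx(10.0 ** (7.0 - 10.2), rel=1e-12)
        assert c.kw_prime / h == approx(10.0 ** (7.0 - 10.6), rel=1e-12)
        assert c.alpha == 0.23

    def test_constants_are_injectable(self):
        custom = DissociationConstants(kc=10.0**-3.0)
        di = dissolved_co2_from_total(20.0, h_from_ph(7.0), custom)
        hco3 = bicarbonate_from_dissolved(di, h_from_ph(7.0), custom)
        assert hco3 / di == approx(10.0 ** (7.0 - 6.0), rel=1e-12)

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(InvalidConcentrationError):
            DissociationConstants(alpha=0.0)
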