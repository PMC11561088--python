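"""0D hydraulic network: elementary relations and network behaviour."""

import math

import numpy as np
import pytest

from serpmix.chip_geometry import ChipSpec, ValidationError, default_segment_sequence
from serpmix.lumped_model import (
    ACN,
    MBAR,
    TRIS,
    WATER,
    OperatingPoint,
    PressurePoint,
    SingularRegimeError,
    bend_drop,
    bend_loss_coeff,
    compare_0d_cfd,
    dean,
    limit_tfr,
    network_drop,
    reynolds,
    straight_drop,
)


class TestElementaryRelations:
    def test_straight_drop_hand_value(self):
        # inlet arm of the reference chip at FRR 1:1 (half the 0.2 ml/min TFR)
        dp = straight_drop(1.5e-3, 8.333e-2, 1e-3, 400.0 / 3.0 * 1e-6)
        assert dp == pytest.approx(2.25e2, rel=2e-3)

    def test_straight_drop_linearity_and_no_flow(self):
        base = straight_drop(1e-3, 0.1, 1e-3, 1e-4)
        assert straight_drop(2e-3, 0.1, 1e-3, 1e-4) == pytest.approx(2 * base)
        assert straight_drop(1e-3, 0.0, 1e-3, 1e-4) == 0.0

    def test_reynolds_hand_value(self):
        assert reynolds(1000.0, 0.1667, 400.0 / 3.0 * 1e-6, 1e-3) == pytest.approx(
            22.2, rel=1e-2
        )

    def test_dean_hand_value_in_regime(self):
        Re = reynolds(1000.0, 0.1667, 400.0 / 3.0 * 1e-6, 1e-3)
        Dn = dean(Re, 400.0 / 3.0 * 1e-6, 800e-6)
        assert Dn == pytest.approx(6.4, rel=1e-2)
        assert Dn < 110.0  # no-secondary-flow regime

    def test_no_flow_gives_zero_dimensionless_numbers(self):
        assert reynolds(1000.0, 0.0, 1e-4, 1e-3) == 0.0
        assert dean(0.0, 1e-4, 8e-4) == 0.0


class TestBendLoss:
    Dh = 400.0 / 3.0 * 1e-6
    R = 800e-6
    Re = 22.22
    Dn = 6.414

    def test_linear_in_angle(self):
        k90 = bend_loss_coeff(self.Re, self.Dn, self.R, math.pi / 2, self.Dh)
        k180 = bend_loss_coeff(self.Re, self.Dn, self.R, math.pi, self.Dh)
        assert k180 == pytest.approx(2 * k90, rel=1e-12)

    def test_creeping_dean_limit(self):
        k = bend_loss_coeff(self.Re, 0.0, self.R, math.pi / 2, self.Dh)
        assert k == pytest.approx(
            32.0 * self.R * math.pi / 2 / (self.Dh * self.Re), rel=1e-12
        )

    def test_both_correlation_readings_pinned(self):
        # independent hand evaluation of both readings of the printed formula
        pref = 32.0 * self.R * math.pi / 2 / (self.Dh * self.Re)
        k_lit = bend_loss_coeff(self.Re, self.Dn, self.R, math.pi / 2, self.Dh, "literal")
        k_pow = bend_loss_coeff(self.Re, self.Dn, self.R, math.pi / 2, self.Dh, "power")
        assert k_lit == pytest.approx(pref * (0.026 * self.Dn * math.e**0.661 + 1), rel=1e-12)
        assert k_pow == pytest.approx(pref * (0.026 * self.Dn**0.661 + 1), rel=1e-12)
        assert k_lit != pytest.approx(k_pow, rel=1e-3)

    def test_zero_reynolds_singular(self):
        with pytest.raises(SingularRegimeError):
            bend_loss_coeff(0.0, 0.0, self.R, math.pi, self.Dh)

    def test_bend_drop_arithmetic(self):
        assert bend_drop(1.0, 1000.0, 0.1) == pytest.approx(5.0)
        assert bend_drop(3.0, 1000.0, 0.0) == 0.0


class TestNetwork:
    def test_no_flow_limit(self, reference_spec):
        assert network_drop(reference_spec, WATER, OperatingPoint(0.0)) == 0.0

    def test_monotone_in_tfr(self, reference_spec):
        drops = [
            network_drop(reference_spec, WATER, OperatingPoint(t))
            for t in (0.05, 0.1, 0.2, 0.4)
        ]
        assert np.all(np.diff(drops) > 0)

    def test_segment_order_permutation_invariant(self, reference_spec):
        segs = list(reference_spec.segments)
        permuted = ChipSpec(segment_sequence=tuple(segs[::-1]))
        assert network_drop(permuted, WATER, OperatingPoint(0.2)) == pytest.approx(
            network_drop(reference_spec, WATER, OperatingPoint(0.2)), rel=1e-12
        )

    def test_reference_chip_pinned_by_segmentwise_oracle(self, reference_spec):
        """Brute-force segment-by-segment evaluation of the two drop laws."""
        spec = reference_spec
        Dh = 2 * 200e-6 * 100e-6 / (300e-6)
        A = 200e-6 * 100e-6
        Q = 0.2 * 1e-6 / 60
        v = Q / A
        Re = 1000.0 * v * Dh / 1e-3
        dp = 32e-3 * 1.5e-3 * (v / 2) / Dh**2  # governing inlet arm (half flow)
        for L_um in [2500.0, 5600.0] + [13000.0] * 13:
            dp += 32e-3 * (L_um * 1e-6) * v / Dh**2
        for R_um, th in [(800.0, math.pi / 2)] + [(800.0, math.pi)] * 13:
            R = R_um * 1e-6
            Dn = Re * math.sqrt(Dh / (2 * R))
            dp += (
                16 * R * (0.026 * Dn * math.e**0.661 + 1) * 1000.0 * v**2 * th / (Dh * Re)
            )
        assert network_drop(spec, WATER, OperatingPoint(0.2)) == pytest.approx(
            dp, rel=1e-9
        )

    def test_governing_inlet_branch_is_larger_drop(self, reference_spec):
        st = network_drop(
            reference_spec, WATER, OperatingPoint(0.2, (1, 7)), return_state=True
        )
        assert st.governing_inlet_drop == max(st.inlet_drops)
        assert st.inlet_drops[1] > st.inlet_drops[0]  # anti-solvent arm carries more

    def test_fluid_viscosity_scaling_of_straights(self):
        # straight-only network: drop scales linearly with viscosity
        seq = default_segment_sequence(1000, 1000, 1000, 300, 300, 2)[:1]
        spec = ChipSpec(segment_sequence=seq, n_straight=1)
        d_w = network_drop(spec, WATER, OperatingPoint(0.2))
        d_a = network_drop(spec, ACN, OperatingPoint(0.2))
        assert d_a / d_w == pytest.approx(ACN.mu / WATER.mu, rel=1e-12)


class TestLimitTFR:
    def test_defining_property(self, reference_spec):
        tfr = limit_tfr(reference_spec, WATER, 800.0)
        dp = network_drop(reference_spec, WATER, OperatingPoint(tfr))
        assert dp == pytest.approx(800.0 * MBAR, rel=1e-6)

    def test_halved_burst_means_smaller_limit(self, reference_spec):
        assert limit_tfr(reference_spec, WATER, 400.0) < limit_tfr(
            reference_spec, WATER, 800.0
        )

    def test_working_point_below_burst(self, reference_spec):
        # the study's working TFR must not rupture the cartridge
        dp = network_drop(reference_spec, WATER, OperatingPoint(0.2))
        assert dp < 800.0 * MBAR
        assert limit_tfr(reference_spec, WATER, 800.0) > 0.2


class TestCompare0DCFD:
    def test_identical_inputs_zero(self):
        a = PressurePoint(OperatingPoint(0.2), "water", 1000.0, "0d")
        b = PressurePoint(OperatingPoint(0.2), "water", 1000.0, "cfd")
        assert compare_0d_cfd(a, b) == 0.0

    def test_mismatched_operating_points_rejected(self):
        a = PressurePoint(OperatingPoint(0.2), "water", 1000.0)
        b = PressurePoint(OperatingPoint(0.4), "water", 900.0)
        with pytest.raises(ValidationError):
            compare_0d_cfd(a, b)

    def test_signed_relative_difference(self):
        a = PressurePoint(OperatingPoint(0.2), "water", 1100.0)
        b = PressurePoint(OperatingPoint(0.2), "water", 1000.0)
        assert compare_0d_cfd(a, b) == pytest.approx(0.1)
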