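"""Mixing metrics: closed forms, trivial limits, and distribution filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serpmix.chip_geometry import ValidationError
from serpmix.flow_solver import FlowField
from serpmix.lumped_model import OperatingPoint
from serpmix.mixing_metrics import (
    DegenerateReferenceError,
    ResidenceTimes,
    SectionProfile,
    area_of_precipitation,
    mixing_efficiency,
    mixing_index,
    mixing_time,
    residence_times,
)


def _profile(x, index=1, station=0.0):
    x = np.asarray(x, dtype=float)
    return SectionProfile(index=index, station=station, t=np.arange(len(x)), x=x)


class TestMixingIndex:
    def test_reference_against_itself_is_unmixed(self):
        ref = _profile([1, 1, 1, 0, 0, 0])
        assert mixing_index(ref, ref) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_profile_fully_mixed(self):
        ref = _profile([1, 1, 0, 0])
        uni = _profile([0.5, 0.5, 0.5, 0.5], index=2)
        assert mixing_index(uni, ref) == pytest.approx(100.0)

    def test_degenerate_reference_rejected(self):
        uni = _profile([0.5, 0.5, 0.5])
        with pytest.raises(DegenerateReferenceError):
            mixing_index(uni, uni)

    def test_mismatched_sample_counts_rejected(self):
        with pytest.raises(ValidationError):
            mixing_index(_profile([0, 1, 1]), _profile([0, 1]))

    @given(
        shift=st.floats(-0.2, 0.2),
        amp=st.floats(0.05, 0.25),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_to_constant_shift(self, shift, amp):
        # variance-based: adding a constant to both sections changes nothing
        rng = np.random.default_rng(7)
        base = 0.5 + amp * np.sign(np.linspace(-1, 1, 10))
        cur = 0.5 + amp * rng.uniform(-1, 1, 10) * 0.3
        mi0 = mixing_index(_profile(cur, 2), _profile(base))
        mi1 = mixing_index(_profile(cur + shift, 2), _profile(base + shift))
        assert mi1 == pytest.approx(mi0, abs=1e-9)

    def test_clamped_to_range(self):
        ref = _profile([0.4, 0.6])
        worse = _profile([0.0, 1.0], index=2)  # larger variance than reference
        assert mixing_index(worse, ref) == 0.0


class TestMixingEfficiency:
    def test_all_pure_solvent_is_zero(self, small_mesh):
        y = np.ones(small_mesh.shape)
        assert mixing_efficiency(y, small_mesh) == pytest.approx(0.0)

    def test_one_unmixed_cell_of_four(self, small_mesh):
        y = np.array([[1.0, 0.5], [0.2, 0.9]])
        assert mixing_efficiency(y, None) == pytest.approx(75.0)

    def test_threshold_is_strict_greater(self, small_mesh):
        y = np.full((2, 2), 0.95)
        assert mixing_efficiency(y, None) == pytest.approx(100.0)


class TestAreaOfPrecipitation:
    def test_uniform_inside_window(self, small_mesh):
        x = np.full(small_mesh.shape, 0.8)
        pct, mask = area_of_precipitation(x, small_mesh)
        assert pct == pytest.approx(100.0)
        assert mask.all()

    def test_uniform_outside_window(self, small_mesh):
        x = np.full(small_mesh.shape, 0.5)
        pct, mask = area_of_precipitation(x, small_mesh)
        assert pct == 0.0
        assert not mask.any()

    def test_strict_bounds(self, small_mesh):
        x = np.full(small_mesh.shape, 0.95)
        pct, _ = area_of_precipitation(x, small_mesh)
        assert pct == 0.0

    def test_area_weighted_not_cell_counted(self, small_mesh):
        # put the window only on the largest-area cells; AoP% uses areas
        order = np.argsort(small_mesh.area, axis=None)
        x = np.zeros(small_mesh.n_cells)
        big = order[-small_mesh.n_cells // 10 :]
        x[big] = 0.8
        pct, mask = area_of_precipitation(x.reshape(small_mesh.shape), small_mesh)
        frac = small_mesh.area.ravel()[big].sum() / small_mesh.total_area()
        assert pct == pytest.approx(100 * frac, rel=1e-12)


class TestMixingTime:
    @pytest.mark.parametrize(
        "frr_n, expected",
        [
            (1.0, 0.31746),  # w^2/(9 D (1+1)^2)
            (3.0, 0.71429),
            (5.0, 0.88183),
            (7.0, 0.97222),
        ],
    )
    def test_hand_values(self, frr_n, expected):
        tau = mixing_time(200e-6, 3.5e-9, frr_n)
        assert tau == pytest.approx(expected, rel=1e-4)

    def test_infinite_dilution_limit(self):
        w, D = 200e-6, 3.5e-9
        assert mixing_time(w, D, 1e12) == pytest.approx(w**2 / (9 * D), rel=1e-9)

    def test_accepts_operating_point(self):
        tau = mixing_time(200e-6, 3.5e-9, OperatingPoint(0.2, (1, 7)))
        assert tau == pytest.approx(0.97222, rel=1e-4)

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValidationError):
            mixing_time(200e-6, 3.5e-9, 0.0)


def _flow_with_speed(mesh, speed):
    z = np.zeros(mesh.shape)
    return FlowField(
        u=speed, v=z, p=z, m_s=np.zeros((mesh.n_s + 1, mesh.n_t)),
        m_t=np.zeros((mesh.n_s, mesh.n_t + 1)), residual_history=[], n_iterations=0,
        converged=True, reynolds=0.0, dean_max=0.0, dp_inlet=0.0, mass_balance_error=0.0,
    )


class TestResidenceTimes:
    def test_outlet_cells_filtered_by_tau_mix(self, small_mesh):
        mask = np.zeros(small_mesh.shape, dtype=bool)
        mask[-1, :] = True  # cells at the outlet column: tiny L
        flow = _flow_with_speed(small_mesh, np.full(small_mesh.shape, 0.1))
        rt = residence_times(mask, flow, small_mesh, tau_mix_s=0.31746)
        assert rt.filtered.size == 0
        assert rt.raw.size == small_mesh.n_t

    def test_halving_velocity_doubles_tau(self, small_mesh):
        mask = np.zeros(small_mesh.shape, dtype=bool)
        mask[: small_mesh.n_s // 2] = True
        f1 = _flow_with_speed(small_mesh, np.full(small_mesh.shape, 0.2))
        f2 = _flow_with_speed(small_mesh, np.full(small_mesh.shape, 0.1))
        r1 = residence_times(mask, f1, small_mesh, 0.0)
        r2 = residence_times(mask, f2, small_mesh, 0.0)
        assert np.allclose(r2.raw, 2 * r1.raw)

    def test_stagnant_cells_excluded(self, small_mesh):
        mask = np.zeros(small_mesh.shape, dtype=bool)
        mask[0, :2] = True
        speed = np.full(small_mesh.shape, 0.1)
        speed[0, 0] = 0.0
        rt = residence_times(mask, _flow_with_speed(small_mesh, speed), small_mesh, 0.0)
        assert rt.n_stagnant == 1
        assert rt.raw.size == 1

    def test_filtering_cannot_decrease_median(self, small_mesh):
        mask = np.ones(small_mesh.shape, dtype=bool)
        flow = _flow_with_speed(small_mesh, np.full(small_mesh.shape, 0.15))
        r0 = residence_times(mask, flow, small_mesh, 0.0)
        r1 = residence_times(mask, flow, small_mesh, float(np.median(r0.raw)) * 0.5)
        assert r1.median >= r0.median - 1e-15

    def test_percentiles_linear_interpolation(self):
        rt = ResidenceTimes(
            raw=np.array([1.0, 2, 3, 4]), filtered=np.array([1.0, 2, 3, 4]),
            tau_mix=0.0, n_stagnant=0,
        )
        assert rt.percentiles().tolist() == [1.75, 2.5, 3.25]

    def test_empty_aop_gives_nan_stats(self):
        rt = ResidenceTimes(raw=np.array([]), filtered=np.array([]), tau_mix=1.0, n_stagnant=0)
        assert np.isnan(rt.median)
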