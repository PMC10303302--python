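import numpy as np
import pytest

from vffr import (
    BloodProperties,
    FlowState,
    ReferenceLine,
    VesselProfile,
    compute_vffr,
    ffr_pullback,
    fit_reference,
    hyperemic_flow,
    pressure_drop,
    resample_profile,
    solve_1d_steady,
)
from vffr.hemodynamics import MMHG_PA, NonPhysicalFlowError

from conftest import LIBRARY_FLOW_ML_S, lesion_library


def flat_reference(profile, d_mm=3.0):
    return ReferenceLine(0.0, d_mm, fit_mask=np.ones(profile.n_samples, bool))


class TestHyperemicFlow:
    def test_frame_count_transit_velocity(self, uniform_tube):
        ref = flat_reference(uniform_tube)
        flow = hyperemic_flow(
            uniform_tube, ref, mode="frame_count", frame_transit=(30, 15.0, 60.0)
        )
        assert flow.v_ref_m_s == pytest.approx(0.030)  # 60 mm in 2 s
        assert flow.q_ml_s == pytest.approx(0.030 * np.pi * 1.5**2)

    def test_diameter_scaling_default_constant(self, uniform_tube):
        ref = flat_reference(uniform_tube)
        flow = hyperemic_flow(uniform_tube, ref)
        assert flow.v_ref_m_s == pytest.approx(0.35, abs=1e-3)
        # cross-check Q = v * A with A = pi * 1.5^2 = 7.069 mm^2
        assert flow.q_ml_s == pytest.approx(0.35 * 7.0686, rel=1e-3)

    def test_velocity_scales_with_diameter_squared(self, uniform_tube):
        f3 = hyperemic_flow(uniform_tube, flat_reference(uniform_tube, 3.0))
        f6 = hyperemic_flow(uniform_tube, flat_reference(uniform_tube, 6.0))
        assert f6.v_ref_m_s == pytest.approx(4 * f3.v_ref_m_s)
        assert f6.q_ml_s == pytest.approx(16 * f3.q_ml_s)

    def test_frame_mode_requires_transit_data(self, uniform_tube):
        with pytest.raises(ValueError):
            hyperemic_flow(uniform_tube, flat_reference(uniform_tube), mode="frame_count")


class TestPressureDrop:
    def test_zero_flow_gives_zero_drop(self, uniform_tube):
        flow = FlowState(q_ml_s=0.0, v_ref_m_s=0.0, source="fixed")
        field = pressure_drop(uniform_tube, flow)
        np.testing.assert_array_equal(field.cumulative_drop_mmhg, 0.0)
        curve = ffr_pullback(field)
        np.testing.assert_array_equal(curve.ffr, 1.0)

    def test_poiseuille_closed_form_straight_tube(self, uniform_tube):
        # dP = 8 mu L Q / (pi r^4): 105.6 Pa for d=3mm, L=30mm, Q=2mL/s
        flow = FlowState(q_ml_s=2.0, v_ref_m_s=0.283, source="fixed")
        blood = BloodProperties(viscosity_pa_s=0.0035)
        expected_pa = 8 * 0.0035 * 0.030 * 2e-6 / (np.pi * 1.5e-3**4)
        field = pressure_drop(resample_profile(uniform_tube, 0.1), flow, blood)
        assert field.distal_drop_mmhg * MMHG_PA == pytest.approx(expected_pa, rel=1e-6)
        assert field.distal_drop_mmhg == pytest.approx(0.792, abs=0.01)
        np.testing.assert_array_equal(field.expansion_component_mmhg, 0.0)

    def test_components_sum_and_are_monotone(self, stenotic_vessel):
        profile, _ = stenotic_vessel
        ref = fit_reference(profile, lesion_exclusion=(24.0, 36.0))
        flow = hyperemic_flow(profile, ref)
        field = pressure_drop(profile, flow)
        np.testing.assert_allclose(
            field.cumulative_drop_mmhg,
            field.viscous_component_mmhg + field.expansion_component_mmhg,
            atol=1e-12,
        )
        assert np.all(np.diff(field.viscous_component_mmhg) >= 0)
        assert np.all(np.diff(field.expansion_component_mmhg) >= -1e-15)

    def test_component_scaling_in_flow(self, stenotic_vessel):
        """Viscous drop is linear in Q; expansion drop is quadratic in Q."""
        profile, _ = stenotic_vessel
        f1 = FlowState(q_ml_s=1.5, v_ref_m_s=0.2, source="fixed")
        f2 = FlowState(q_ml_s=3.0, v_ref_m_s=0.4, source="fixed")
        p1, p2 = pressure_drop(profile, f1), pressure_drop(profile, f2)
        assert p2.viscous_component_mmhg[-1] == pytest.approx(
            2 * p1.viscous_component_mmhg[-1], rel=1e-9
        )
        assert p2.expansion_component_mmhg[-1] == pytest.approx(
            4 * p1.expansion_component_mmhg[-1], rel=1e-9
        )

    def test_abrupt_expansion_matches_borda_carnot(self):
        # 75% area stenosis with an abrupt distal expansion
        s = np.arange(0.0, 30.0 + 1e-9, 0.1)
        a_ref = np.pi * 1.5**2
        area = np.where((s >= 10.0) & (s <= 20.0), 0.25 * a_ref, a_ref)
        profile = VesselProfile(s, area)
        flow = FlowState(q_ml_s=2.0, v_ref_m_s=0.283, source="fixed")
        blood = BloodProperties()
        field = pressure_drop(profile, flow, blood)
        q = 2e-6
        bc = 0.5 * blood.density_kg_m3 * q * q * (1 / (0.25 * a_ref * 1e-6) - 1 / (a_ref * 1e-6)) ** 2
        assert field.expansion_component_mmhg[-1] == pytest.approx(bc / MMHG_PA, rel=1e-6)
        fv = solve_1d_steady(profile, flow, blood, n_cells=300)
        assert fv.distal_drop_mmhg == pytest.approx(field.distal_drop_mmhg, rel=0.05)


class TestFfrPullback:
    def test_simple_ratio(self, uniform_tube):
        # Pa = 90, distal drop 18 mmHg -> FFR 0.80
        s = uniform_tube.arclength_mm
        from vffr import PressureField

        drop = np.linspace(0.0, 18.0, s.size)
        field = PressureField(s, drop, drop, np.zeros_like(drop))
        curve = ffr_pullback(field, pa_mmhg=90.0)
        assert curve.ffr_distal == pytest.approx(0.80)
        assert curve.ffr[0] == 1.0

    def test_nonphysical_regime_raises(self, uniform_tube):
        from vffr import PressureField

        s = uniform_tube.arclength_mm
        drop = np.linspace(0.0, 95.0, s.size)
        field = PressureField(s, drop, drop, np.zeros_like(drop))
        with pytest.raises(NonPhysicalFlowError):
            ffr_pullback(field, pa_mmhg=90.0)

    def test_pullback_monotone_on_lesion_library(self):
        for profile, _ in lesion_library():
            curve = compute_vffr(
                profile, engine="reduced_order", flow_mode="fixed", q_fixed_ml_s=LIBRARY_FLOW_ML_S
            )
            assert np.all(np.diff(curve.ffr) <= 1e-12)
            assert curve.ffr[0] == pytest.approx(1.0)

    def test_severe_lesion_at_full_hyperemia_is_nonphysical_in_both_engines(self):
        from vffr import StenosisSpec, VesselSpec, make_vessel

        spec = VesselSpec(stenoses=(StenosisSpec(center_mm=30.0, length_mm=15.0, ds_pct=80.0),))
        profile, _ = make_vessel(spec)
        for engine in ("reduced_order", "fv1d"):
            with pytest.raises(NonPhysicalFlowError):
                compute_vffr(profile, engine=engine)


class TestFiniteVolumeSolver:
    def test_uniform_tube_matches_poiseuille(self, uniform_tube):
        flow = FlowState(q_ml_s=2.0, v_ref_m_s=0.283, source="fixed")
        blood = BloodProperties(viscosity_pa_s=0.0035)
        field = solve_1d_steady(uniform_tube, flow, blood, n_cells=200)
        expected = 8 * 0.0035 * 0.030 * 2e-6 / (np.pi * 1.5e-3**4) / MMHG_PA
        # cell centers stop half a cell short of the outlet
        expected *= (200 - 0.5) / 200
        assert field.distal_drop_mmhg == pytest.approx(expected, rel=0.005)

    def test_zero_flow(self, uniform_tube):
        flow = FlowState(q_ml_s=0.0, v_ref_m_s=0.0, source="fixed")
        field = solve_1d_steady(uniform_tube, flow, n_cells=64)
        np.testing.assert_array_equal(field.cumulative_drop_mmhg, 0.0)

    def test_grid_convergence_order_at_least_one(self, stenotic_vessel):
        profile, _ = stenotic_vessel
        ref = fit_reference(profile, lesion_exclusion=(24.0, 36.0))
        flow = hyperemic_flow(profile, ref)
        drops = {}
        for n in (100, 200, 400, 3200):
            drops[n] = solve_1d_steady(profile, flow, n_cells=n).distal_drop_mmhg
        e = {n: abs(drops[n] - drops[3200]) for n in (100, 200, 400)}
        order = np.log2(e[100] / e[200])
        assert order >= 1.0
        assert abs(drops[400] - drops[3200]) < abs(drops[100] - drops[3200])

    def test_rejects_too_few_cells(self, uniform_tube):
        flow = FlowState(q_ml_s=1.0, v_ref_m_s=0.14, source="fixed")
        with pytest.raises(ValueError):
            solve_1d_steady(uniform_tube, flow, n_cells=8)


class TestComputeVffr:
    def test_uniform_tube_stays_near_one(self):
        # 25 mm healthy 3 mm segment: Poiseuille drop < 1 mmHg at default flow
        s = np.arange(0.0, 25.0 + 1e-9, 0.5)
        tube = VesselProfile(s, np.full(s.size, np.pi * 1.5**2))
        for engine in ("reduced_order", "fv1d"):
            curve = compute_vffr(tube, engine=engine)
            field = curve.provenance["pressure_field"]
            assert field.distal_drop_mmhg < 1.0
            assert curve.ffr_distal > 0.99

    def test_zero_flow_gives_exactly_one(self, uniform_tube):
        curve = compute_vffr(uniform_tube, flow_mode="fixed", q_fixed_ml_s=0.0)
        assert curve.ffr_distal == 1.0

    def test_engines_agree_on_moderate_lesion(self, stenotic_vessel):
        profile, _ = stenotic_vessel
        ro = compute_vffr(profile, engine="reduced_order")
        fv = compute_vffr(profile, engine="fv1d", n_cells=600)
        assert abs(ro.ffr_distal - fv.ffr_distal) < 0.02

    def test_engine_agreement_across_lesion_library(self):
        """Reduced-order vs finite-volume within 0.02 FFR on 20 lesions."""
        for profile, _ in lesion_library():
            kw = dict(flow_mode="fixed", q_fixed_ml_s=LIBRARY_FLOW_ML_S)
            ro = compute_vffr(profile, engine="reduced_order", **kw)
            fv = compute_vffr(profile, engine="fv1d", n_cells=600, **kw)
            assert abs(ro.ffr_distal - fv.ffr_distal) < 0.02, profile

    def test_ffr_invariant_to_fine_resampling(self, stenotic_vessel):
        profile, _ = stenotic_vessel
        c1 = compute_vffr(profile, step_mm=0.1)
        c2 = compute_vffr(profile, step_mm=0.025)
        assert abs(c1.ffr_distal - c2.ffr_distal) < 0.005

    def test_provenance_records_engine(self, uniform_tube):
        curve = compute_vffr(uniform_tube, engine="fv1d")
        assert curve.provenance["engine"] == "fv1d"
        assert curve.provenance["n_cells"] == 400
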