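"""Structural model construction, simulation, and closed-form agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xspeciespk import (
    DoseEvent,
    PKParameters,
    StructuralModelSpec,
    ValidationError,
    build_model,
    closed_form_reference,
    effective_F,
    simulate_profile,
)
from conftest import iv_dose, oral_dose


class TestSpecValidation:
    @pytest.mark.parametrize(
        "spec,required",
        [
            (StructuralModelSpec(2, "dual_first_order"),
             {"CL", "V1", "V2", "Q", "ka1", "ka2", "frac1", "F"}),
            (StructuralModelSpec(1, "iv_bolus"), {"CL", "V1"}),
            (StructuralModelSpec(1, "transit_chain", features={"ehc"}, n_transit=3),
             {"MTT", "f_bile", "k_bile", "t_empty"}),
        ],
    )
    def test_required_parameters(self, spec, required):
        model = build_model(spec)
        assert required <= set(model.required_parameters)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_compartments=3, absorption="iv_bolus"),
            dict(n_compartments=1, absorption="gut_wall"),
            dict(n_compartments=1, absorption="first_order", n_transit=2),
            dict(n_compartments=1, absorption="transit_chain", n_transit=0),
            dict(n_compartments=1, absorption="iv_bolus", features={"dose_on_F"}),
        ],
    )
    def test_inconsistent_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            StructuralModelSpec(**kwargs)

    def test_missing_parameter_named_in_error(self):
        spec = StructuralModelSpec(2, "first_order", features={"ehc"})
        model = build_model(spec)
        p = PKParameters(CL=1.0, V1=5.0, V2=5.0, Q=1.0, ka1=1.0, F=0.5,
                         k_bile=1.0, t_empty=2.0)  # f_bile absent
        with pytest.raises(ValidationError, match="f_bile"):
            model.simulate(p, [oral_dose()], np.linspace(0, 24, 25))

    def test_parameter_invariants(self):
        with pytest.raises(ValidationError):
            PKParameters(CL=-1.0, V1=5.0)
        with pytest.raises(ValidationError):
            PKParameters(CL=1.0, V1=5.0, F=1.5)
        with pytest.raises(ValidationError):
            PKParameters(CL=1.0, V1=5.0, frac1=1.2)


class TestSimulation:
    def test_zero_dose_gives_zero_profile(self, oral_1cmt):
        _, model, params = oral_1cmt
        prof = simulate_profile(model, params, [oral_dose(amount=0.0)],
                                np.linspace(0, 24, 49))
        assert np.all(prof.concentrations == 0)

    def test_iv_bolus_c0_is_dose_over_volume(self):
        model = build_model(StructuralModelSpec(1, "iv_bolus"))
        p = PKParameters(CL=1.0, V1=0.02)
        prof = model.simulate(p, [iv_dose(1.0)], np.linspace(0, 1, 11))
        # 1 mg / 0.02 L = 50 ug/mL = 50000 ng/mL
        assert prof.concentrations[0] == pytest.approx(50000.0, rel=1e-9)

    @pytest.mark.parametrize("fixture", ["oral_1cmt", "iv_1cmt", "iv_2cmt"])
    def test_ode_matches_closed_form(self, fixture, grid_120h, request):
        spec, model, params = request.getfixturevalue(fixture)
        route = "iv_bolus" if spec.absorption == "iv_bolus" else "oral_solution"
        prof = model.simulate(params, [DoseEvent("s", 0.0, 1.0, route=route)],
                              grid_120h, method="ode")
        ref = closed_form_reference(spec, params, 1.0, grid_120h, route=route)
        mask = ref > 1e-12
        rel = np.abs(prof.concentrations[mask] - ref[mask]) / ref[mask]
        assert rel.max() < 1e-6

    def test_biexponential_2cmt_iv(self, iv_2cmt, grid_120h):
        spec, model, params = iv_2cmt
        prof = model.simulate(params, [iv_dose(1.0)], grid_120h, method="ode")
        ref = closed_form_reference(spec, params, 1.0, grid_120h, route="iv_bolus")
        assert np.allclose(prof.concentrations, ref, rtol=1e-6)

    @pytest.mark.parametrize(
        "spec,params",
        [
            (StructuralModelSpec(2, "dual_first_order"),
             PKParameters(CL=0.045, V1=0.1, V2=0.15, Q=0.05, ka1=2.5, ka2=0.4,
                          frac1=0.6, F=0.7)),
            (StructuralModelSpec(1, "transit_chain", n_transit=3),
             PKParameters(CL=0.05, V1=0.15, MTT=1.2, F=0.4)),
        ],
    )
    def test_analytic_path_matches_ode(self, spec, params):
        model = build_model(spec)
        grid = np.linspace(0, 24, 241)
        ode = model.simulate(params, [oral_dose(0.3)], grid, method="ode")
        ana = model.simulate(params, [oral_dose(0.3)], grid, method="analytic")
        assert np.allclose(ode.concentrations, ana.concentrations,
                           rtol=1e-6, atol=1e-4)

    def test_superposition_dose_doubling(self, iv_2cmt):
        _, model, params = iv_2cmt
        grid = np.linspace(0, 48, 97)
        one = model.simulate(params, [iv_dose(1.0)], grid)
        two = model.simulate(params, [iv_dose(2.0)], grid)
        assert np.allclose(two.concentrations, 2 * one.concentrations, rtol=1e-8)

    def test_zero_order_release_delays_absorption(self):
        spec = StructuralModelSpec(1, "first_order")
        model = build_model(spec)
        p = PKParameters(CL=0.5, V1=5.0, ka1=1.2, F=0.8, D_zero=0.75)
        grid = np.linspace(0, 48, 961)
        tablet = model.simulate(p, [oral_dose(1.0, route="oral_tablet")], grid)
        solution = model.simulate(p, [oral_dose(1.0, route="oral_solution")], grid)
        # during the release window the tablet profile lags the solution
        assert tablet.concentrations[5] < solution.concentrations[5]
        # total exposure unaffected by release rate (linear model)
        assert np.trapezoid(tablet.concentrations, grid) == pytest.approx(
            np.trapezoid(solution.concentrations, grid), rel=1e-3
        )


class TestConservation:
    @pytest.mark.parametrize(
        "spec,params,dose",
        [
            (StructuralModelSpec(1, "first_order"),
             PKParameters(CL=0.5, V1=5.0, ka1=1.2, F=0.8), oral_dose(1.0)),
            (StructuralModelSpec(2, "dual_first_order"),
             PKParameters(CL=0.045, V1=0.1, V2=0.15, Q=0.05, ka1=2.5, ka2=0.4,
                          frac1=0.6, F=0.7), oral_dose(0.3)),
            (StructuralModelSpec(2, "iv_bolus"),
             PKParameters(CL=1.0, V1=5.0, V2=10.0, Q=2.0), iv_dose(1.0)),
        ],
    )
    def test_mass_balance_without_ehc(self, spec, params, dose):
        model = build_model(spec)
        grid = np.linspace(0, 48, 49)
        _, states = model.simulate(params, [dose], grid, method="ode",
                                   return_states=True)
        f = params.F if dose.route != "iv_bolus" else 1.0
        total = states["amounts"][: model.i_elim + 1].sum(axis=0)
        assert np.allclose(total, f * dose.amount, rtol=1e-6)

    def test_ehc_recycled_mass_bounded(self):
        spec = StructuralModelSpec(1, "transit_chain", features={"ehc"}, n_transit=3)
        model = build_model(spec)
        p = PKParameters(CL=0.05, V1=0.15, MTT=1.2, F=0.4,
                         f_bile=0.25, k_bile=1.5, t_empty=3.0)
        grid = np.linspace(0, 48, 193)
        _, states = model.simulate(p, [oral_dose(1.5)], grid, method="ode",
                                   return_states=True)
        assert np.all(
            states["recycled"] <= p.f_bile * states["hepatic_eliminated"] + 1e-9
        )
        # the gallbladder stays shut before the emptying time
        pre = grid < p.t_empty
        assert np.all(states["recycled"][pre] == 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        cl=st.floats(0.01, 5.0),
        v1=st.floats(0.05, 50.0),
        ka=st.floats(0.05, 10.0),
        f=st.floats(0.05, 1.0),
    )
    def test_states_nonnegative_for_random_parameters(self, cl, v1, ka, f):
        model = build_model(StructuralModelSpec(1, "first_order"))
        p = PKParameters(CL=cl, V1=v1, ka1=ka, F=f)
        grid = np.linspace(0, 24, 49)
        prof, states = model.simulate(p, [oral_dose(1.0)], grid, method="ode",
                                      return_states=True)
        assert states["amounts"].min() > -1e-9
        assert prof.concentrations.min() >= 0


class TestClosedFormEdges:
    def test_flip_flop_limit_ka_equals_ke(self):
        spec = StructuralModelSpec(1, "first_order")
        p = PKParameters(CL=1.0, V1=2.0, ka1=0.5, F=1.0)  # ke = ka = 0.5
        t = np.array([0.0, 1.0, 2.0, 4.0])
        ref = closed_form_reference(spec, p, 1.0, t)
        expect = 1.0 * 1.0 * 0.5 * t * np.exp(-0.5 * t) / 2.0 * 1000.0
        assert np.allclose(ref, expect, rtol=1e-9)
        assert ref[0] == 0.0

    def test_half_life_identity(self):
        spec = StructuralModelSpec(1, "iv_bolus")
        p = PKParameters(CL=0.5, V1=5.0)
        t_half = np.log(2) * 5.0 / 0.5
        ref = closed_form_reference(spec, p, 1.0, np.array([0.0, t_half]),
                                    route="iv_bolus")
        assert ref[1] == pytest.approx(ref[0] / 2.0, rel=1e-12)

    def test_unsupported_spec_raises(self):
        spec = StructuralModelSpec(2, "dual_first_order")
        p = PKParameters(CL=1.0, V1=5.0, V2=5.0, Q=1.0, ka1=1.0, ka2=0.5,
                         frac1=0.5, F=0.8)
        with pytest.raises(ValidationError):
            closed_form_reference(spec, p, 1.0, np.array([1.0]))


class TestEffectiveF:
    def test_no_dose_effect_is_identity(self):
        p = PKParameters(F=0.5, theta_dose=None)
        assert effective_F(p, 100.0, 50.0) == 0.5

    def test_reference_dose_is_identity(self):
        p = PKParameters(F=0.5, theta_dose=0.01)
        assert effective_F(p, 80.0, 80.0) == pytest.approx(0.5)

    def test_halving_at_ln2_over_theta(self):
        p = PKParameters(F=0.5, theta_dose=0.01)
        assert effective_F(p, 100.0, 100.0 - 69.3) == pytest.approx(0.25, rel=1e-3)

    def test_clamped_above_one_with_warning(self):
        p = PKParameters(F=0.9, theta_dose=0.01)
        with pytest.warns(UserWarning, match="clamp"):
            assert effective_F(p, 10.0, 100.0) == 1.0

    def test_monotone_decreasing_in_dose(self):
        p = PKParameters(F=0.5, theta_dose=0.01)
        vals = [effective_F(p, d, 100.0) for d in (100.0, 150.0, 200.0)]
        assert vals[0] > vals[1] > vals[2]
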