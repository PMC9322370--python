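"""Allometric scaling, ionization and dissolution corrections, simplification."""

import numpy as np
import pytest

from xspeciespk import (
    DissolutionCorrection,
    DoseEvent,
    IonizationSpec,
    PKParameters,
    ScalingPolicy,
    StructuralModelSpec,
    ValidationError,
    allometric_scale,
    apply_dissolution,
    auc_inf,
    build_model,
    fraction_ionized,
    get_preset,
    ionization_corrected_F,
    simplify_for_translation,
)


class TestAllometricScale:
    def test_reference_weight_is_identity(self):
        p = PKParameters(CL=0.05, V1=0.1, V2=0.2, Q=0.03)
        out = allometric_scale(p, 30.0)
        for name in ("CL", "V1", "V2", "Q"):
            assert out.get(name) == pytest.approx(p.get(name), rel=1e-12)

    def test_human_weight_multipliers(self):
        p = PKParameters(CL=1.0, V1=1.0, Q=1.0, V2=1.0)
        out = allometric_scale(p, 70_000.0)
        assert out.CL == pytest.approx((70_000 / 30) ** 0.75, rel=1e-9)
        assert out.Q == pytest.approx((70_000 / 30) ** 0.75, rel=1e-9)
        assert out.V1 == pytest.approx(70_000 / 30, rel=1e-9)
        assert out.V2 == pytest.approx(70_000 / 30, rel=1e-9)

    def test_rate_constants_and_fractions_untouched(self):
        p = PKParameters(CL=0.05, V1=0.1, ka1=1.3, F=0.6, MTT=1.2)
        out = allometric_scale(p, 70_000.0)
        assert out.ka1 == p.ka1
        assert out.F == p.F
        assert out.MTT == p.MTT

    def test_double_scaling_raises(self):
        p = PKParameters(CL=0.05, V1=0.1)
        out = allometric_scale(p, 70_000.0)
        assert out.scaled_from_mouse
        with pytest.raises(ValidationError, match="already scaled"):
            allometric_scale(out, 60_000.0)

    def test_auc_consistency_under_scaling(self):
        # linear model: scaled-human AUC_inf == F * Dose / CL_scaled
        preset = get_preset("brigatinib")
        model = build_model(preset.optimized_spec)
        scaled = allometric_scale(preset.mouse_params_optimized, 70_000.0)
        dose = 180.0
        grid = np.linspace(0.0, 240.0, 2401)
        prof = model.simulate(
            scaled, [DoseEvent("h", 0.0, dose)], grid, method="ode"
        )
        analytic = scaled.get("F") * dose / scaled.get("CL")
        assert auc_inf(prof) == pytest.approx(analytic, rel=0.005)


class TestIonization:
    def test_half_ionized_at_pka(self):
        assert fraction_ionized(3.79, 3.79) == 0.5

    def test_reported_stomach_fractions(self):
        assert fraction_ionized(1.75, 3.79) == pytest.approx(0.9910, abs=5e-4)
        assert fraction_ionized(3.5, 3.79) == pytest.approx(0.6607, abs=5e-4)

    def test_strictly_decreasing_in_ph(self):
        vals = [fraction_ionized(ph, 3.79) for ph in np.linspace(0.5, 13.5, 40)]
        assert np.all(np.diff(vals) < 0)
        assert all(0 < v < 1 for v in vals)

    def test_equal_phs_leave_f_unchanged(self):
        spec = IonizationSpec(pKa=3.79, pH_human_stomach=2.0, pH_mouse_stomach=2.0)
        assert ionization_corrected_F(0.4, spec) == pytest.approx(0.4)

    def test_fisogatinib_correction(self):
        assert ionization_corrected_F(0.40, IonizationSpec(pKa=3.79)) == pytest.approx(
            0.60, abs=0.005
        )

    def test_clamped_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert ionization_corrected_F(0.80, IonizationSpec(pKa=3.79)) == 1.0

    def test_monotone_in_f_mouse(self):
        spec = IonizationSpec(pKa=3.79)
        vals = [ionization_corrected_F(f, spec) for f in (0.1, 0.2, 0.3, 0.4)]
        assert np.all(np.diff(vals) > 0)


class TestDissolution:
    def test_zero_order_presets(self):
        for drug, d_zero in (("lorlatinib", 0.75), ("brigatinib", 0.75),
                             ("ribociclib", 0.5)):
            preset = get_preset(drug)
            _, p = apply_dissolution(
                preset.optimized_spec, preset.mouse_params_optimized,
                preset.dissolution,
            )
            assert p.D_zero == d_zero

    def test_mtt_shift_preset(self):
        preset = get_preset("fisogatinib")
        _, p = apply_dissolution(
            preset.optimized_spec, preset.mouse_params_optimized,
            preset.dissolution,
        )
        assert p.MTT == pytest.approx(preset.mouse_params_optimized.MTT + 0.375)

    def test_solution_route_unchanged(self):
        preset = get_preset("lorlatinib")
        spec, p = apply_dissolution(
            preset.final_spec, preset.mouse_params_final, preset.dissolution,
            route="oral_solution",
        )
        assert p == preset.mouse_params_final

    def test_mtt_shift_without_mtt_raises(self):
        with pytest.raises(ValidationError, match="MTT"):
            apply_dissolution(
                StructuralModelSpec(1, "first_order"),
                PKParameters(CL=1.0, V1=5.0, ka1=1.0, F=0.5),
                DissolutionCorrection("mtt_shift", 0.375),
            )


class TestSimplify:
    def test_ribociclib_loses_ehc(self):
        spec = get_preset("ribociclib").final_spec
        out = simplify_for_translation(spec)
        assert "ehc" not in out.features
        assert out.n_compartments == 2

    def test_brigatinib_loses_dose_effect(self):
        spec = get_preset("brigatinib").final_spec
        out = simplify_for_translation(spec)
        assert "dose_on_F" not in out.features

    def test_lorlatinib_unchanged(self):
        spec = get_preset("lorlatinib").final_spec
        assert simplify_for_translation(spec) == spec


def test_scaling_policy_validation():
    with pytest.raises(ValidationError):
        ScalingPolicy(reference_weight=0.0)
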