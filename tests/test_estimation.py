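"""Pooled likelihood, fitting, and the dOFV covariate rule."""

import math

import numpy as np
import pandas as pd
import pytest

from xspeciespk import (
    BSVModel,
    CovariateEffect,
    ErrorModel,
    FitResult,
    PKParameters,
    StructuralModelSpec,
    ValidationError,
    build_model,
    closed_form_reference,
    fit_pooled,
    lrt_covariate,
    neg2ll,
)
from xspeciespk.synthetic import (
    DoseArm,
    MouseStudyDataset,
    StudyDesign,
    generate_mouse_study,
)


def make_dataset(rows):
    cols = ["ID", "TIME", "AMT", "DV", "EVID", "STRAIN", "BWT", "DOSEGRP",
            "ROUTE", "BLQ"]
    return MouseStudyDataset(pd.DataFrame(rows, columns=cols))


def iv_rows(sid, dose, times, dvs, strain="WT"):
    rows = [dict(ID=sid, TIME=0.0, AMT=dose, DV=np.nan, EVID=1, STRAIN=strain,
                 BWT=30.0, DOSEGRP=dose, ROUTE="iv_bolus", BLQ=0)]
    for t, dv in zip(times, dvs):
        rows.append(dict(ID=sid, TIME=t, AMT=np.nan, DV=dv, EVID=0,
                         STRAIN=strain, BWT=30.0, DOSEGRP=dose,
                         ROUTE="iv_bolus", BLQ=0))
    return rows


class TestNeg2LL:
    def test_single_exact_observation_gives_log_2pi(self):
        # pred == obs with unit additive sd: OFV = ln(2*pi)
        model = build_model(StructuralModelSpec(1, "iv_bolus"))
        p = PKParameters(CL=1.0, V1=0.1)  # ke = 10/h
        t = math.log(1000.0) / 10.0       # prediction decays to exactly 10 ng/mL
        ds = make_dataset(iv_rows(1, 1.0, [t], [10.0]))
        ofv = neg2ll(model, p, ErrorModel(0.0, 1.0), ds)
        assert ofv == pytest.approx(math.log(2 * math.pi), abs=1e-6)

    def test_hand_summed_three_point_dataset(self):
        spec = StructuralModelSpec(1, "iv_bolus")
        model = build_model(spec)
        p = PKParameters(CL=0.5, V1=5.0)
        times = [1.0, 4.0, 8.0]
        obs = [180.0, 120.0, 80.0]
        err = ErrorModel(0.15, 1.0)
        # independent oracle: textbook closed form + explicit normal density sum
        preds = closed_form_reference(spec, p, 1.0, np.array(times), route="iv_bolus")
        expected = 0.0
        for y, mu in zip(obs, preds):
            s2 = (0.15 * mu) ** 2 + 1.0
            expected += math.log(2 * math.pi * s2) + (y - mu) ** 2 / s2
        ds = make_dataset(iv_rows(1, 1.0, times, obs))
        assert neg2ll(model, p, err, ds) == pytest.approx(expected, rel=1e-9)

    def test_deterministic(self):
        model = build_model(StructuralModelSpec(1, "iv_bolus"))
        p = PKParameters(CL=0.5, V1=5.0)
        ds = make_dataset(iv_rows(1, 1.0, [1.0, 2.0], [150.0, 130.0]))
        a = neg2ll(model, p, ErrorModel(0.1, 0.5), ds)
        b = neg2ll(model, p, ErrorModel(0.1, 0.5), ds)
        assert a == b

    def test_pure_proportional_error_with_zero_prediction_raises(self):
        model = build_model(StructuralModelSpec(1, "first_order"))
        p = PKParameters(CL=0.5, V1=5.0, ka1=1.0, F=0.8)
        rows = [dict(ID=1, TIME=0.0, AMT=1.0, DV=np.nan, EVID=1, STRAIN="WT",
                     BWT=30.0, DOSEGRP=1.0, ROUTE="oral_solution", BLQ=0),
                dict(ID=1, TIME=0.0, AMT=np.nan, DV=0.0, EVID=0,
                     STRAIN="WT", BWT=30.0, DOSEGRP=1.0,
                     ROUTE="oral_solution", BLQ=1)]
        ds = make_dataset(rows)
        with pytest.raises(ValidationError, match="additive"):
            neg2ll(model, p, ErrorModel(0.15, 0.0), ds)


class TestFitPooled:
    def _noise_free_study(self, seed=3):
        model = build_model(StructuralModelSpec(1, "iv_bolus"))
        truth = PKParameters(CL=0.5, V1=5.0)
        design = StudyDesign(
            arms=(DoseArm(1.0, "iv_bolus", {"WT": 5}),),
            sampling_times=(0.25, 0.5, 1, 2, 4, 8),
            error=ErrorModel(0.0, 0.0), bsv=BSVModel({}), lloq=0.0,
        )
        return model, truth, generate_mouse_study(model, truth, (), design, seed)

    def test_self_consistency_on_noise_free_data(self):
        # constant (additive) error: the pooled-ML optimum is exactly the
        # generating truth and the OFV sits at the error-model floor
        model, truth, ds = self._noise_free_study()
        fit = fit_pooled(model, ds, truth, estimate_error=False,
                         error_init=ErrorModel(0.0, 1.0), n_starts=1)
        assert fit.converged
        assert fit.estimates.CL == pytest.approx(0.5, rel=1e-4)
        assert fit.estimates.V1 == pytest.approx(5.0, rel=1e-4)
        floor = neg2ll(model, truth, ErrorModel(0.0, 1.0), ds)
        assert fit.ofv == pytest.approx(floor, abs=1e-6)

    def test_clearance_recovery_iv_study(self):
        model = build_model(StructuralModelSpec(1, "iv_bolus"))
        truth = PKParameters(CL=0.5, V1=5.0)
        design = StudyDesign(
            arms=(DoseArm(1.0, "iv_bolus", {"WT": 20}),),
            sampling_times=(0.25, 0.5, 1, 2, 4, 8),
            error=ErrorModel(0.15, 0.5), bsv=BSVModel({}),
        )
        ds = generate_mouse_study(model, truth, (), design, seed=11)
        fit = fit_pooled(model, ds, truth.replace(CL=0.8, V1=3.0), n_starts=3,
                         seed=11)
        assert fit.estimates.CL == pytest.approx(0.5, rel=0.10)

    def test_init_outside_bounds_rejected(self):
        model, truth, ds = self._noise_free_study()
        with pytest.raises(ValidationError, match="bounds"):
            fit_pooled(model, ds, truth, bounds={"CL": (1.0, 10.0)})

    def test_missing_init_parameter_rejected(self):
        model, truth, ds = self._noise_free_study()
        with pytest.raises(ValidationError, match="V1"):
            fit_pooled(model, ds, PKParameters(CL=0.5), free=("CL", "V1"))

    def test_nesting_never_increases_ofv(self):
        model = build_model(StructuralModelSpec(1, "first_order"))
        truth = PKParameters(CL=0.045, V1=0.12, ka1=1.0, F=0.7)
        design = StudyDesign(
            arms=(DoseArm(0.3, "oral_solution", {"WT": 8, "Cyp3aXAV": 8}),),
            sampling_times=(0.25, 0.5, 1, 2, 4, 8),
            error=ErrorModel(0.15, 0.5), bsv=BSVModel({}),
        )
        for seed in (1, 2, 3):
            ds = generate_mouse_study(model, truth, (), design, seed)
            base = fit_pooled(model, ds, truth, free=("CL", "V1", "ka1"),
                              n_starts=1, seed=seed)
            ext = fit_pooled(
                model, ds, base.estimates, free=("CL", "V1", "ka1"),
                effects_init=(CovariateEffect("CL", "Cyp3aXAV", 1.0),),
                n_starts=1, seed=seed,
            )
            assert ext.ofv <= base.ofv + 1e-9


def _fit_result(ofv):
    return FitResult(
        estimates=PKParameters(CL=1.0, V1=5.0), fold_changes={},
        error=ErrorModel(0.1, 0.5), ofv=ofv, rse={}, converged=True,
        n_obs=10, n_subjects=2, n_params=3,
    )


class TestLRT:
    @pytest.mark.parametrize(
        "dofv,df,expected",
        [
            (-6.7, 1, True),    # just below the -6.64 cutoff
            (-6.0, 1, False),   # not far enough below
            (-45.0, 3, True),   # large drop over three extra parameters
        ],
    )
    def test_significance_rule(self, dofv, df, expected):
        dec = lrt_covariate(_fit_result(100.0), _fit_result(100.0 + dofv), df=df)
        assert dec.significant is expected
        assert dec.dOFV == pytest.approx(dofv)

    def test_threshold_is_chi2_quantile(self):
        dec = lrt_covariate(_fit_result(10.0), _fit_result(9.0), df=1, alpha=0.01)
        assert dec.threshold == pytest.approx(-6.6349, abs=1e-3)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValidationError):
            lrt_covariate(_fit_result(10.0), _fit_result(9.0), df=0)
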