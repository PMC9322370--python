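"""Virtual human populations and population simulation."""

import numpy as np
import pytest
from scipy.stats import truncnorm

from xspeciespk import (
    BSVModel,
    ErrorModel,
    HumanPopulationSpec,
    ScalingPolicy,
    SubjectCovariates,
    ValidationError,
    build_model,
    generate_virtual_population,
    get_preset,
    percentile_bands,
    simulate_population,
)
from xspeciespk.human import SimulationResult, default_grid


class TestVirtualPopulation:
    def test_floor_respected(self):
        pop = generate_virtual_population(HumanPopulationSpec(n_individuals=5000, seed=3))
        weights = np.array([s.bodyweight for s in pop]) / 1000.0
        assert weights.min() >= 50.0

    def test_seed_reproducibility(self):
        a = generate_virtual_population(HumanPopulationSpec(seed=9))
        b = generate_virtual_population(HumanPopulationSpec(seed=9))
        assert [s.bodyweight for s in a] == [s.bodyweight for s in b]

    def test_mean_matches_truncated_normal(self):
        pop = generate_virtual_population(
            HumanPopulationSpec(n_individuals=100_000, seed=1)
        )
        w = np.array([s.bodyweight for s in pop]) / 1000.0
        expected = truncnorm.mean((50 - 70) / 17, np.inf, loc=70, scale=17)
        assert w.mean() == pytest.approx(expected, rel=0.005)

    def test_subjects_are_human(self):
        pop = generate_virtual_population(HumanPopulationSpec(n_individuals=3, seed=0))
        assert all(s.species == "human" and s.strain == "human" for s in pop)


def _human_pop(weights_kg):
    return [
        SubjectCovariates(f"H{i}", "human", w * 1000.0, species="human")
        for i, w in enumerate(weights_kg)
    ]


class TestSimulatePopulation:
    def setup_method(self):
        self.preset = get_preset("brigatinib")
        self.model = build_model(self.preset.optimized_spec)
        self.params = self.preset.mouse_params_optimized
        self.grid = default_grid(48.0, 0.5)

    def test_identical_weights_give_identical_rows(self):
        result = simulate_population(
            self.model, self.params, _human_pop([70, 70, 70]), 180.0, self.grid,
            scaling_policy=ScalingPolicy(),
        )
        assert np.allclose(result.concentrations[0], result.concentrations[1])
        assert np.allclose(result.concentrations[0], result.concentrations[2])

    def test_heavier_individual_has_lower_cmax(self):
        result = simulate_population(
            self.model, self.params, _human_pop([55, 95]), 180.0, self.grid,
            scaling_policy=ScalingPolicy(),
        )
        cmaxes = result.concentrations.max(axis=1)
        assert cmaxes[0] > cmaxes[1]

    def test_standard_dose_run_nonnegative(self):
        preset = get_preset("lorlatinib")
        model = build_model(preset.optimized_spec)
        result = simulate_population(
            model, preset.mouse_params_optimized, _human_pop([60, 70, 85]),
            100.0, default_grid(120.0, 0.5), scaling_policy=ScalingPolicy(),
        )
        assert np.all(result.concentrations >= 0)
        assert result.concentrations.max() > 0

    def test_extrapolated_path_forbids_bsv_and_error(self):
        with pytest.raises(ValidationError, match="never extrapolated"):
            simulate_population(
                self.model, self.params, _human_pop([70]), 180.0, self.grid,
                scaling_policy=ScalingPolicy(), bsv=BSVModel({"CL": 0.1}),
            )
        with pytest.raises(ValidationError, match="never extrapolated"):
            simulate_population(
                self.model, self.params, _human_pop([70]), 180.0, self.grid,
                scaling_policy=ScalingPolicy(), error=ErrorModel(0.1, 0.0),
            )

    def test_reference_path_supports_replicates_with_bsv(self):
        human_params = self.params.replace(CL=10.0, V1=80.0, V2=120.0, Q=15.0)
        result = simulate_population(
            self.model, human_params, _human_pop([70, 80]), 180.0, self.grid,
            scaling_policy=None, bsv=BSVModel({"CL": 0.09}),
            error=ErrorModel(0.1, 0.5), n_replicates=5, seed=4,
        )
        assert result.n_rows == 10
        # BSV makes replicates differ
        assert not np.allclose(result.concentrations[0], result.concentrations[2])

    def test_mouse_covariates_rejected(self):
        mouse = [SubjectCovariates("m1", "WT", 30.0)]
        with pytest.raises(ValidationError, match="human"):
            simulate_population(
                self.model, self.params, mouse, 180.0, self.grid,
                scaling_policy=ScalingPolicy(),
            )


class TestPercentileBands:
    def _result(self, matrix):
        m = np.asarray(matrix, dtype=float)
        return SimulationResult(
            np.arange(m.shape[1], dtype=float) + 1.0, m,
            np.arange(m.shape[0]), np.zeros(m.shape[0], dtype=int),
        )

    def test_constant_matrix_collapses(self):
        lo, med, hi = percentile_bands(self._result(np.full((7, 4), 3.0)))
        assert np.all(lo == 3.0) and np.all(med == 3.0) and np.all(hi == 3.0)

    def test_linear_interpolation_convention(self):
        m = np.arange(1.0, 11.0).reshape(10, 1)
        lo, med, hi = percentile_bands(self._result(m), level=80.0)
        assert lo[0] == pytest.approx(1.9)
        assert hi[0] == pytest.approx(9.1)
        assert med[0] == pytest.approx(5.5)

    def test_level_zero_is_median(self):
        m = np.arange(1.0, 11.0).reshape(10, 1)
        lo, med, hi = percentile_bands(self._result(m), level=0.0)
        assert lo[0] == med[0] == hi[0]

    def test_single_row_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            lo, med, hi = percentile_bands(self._result([[1.0, 2.0]]))
        assert np.array_equal(lo, [1.0, 2.0])
        assert np.array_equal(hi, [1.0, 2.0])
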