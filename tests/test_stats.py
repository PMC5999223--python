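"""Gated group tests, correlations, model grid, single fits and k-fold CV."""

import numpy as np
import pandas as pd
import pytest

from thymentropy import (
    CohortConfig,
    ModelError,
    entropy_sample_size_check,
    fit_model_grid,
    fit_single_predictor,
    gated_two_group_test,
    kfold_cv,
    pearson_with_p,
    simulate_cohort,
)
from thymentropy.stats import DEFAULT_ENDPOINTS, LOGISTIC_ENDPOINTS


class TestGatedTwoGroupTest:
    def test_normal_samples_use_t_and_control_type_i(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 1, 200)])
        g = np.repeat(["a", "b"], 200)
        res = gated_two_group_test(x, g)
        assert res.test_used == "t"
        assert res.p_value > 0.05

    def test_heavy_tailed_samples_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.standard_cauchy(150), rng.standard_cauchy(150)])
        g = np.repeat([0, 1], 150)
        res = gated_two_group_test(x, g)
        assert res.test_used == "wilcoxon"
        assert min(res.shapiro_p) <= 0.05

    def test_constant_group_forces_wilcoxon(self):
        x = [1.0, 1.0, 1.0, 2.0, 3.0, 4.0]
        g = ["a"] * 3 + ["b"] * 3
        res = gated_two_group_test(x, g)
        assert res.test_used == "wilcoxon" and res.forced
        assert np.isnan(res.shapiro_p[0])

    def test_requires_two_groups_of_three(self):
        with pytest.raises(ModelError):
            gated_two_group_test([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(ModelError):
            gated_two_group_test([1, 2, 3, 4], ["a", "a", "a", "b"])


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(8)
        res = pearson_with_p(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(res.r) < 0.1
        assert res.n == 1000

    def test_constant_input_is_error(self):
        with pytest.raises(ModelError, match="constant"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def planted_fit():
    cohort = simulate_cohort(CohortConfig(seed=21, n_cases=200), tables=False)
    return fit_model_grid(cohort.manifest.to_frame(), cohort.clinical)


class TestModelGrid:
    def test_family_assignment_matches_endpoint_scale(self, planted_fit):
        for ep in DEFAULT_ENDPOINTS:
            expected = "logistic" if ep in LOGISTIC_ENDPOINTS else "linear"
            assert planted_fit.families[ep] == expected

    def test_all_p_values_in_unit_interval(self, planted_fit):
        p = planted_fit.p_values.to_numpy(dtype=float)
        finite = p[~np.isnan(p)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_planted_fat_effect_cell_significant(self, planted_fit):
        assert (
            planted_fit.p_values.loc["prednisone_post_g", "H_pointsum_grading_intrathymic_fat"]
            < 0.05
        )

    def test_zero_variance_endpoint_is_error(self):
        cohort = simulate_cohort(CohortConfig(seed=22, n_cases=30), tables=False)
        clinical = cohort.clinical.copy()
        clinical["qmg_baseline"] = 10.0
        with pytest.raises(ModelError, match="qmg_baseline"):
            fit_model_grid(cohort.manifest.to_frame(), clinical)

    def test_grid_csv_marks_significance(self, planted_fit, tmp_path):
        path = tmp_path / "grid.csv"
        planted_fit.to_csv(path)
        text = path.read_text()
        assert "*" in text and "family" in text


class TestSinglePredictor:
    def test_exact_line_recovered(self):
        x = np.arange(20.0)
        fit = fit_single_predictor(3 * x, x)
        assert fit.slope == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_planted_slope_within_three_se(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=200)
        y = 5.0 * x + rng.normal(0, 1, 200)
        fit = fit_single_predictor(y, x)
        assert abs(fit.slope - 5.0) < 3 * fit.se

    def test_independent_data_r2_near_zero(self):
        rng = np.random.default_rng(32)
        fit = fit_single_predictor(rng.normal(size=500), rng.normal(size=500))
        assert fit.r_squared < 0.02

    def test_constant_predictor_is_error(self):
        with pytest.raises(ModelError):
            fit_single_predictor([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])


class TestKFoldCV:
    def test_noiseless_linear_data_zero_mse(self):
        x = np.linspace(0, 1, 30)
        report = kfold_cv(2 * x + 1, x, k=3, seed=0)
        assert report.mean_mse == pytest.approx(0.0, abs=1e-20)

    def test_fold_sizes_near_equal(self):
        report = kfold_cv(np.arange(10.0), np.arange(10.0) * 0.5, k=3, seed=1)
        assert sorted(report.fold_sizes) == [3, 3, 4]

    def test_mse_calibrated_to_noise_variance(self):
        rng = np.random.default_rng(40)
        x = rng.normal(size=300)
        y = 1.0 + 2.0 * x + rng.normal(0, 2.0, size=300)
        report = kfold_cv(y, x, k=3, seed=0)
        assert report.mean_mse == pytest.approx(4.0, rel=0.25)
        assert report.full_data_mse == pytest.approx(4.0, rel=0.25)

    def test_same_seed_identical_report(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=60)
        y = x + rng.normal(0, 1, 60)
        a = kfold_cv(y, x, k=3, seed=9)
        b = kfold_cv(y, x, k=3, seed=9)
        assert a == b
        assert a.to_json() == b.to_json()

    def test_fold_too_small_for_predictors_is_error(self):
        with pytest.raises(ModelError):
            kfold_cv(np.arange(8.0), np.ones((8, 5)) * np.arange(8)[:, None], k=4, seed=0)


class TestSampleSizeCheck:
    def test_constant_m_is_error(self):
        frame = pd.DataFrame(
            {"H_shannon_n_follicle_cd23": [0.1, 0.5, 0.9], "m_n_follicle_cd23": [6, 6, 6]}
        )
        with pytest.raises(ModelError, match="constant"):
            entropy_sample_size_check(frame)

    def test_independent_heterogeneity_gives_small_r(self):
        cohort = simulate_cohort(CohortConfig(seed=50, n_cases=200), tables=False)
        res = entropy_sample_size_check(cohort.manifest.to_frame())
        assert abs(res.r) < 0.3

    def test_m_coupled_heterogeneity_gives_positive_r(self):
        # plant heterogeneity that grows with the number of slides
        rng = np.random.default_rng(51)
        m = np.maximum(3, np.rint(rng.normal(11, 5, 200)).astype(int))
        from thymentropy import entropy_shannon

        h = []
        for mi in m:
            alpha = 0.02 * mi  # concentration grows with m
            levels = rng.choice(10, size=mi, p=rng.dirichlet(np.full(10, alpha)))
            h.append(entropy_shannon(levels))
        frame = pd.DataFrame({"H_shannon_n_follicle_cd23": h, "m_n_follicle_cd23": m})
        res = entropy_sample_size_check(frame)
        assert res.r > 0.3 and res.p_value < 0.05
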