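"""Random-intercept mixed models: boundaries, closed forms, recovery, selection."""

import numpy as np
import pandas as pd
import pytest

from oracles import balanced_lmm_closed_form
from rejumet.dose_response import (RandomInterceptLMM, fit_class_dose_models,
                                   fit_mouse_class_model, fit_random_intercept_lmm,
                                   polynomial_dose_design, select_polynomial_order)
from rejumet.preprocess import class_sums
from rejumet.simulate import (HumanDesignConfig, MouseDesignConfig,
                              generate_human_study, generate_mouse_study)


def _simulate_lmm(n_subj, n_per, beta, sigma_b, sigma_e, seed, doses=(0, 25, 50, 100)):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subj), n_per)
    dose = np.tile(np.asarray(doses[:n_per], dtype=float), n_subj)
    X = polynomial_dose_design(dose, len(beta) - 1)
    y = X.to_numpy() @ np.asarray(beta) + rng.normal(0, sigma_b, n_subj)[subj] \
        + rng.normal(0, sigma_e, n_subj * n_per)
    return X, y, subj, dose


class TestRandomInterceptLMM:
    def test_one_obs_per_subject_reduces_to_ols(self):
        """Flat profile in λ: boundary λ=0 chosen, fixed effects equal OLS."""
        rng = np.random.default_rng(0)
        n = 40
        dose = rng.choice([0.0, 25.0, 50.0, 100.0], n)
        X = polynomial_dose_design(dose, 2)
        y = 1 + 0.01 * dose + rng.normal(0, 1, n)
        fit = RandomInterceptLMM().fit(X, y, np.arange(n))
        assert fit.lambda_ == 0.0
        assert fit.sigma2_subject_ == 0.0
        ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef_, ols, rtol=1e-10)

    def test_balanced_two_obs_matches_closed_form(self):
        """ML estimates agree with the textbook balanced solution within 1e-6."""
        rng = np.random.default_rng(1)
        a, m = 25, 2
        subj = np.repeat(np.arange(a), m)
        y = 2.0 + rng.normal(0, 0.9, a)[subj] + rng.normal(0, 0.4, a * m)
        X = pd.DataFrame({"Intercept": np.ones(a * m)})
        fit = RandomInterceptLMM().fit(X, y, subj)
        mu, sb, se = balanced_lmm_closed_form(y, a, m)
        assert fit.coef_[0] == pytest.approx(mu, abs=1e-6)
        assert fit.sigma2_subject_ == pytest.approx(sb, abs=1e-6)
        assert fit.sigma2_resid_ == pytest.approx(se, abs=1e-6)

    def test_parameter_recovery_within_3se(self):
        """True (β, σ²_b, σ²_e) recovered at n=200 subjects."""
        beta = np.array([1.0, 0.02, -0.0003])
        X, y, subj, dose = _simulate_lmm(200, 4, beta, 0.5, 0.3, seed=2)
        fit = RandomInterceptLMM().fit(X, y, subj)
        for est, se, true in zip(fit.coef_, fit.se_, beta):
            assert abs(est - true) < 3 * se
        assert fit.sigma2_subject_ == pytest.approx(0.25, rel=0.3)
        assert fit.sigma2_resid_ == pytest.approx(0.09, rel=0.3)

    def test_matches_statsmodels_ml(self):
        import statsmodels.api as sm

        X, y, subj, _ = _simulate_lmm(30, 4, [1.0, 0.01, -0.0001], 0.6, 0.4, seed=3)
        fit = RandomInterceptLMM().fit(X, y, subj)
        ref = sm.MixedLM(y, X.to_numpy(), groups=subj).fit(reml=False)
        np.testing.assert_allclose(fit.coef_, ref.fe_params, rtol=1e-5)
        assert fit.deviance_ == pytest.approx(-2 * ref.llf, abs=1e-5)

    def test_optimum_never_below_ols_loglik(self):
        """Profiled ML log-likelihood at the optimum ≥ value at λ = 0."""
        for seed in range(5):
            X, y, subj, _ = _simulate_lmm(20, 3, [0.5, 0.01, 0.0], 0.7, 0.5,
                                          seed=seed, doses=(0, 50, 100))
            model = RandomInterceptLMM()
            fit = model.fit(X, y, subj)
            model._X = X.to_numpy()
            model._y = np.asarray(y)
            uniq, codes = np.unique(subj, return_inverse=True)
            model._group_n = np.bincount(codes).astype(float)
            model._sx, model._sy = model._group_sums(model._X, model._y,
                                                     codes, len(uniq))
            dev0 = model._profile(0.0)[0]
            assert fit.deviance_ <= dev0 + 1e-8

    def test_constant_outcome_handled(self):
        X = polynomial_dose_design(np.tile([0.0, 50.0], 10), 1)
        y = np.full(20, 3.0)
        fit = RandomInterceptLMM().fit(X, y, np.repeat(np.arange(10), 2))
        assert fit.coef_[1] == pytest.approx(0.0, abs=1e-10)

    def test_single_subject_rejected(self):
        X = pd.DataFrame({"Intercept": np.ones(4)})
        with pytest.raises(ValueError, match="subjects"):
            RandomInterceptLMM().fit(X, np.arange(4.0), np.zeros(4))


class TestPolynomialSelection:
    def test_excess_order_excluded(self):
        X, y, subj, dose = _simulate_lmm(30, 3, [1.0, 0.01], 0.4, 0.3, seed=4,
                                         doses=(0, 50, 100))
        order, fits = select_polynomial_order(y, dose, subj, orders=(1, 2, 3))
        assert 3 not in fits  # only 3 distinct doses

    def test_deviance_monotone_in_order(self):
        X, y, subj, dose = _simulate_lmm(50, 4, [1.0, 0.02, -0.0003], 0.4, 0.3,
                                         seed=5)
        _, fits = select_polynomial_order(y, dose, subj, orders=(1, 2, 3))
        devs = [fits[o].deviance for o in sorted(fits)]
        assert all(a >= b - 1e-8 for a, b in zip(devs, devs[1:]))

    def test_quadratic_truth_selects_order_two(self):
        """U-shaped truth: order 2 wins by information criterion in most reps."""
        wins = 0
        for seed in range(20):
            _, y, subj, dose = _simulate_lmm(
                100, 4, [0.0, -0.016, 0.00016], 0.1, 0.1, seed=100 + seed)
            order, _ = select_polynomial_order(y, dose, subj, orders=(1, 2, 3))
            wins += order == 2
        assert wins >= 16

    def test_linear_truth_near_flat_deviance_beyond_order_one(self):
        _, y, subj, dose = _simulate_lmm(300, 4, [1.0, 0.01], 0.3, 0.3, seed=6)
        _, fits = select_polynomial_order(y, dose, subj, orders=(1, 2, 3))
        drop_12 = fits[1].deviance - fits[2].deviance
        assert drop_12 < 10  # no meaningful gain from the quadratic term

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            select_polynomial_order([1.0, 2.0], [0, 25], ["a", "b"],
                                    criterion="wrong")


class TestClassDoseModels:
    def test_injected_quadratic_effect_recovered(self):
        """PC class falls most at 50 mg: negative-then-rising quadratic term."""
        config = HumanDesignConfig(n_placebo=10, n_treated=40, seed=31)
        matrix, ann, meta, _ = generate_human_study(config)
        sums = class_sums(matrix, ann)
        table, fits = fit_class_dose_models(sums, meta, covariate="bmi")
        pc_quad = table[(table["class"] == "PC") & (table["term"] == "dose^2")]
        pc_lin = table[(table["class"] == "PC") & (table["term"] == "dose")]
        # reversal pushes positive-beta features down: negative linear, positive quadratic
        assert pc_lin["estimate"].iloc[0] < 0
        assert pc_quad["estimate"].iloc[0] > 0

    def test_permuted_dose_nonsignificant(self):
        config = HumanDesignConfig(n_placebo=8, n_treated=8,
                                   dose_response_shape=(0.0, 0.0), seed=32)
        matrix, ann, meta, _ = generate_human_study(config)
        sums = class_sums(matrix, ann)
        table, _ = fit_class_dose_models(sums, meta, covariate="bmi")
        dose_terms = table[table["term"].str.startswith("dose")]
        assert (dose_terms["q"] < 0.05).mean() < 0.3  # null: mostly non-significant

    def test_bh_applied_across_family(self):
        config = HumanDesignConfig(n_placebo=5, n_treated=5, seed=33)
        matrix, ann, meta, _ = generate_human_study(config)
        table, _ = fit_class_dose_models(class_sums(matrix, ann), meta,
                                         covariate="bmi")
        dose_terms = table[table["term"].str.startswith("dose")]
        assert dose_terms["q"].notna().all()
        assert table.loc[table["term"] == "Intercept", "q"].isna().all()


class TestMouseClassModel:
    def test_aging_effect_isolated_to_affected_class(self):
        """Aging injected only on AC features shows up in the AC age term."""
        config = MouseDesignConfig(n_features=60, seed=41, frac_age_affected=1.0,
                                   reversal_fraction=0.0, lod_censor_rate=0.0)
        matrix, ann, meta, truth = generate_mouse_study(config)
        # rebuild values with aging restricted to the AC class
        is_ac = (ann == "AC").to_numpy()
        log2 = np.log2(matrix.data.to_numpy())
        old = (meta["age_group"] == "old").to_numpy()
        log2[np.ix_(old, ~is_ac)] -= truth.aging_effect_per_feature[~is_ac]
        matrix.data.iloc[:, :] = np.exp2(log2)
        table, _ = fit_mouse_class_model(class_sums(matrix, ann), meta)
        age = table[table["term"] == "Age[old]"].set_index("class")["estimate"]
        assert age["AC"] < -0.2
        assert np.all(np.abs(age.drop("AC")) < np.abs(age["AC"]) / 2)

    def test_no_treatment_arm_drops_columns(self):
        config = MouseDesignConfig(n_old_wt_los=0, n_old_at1ko_los=0,
                                   n_old_at2ko_los=0, seed=42)
        matrix, ann, meta, _ = generate_mouse_study(config)
        table, _ = fit_mouse_class_model(class_sums(matrix, ann), meta)
        assert not table["term"].str.startswith("Treatment").any()

    def test_duplicated_visits_leave_fixed_effects_unchanged(self):
        """The random intercept absorbs an exact duplicate of every mouse."""
        config = MouseDesignConfig(n_features=40, seed=43, lod_censor_rate=0.0)
        matrix, ann, meta, _ = generate_mouse_study(config)
        sums = class_sums(matrix, ann)
        table_single, _ = fit_mouse_class_model(sums, meta)
        dup_sums = pd.concat([sums, sums.set_index(sums.index + "_rep")])
        dup_meta = pd.concat([
            meta, meta.assign(sample_id=meta["sample_id"] + "_rep")],
            ignore_index=True)
        table_dup, _ = fit_mouse_class_model(dup_sums, dup_meta)
        merged = table_single.merge(table_dup, on=["class", "term"],
                                    suffixes=("_1", "_2"))
        # λ is driven toward its upper bound for exact duplicates, so the
        # equality is exact only in the λ→∞ limit
        np.testing.assert_allclose(merged["estimate_1"], merged["estimate_2"],
                                   rtol=1e-4, atol=1e-4)
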