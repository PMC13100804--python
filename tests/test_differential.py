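"""Differential-abundance engine: designs, OLS, moderation, BH, Fisher."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import bh_oracle, chi2_4_tail, chi2_4_tail_quad, ebayes_oracle
from rejumet.differential import (ModeratedLinearModel, bh_adjust, build_design,
                                  ebayes_moderate, estimate_variance_prior,
                                  fisher_combine)


def _toy_meta(groups, **extra):
    n = len(groups)
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                         "subject_id": [f"s{i}" for i in range(n)],
                         "species": ["mouse"] * n, "grp": groups})
    for k, v in extra.items():
        meta[k] = v
    return meta


class TestBuildDesign:
    def test_two_group_contrast_estimates_mean_difference(self, two_group_design):
        meta, design = two_group_design
        assert design.column_names == ["Intercept", "grp[b]"]
        y = pd.DataFrame({"f": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]},
                         index=meta["sample_id"])
        model = ModeratedLinearModel(moderated=False).fit(design, y)
        eff = model.contrast_effects("b")
        assert eff.estimate["f"] == pytest.approx(2.0)

    def test_orthogonal_covariate_leaves_contrast_unchanged(self):
        rng = np.random.default_rng(0)
        groups = ["a"] * 10 + ["b"] * 10
        cov = np.tile([-1.0, 1.0], 10)  # orthogonal to the group indicator
        meta = _toy_meta(groups, cov=cov)
        y = pd.DataFrame({"f": rng.normal(0, 1, 20) + np.repeat([0, 1.5], 10)},
                         index=meta["sample_id"])
        d_plain = build_design(meta, group="grp")
        d_cov = build_design(meta, group="grp", covariates=["cov"])
        est_plain = (ModeratedLinearModel(moderated=False).fit(d_plain, y)
                     .contrast_effects("b").estimate["f"])
        est_cov = (ModeratedLinearModel(moderated=False).fit(d_cov, y)
                   .contrast_effects("b").estimate["f"])
        assert est_cov == pytest.approx(est_plain)

    def test_rank_deficiency_names_columns(self):
        meta = _toy_meta(["a", "a", "b", "b"], c1=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="c1"):
            build_design(meta, group="grp", covariates=["c1"])

    def test_subject_block_columns(self):
        meta = _toy_meta(["a", "b", "a", "b"])
        meta["subject_id"] = ["p1", "p1", "p2", "p2"]
        design = build_design(meta, group="grp", block="subject_id")
        assert "subject_id[p2]" in design.column_names


class TestFeatureModels:
    def test_noiseless_recovery(self, two_group_design):
        meta, design = two_group_design
        X = design.frame.to_numpy()
        beta = np.array([[1.0, 2.0], [0.5, -1.0]])  # two features
        Y = pd.DataFrame(X @ beta.T, index=meta["sample_id"], columns=["f1", "f2"])
        model = ModeratedLinearModel(moderated=False).fit(design, Y)
        np.testing.assert_allclose(model.coef_, beta, atol=1e-12)
        np.testing.assert_allclose(model.sigma2_, 0, atol=1e-20)

    def test_two_group_toy_hand_ols(self, two_group_design):
        """{1,2,3} vs {3,4,5}: difference 2, s² = 1, residual df 4."""
        meta, design = two_group_design
        Y = pd.DataFrame({"f": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]},
                         index=meta["sample_id"])
        model = ModeratedLinearModel(moderated=False).fit(design, Y)
        eff = model.contrast_effects("b")
        assert eff.estimate["f"] == pytest.approx(2.0)
        assert model.sigma2_[0] == pytest.approx(1.0)
        assert model.df_residual_[0] == 4

    def test_feature_with_too_few_observations_skipped(self):
        meta = _toy_meta(["a"] * 3 + ["b"] * 3, cov=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        design = build_design(meta, group="grp", covariates=["cov"])
        y = np.random.default_rng(1).normal(0, 1, (6, 2))
        Y = pd.DataFrame(y, index=meta["sample_id"], columns=["ok", "sparse"])
        Y.loc[Y.index[:4], "sparse"] = np.nan  # 2 obs < 3 design columns
        model = ModeratedLinearModel(moderated=False).fit(design, Y)
        assert model.skipped_ == ["sparse"]

    def test_all_skipped_is_error(self, two_group_design):
        meta, design = two_group_design
        Y = pd.DataFrame({"f": [np.nan] * 6}, index=meta["sample_id"])
        with pytest.raises(ValueError, match="skipped"):
            ModeratedLinearModel(moderated=False).fit(design, Y)


class TestEmpiricalBayes:
    @pytest.fixture()
    def simulated(self):
        """50 features, 12 samples, heterogeneous true variances."""
        rng = np.random.default_rng(42)
        n, G, d0_true, s0_true = 12, 50, 4.0, 0.05
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        groups = ["a"] * 6 + ["b"] * 6
        meta = _toy_meta(groups)
        effects = rng.normal(0, 0.4, G)
        Y = rng.normal(0, 1, (n, G)) * np.sqrt(sigma2)
        Y[6:] += effects
        Ydf = pd.DataFrame(Y, index=meta["sample_id"],
                           columns=[f"g{j}" for j in range(G)])
        design = build_design(meta, group="grp")
        return meta, design, Ydf

    def test_matches_direct_formula_oracle(self, simulated):
        """(d0, s0², moderated t, p) agree with the brentq-based oracle to 1e-10."""
        meta, design, Ydf = simulated
        model = ModeratedLinearModel().fit(design, Ydf)
        eff = model.contrast_effects("b")
        c = design.contrast("b")
        su = np.sqrt(np.einsum("i,nij,j->n", c, model.cov_unscaled_, c))
        d0, s0, t, p = ebayes_oracle(model.sigma2_, model.df_residual_,
                                     model.coef_ @ c, su)
        assert model.prior_df_ == pytest.approx(d0, rel=1e-10)
        assert model.prior_var_ == pytest.approx(s0, rel=1e-10)
        np.testing.assert_allclose(eff.table["t"], t, rtol=1e-10)
        np.testing.assert_allclose(eff.table["p"], p, rtol=1e-10)

    def test_matches_reference_r_implementation(self, simulated, tmp_path):
        """Cross-check d0, s0² and moderated t against limma via Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        meta, design, Ydf = simulated
        model = ModeratedLinearModel().fit(design, Ydf)
        eff = model.contrast_effects("b")
        Ydf.T.to_csv(tmp_path / "y.csv")
        script = tmp_path / "check.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            y <- as.matrix(read.csv(commandArgs(TRUE)[1], row.names=1))
            design <- cbind(Intercept=1, b=rep(c(0,1), each=6))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
            out$d0 <- fit$df.prior; out$s0 <- fit$s2.prior
            write.csv(out, commandArgs(TRUE)[2])
        """))
        res = subprocess.run(
            ["Rscript", str(script), str(tmp_path / "y.csv"), str(tmp_path / "r.csv")],
            capture_output=True, text=True, timeout=120)
        if res.returncode != 0:
            pytest.skip(f"limma unavailable: {res.stderr[-200:]}")
        r = pd.read_csv(tmp_path / "r.csv", index_col=0)
        assert model.prior_df_ == pytest.approx(r["d0"].iloc[0], rel=1e-8)
        assert model.prior_var_ == pytest.approx(r["s0"].iloc[0], rel=1e-8)
        np.testing.assert_allclose(eff.table["t"], r["t"], rtol=1e-8)

    def test_infinite_prior_limit_equal_variances(self, two_group_design):
        """Zero spread in residual variances drives d0 → ∞, s̃² → s0²."""
        meta, design = two_group_design
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 6)
        # many features that are exact copies (identical s²)
        Y = pd.DataFrame({f"g{j}": base for j in range(20)},
                         index=meta["sample_id"])
        model = ModeratedLinearModel().fit(design, Y)
        assert np.isinf(model.prior_df_)
        np.testing.assert_allclose(model._moderated_variance(), model.prior_var_)

    def test_zero_prior_limit_is_ordinary_t(self, simulated):
        """With d0 forced to 0, the moderated t equals the ordinary t."""
        meta, design, Ydf = simulated
        model = ModeratedLinearModel().fit(design, Ydf)
        model.prior_df_ = 0.0
        eff_mod = model.contrast_effects("b")
        plain = ModeratedLinearModel(moderated=False).fit(design, Ydf)
        eff_plain = plain.contrast_effects("b")
        np.testing.assert_allclose(eff_mod.table["t"], eff_plain.table["t"])

    def test_type_i_rate_under_global_null(self):
        """Moderated p-values at α=0.05 stay within binomial 99% bounds."""
        rng = np.random.default_rng(77)
        n, G, d0_true, s0_true = 10, 10000, 4.0, 0.04
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        meta = _toy_meta(["a"] * 5 + ["b"] * 5)
        Y = pd.DataFrame(rng.normal(0, 1, (n, G)) * np.sqrt(sigma2),
                         index=meta["sample_id"],
                         columns=[f"g{j}" for j in range(G)])
        design = build_design(meta, group="grp")
        eff = ModeratedLinearModel().fit(design, Y).contrast_effects("b")
        rate = float(np.mean(eff.table["p"] < 0.05))
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / G)
        assert abs(rate - 0.05) < half_width

    def test_prior_estimation_needs_two_features(self):
        with pytest.raises(ValueError):
            estimate_variance_prior(np.array([1.0]), np.array([4.0]))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_matches_definitional_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            p = rng.uniform(1e-6, 1.0, rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20),
           st.integers(0, 19), st.floats(0.01, 0.99))
    def test_shrinking_one_p_never_loses_discoveries(self, p, idx, factor):
        """Monotonicity: lowering any p cannot reduce the discovery count."""
        p = list(p)
        idx = idx % len(p)
        q_before = bh_adjust(p)
        p[idx] *= factor
        q_after = bh_adjust(p)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            assert np.sum(q_after <= alpha) >= np.sum(q_before <= alpha)


class TestFisherCombine:
    def test_ones_combine_to_one(self):
        assert fisher_combine([1.0], [1.0])[0] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0.001, 1, 50), rng.uniform(0.001, 1, 50)
        np.testing.assert_allclose(fisher_combine(a, b), fisher_combine(b, a))

    def test_point_one_pair_matches_tail_oracles(self):
        """(0.1, 0.1): X² ≈ 9.2103, combined p from the χ²₄ upper tail."""
        x2 = -2 * (np.log(0.1) + np.log(0.1))
        assert x2 == pytest.approx(9.21034, abs=1e-5)
        combined = fisher_combine([0.1], [0.1])[0]
        assert combined == pytest.approx(chi2_4_tail(x2), abs=1e-12)
        assert combined == pytest.approx(chi2_4_tail_quad(x2), abs=1e-8)

    def test_partial_null_form(self):
        """(p, 1) combines to p·(1 − ln p), the χ²₄ tail at −2 ln p."""
        for p in (0.3, 0.05, 0.001):
            expected = p * (1 - np.log(p))
            assert fisher_combine([p], [1.0])[0] == pytest.approx(expected, rel=1e-10)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0], [0.5])
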