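"""Association models: OLS, FDR, ABE selection, bootstrap stability,
network t-tests."""

import numpy as np
import pandas as pd
import pytest

import netseg
from netseg import (
    CohortSpec,
    abe_select,
    bh_adjust,
    bootstrap_stability,
    fit_linear_model,
    network_contrast_ttest,
    prepare_predictor,
    residualize_on_fd,
    segregation_models,
    simulate_metrics_cohort,
    smd_between_model,
    standardize,
    within_between_models,
)
from netseg.models import _ols_quick

from _oracles import backward_aic_reference, bh_reference, ols_reference


class TestFitLinearModel:
    def test_matches_normal_equations_on_hand_example(self):
        # 5-point textbook example
        X = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5], "x2": [0.0, 1, 0, 1, 0]})
        y = np.array([2.0, 3.1, 3.9, 5.2, 6.1])
        fit = fit_linear_model(y, X)
        Xd = np.column_stack([np.ones(5), X.to_numpy()])
        beta, ssr, r2, aic = ols_reference(y, Xd)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert fit.rsquared == pytest.approx(r2, abs=1e-10)
        assert fit.aic == pytest.approx(aic, abs=1e-8)

    def test_matches_oracle_on_random_designs(self, rng):
        for _ in range(10):
            n, p = 30, 4
            X = pd.DataFrame(rng.standard_normal((n, p)), columns=list("abcd"))
            y = rng.standard_normal(n)
            fit = fit_linear_model(y, X)
            beta, ssr, r2, aic = ols_reference(y, np.column_stack([np.ones(n), X]))
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
            assert fit.aic == pytest.approx(aic, abs=1e-8)

    def test_noise_free_fit_is_exact(self):
        x = np.arange(10.0)
        fit = fit_linear_model(3 + 2 * x, pd.DataFrame({"x": x}))
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear_model(rng.standard_normal(20), X)

    def test_fast_ols_aic_matches_statsmodels(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        y = rng.standard_normal(n)
        _, _, aic, _ = _ols_quick(y, X)
        fit = fit_linear_model(y, pd.DataFrame(X[:, 1:], columns=list("xyz")))
        assert aic == pytest.approx(fit.aic, abs=1e-8)

    def test_permuting_response_breaks_planted_effect(self, rng):
        n = 200
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        pvals = []
        for _ in range(200):
            yp = rng.permutation(y)
            pvals.append(fit_linear_model(yp, pd.DataFrame({"x": x})).pvalues["x"])
        # under permutation the p-value is uniform
        assert np.mean(np.array(pvals) < 0.05) == pytest.approx(0.05, abs=0.05)
        assert 0.3 < np.mean(pvals) < 0.7


class TestResidualize:
    def test_orthogonal_to_fd(self, rng):
        y = rng.standard_normal(100)
        fd = rng.random(100)
        resid = residualize_on_fd(y, fd)
        assert abs(np.corrcoef(resid, fd)[0, 1]) < 1e-10

    def test_pure_fd_signal_vanishes(self, rng):
        fd = rng.random(50)
        assert np.allclose(residualize_on_fd(2 * fd, fd), 0.0, atol=1e-10)

    def test_generator_fd_confound_removed(self):
        spec = CohortSpec(n_subjects=2000, seed=4)
        subj, _ = simulate_metrics_cohort(spec)
        seg = subj["seg_DefaultMode"].to_numpy()
        fd = subj["mean_fd"].to_numpy()
        assert np.corrcoef(seg, fd)[0, 1] < -0.25  # confounded before
        resid = residualize_on_fd(seg, fd)
        assert abs(np.corrcoef(resid, fd)[0, 1]) < 0.01


class TestBH:
    def test_step_up_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_matches_reference_on_random_pvalues(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 15))
            assert np.allclose(bh_adjust(p), bh_reference(p), atol=1e-12)


class TestSegregationModels:
    def test_planted_network_detected_and_recovered(self):
        spec = CohortSpec(n_subjects=227, seed=21)
        subj, _ = simulate_metrics_cohort(spec)
        success_z = standardize(subj["success_true"].to_numpy())
        age_z = standardize(subj["age"].to_numpy())
        fd = subj["mean_fd"].to_numpy()
        seg = pd.DataFrame(
            {
                k: prepare_predictor(subj[f"seg_{k}"].to_numpy(), fd)
                for k in netseg.ANALYSIS_NETWORKS
            }
        )
        fits, summary = segregation_models(success_z, seg, age_z)
        assert summary.loc["DefaultMode", "significant"]
        assert summary.loc["DefaultMode", "beta_seg"] == pytest.approx(0.35, abs=0.15)
        # the planted quadratic age effect lands near its true value (its
        # per-replicate significance is not guaranteed at this effect size)
        assert fits["DefaultMode"].params["age_sq"] == pytest.approx(-0.17, abs=0.2)


class TestWithinBetweenModels:
    @staticmethod
    def _cohort(seed, **spec_kw):
        spec = CohortSpec(n_subjects=400, seed=seed, planted_beta_seg={}, **spec_kw)
        subj, _ = simulate_metrics_cohort(spec)
        z = standardize
        fd = subj["mean_fd"].to_numpy()
        return subj, z(subj["success_true"].to_numpy()), z(subj["age"].to_numpy()), fd

    def test_within_effect_recovered_between_null(self):
        subj, s_z, a_z, fd = self._cohort(31, planted_beta_within={"DefaultMode": 0.4})
        fit = within_between_models(
            s_z,
            prepare_predictor(subj["w_DefaultMode"].to_numpy(), fd),
            prepare_predictor(subj["b_DefaultMode"].to_numpy(), fd),
            a_z,
        )
        assert fit.pvalues["within"] < 0.01 and fit.params["within"] > 0
        assert fit.pvalues["between"] > 0.01
        # no planted age moderation: interactions stay null
        assert fit.pvalues["between_x_age"] > 0.01
        assert fit.pvalues["within_x_age"] > 0.01

    def test_smd_style_signs_recovered(self):
        subj, s_z, a_z, fd = self._cohort(
            32, planted_beta_within={"SomatomotorDorsal": -0.35}
        )
        fit = within_between_models(
            s_z,
            prepare_predictor(subj["w_SomatomotorDorsal"].to_numpy(), fd),
            prepare_predictor(subj["b_SomatomotorDorsal"].to_numpy(), fd),
            a_z,
        )
        assert fit.params["within"] < 0 and fit.pvalues["within"] < 0.05


class TestAbeSelect:
    def test_tau_inf_equals_plain_backward_reference(self, rng):
        for trial in range(10):
            n = 80
            cols = {"const": np.ones(n)}
            for name in "abcde":
                cols[name] = rng.standard_normal(n)
            y = 0.8 * cols["a"] + rng.standard_normal(n)
            res = abe_select(
                y, pd.DataFrame(cols), passive=("const",), tau=np.inf
            )
            ref_cols, ref_aic = backward_aic_reference(y, cols, ("const",))
            assert set(res.selected) == set(ref_cols)
            assert res.aic == pytest.approx(ref_aic, abs=1e-10)

    def test_noise_candidates_mostly_eliminated(self, rng):
        n = 500
        cols = {"const": np.ones(n)}
        for i in range(10):
            cols[f"x{i}"] = rng.standard_normal(n)
        y = rng.standard_normal(n)
        res = abe_select(y, pd.DataFrame(cols))
        assert len(res.selected) <= 5  # most noise dropped
        assert res.aic <= res.full_aic

    def test_strong_predictor_survives(self, rng):
        survived = 0
        for rep in range(20):
            n = 227
            cols = {"const": np.ones(n)}
            for i in range(13):
                cols[f"x{i}"] = rng.standard_normal(n)
            y = 0.5 * cols["x3"] + rng.standard_normal(n)
            res = abe_select(y, pd.DataFrame(cols))
            survived += "x3" in res.selected
        assert survived >= 19

    def test_aic_never_exceeds_full_model(self, rng):
        for _ in range(20):
            n = 60
            cols = {"const": np.ones(n)}
            for i in range(6):
                cols[f"x{i}"] = rng.standard_normal(n)
            y = rng.standard_normal(n)
            res = abe_select(y, pd.DataFrame(cols), tau=rng.choice([0.05, np.inf]))
            assert res.aic <= res.full_aic + 1e-10


class TestBootstrapStability:
    def _design(self, rng, n=150):
        X = pd.DataFrame(
            {
                "const": np.ones(n),
                "strong": rng.standard_normal(n),
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n),
            }
        )
        y = 0.6 * X["strong"].to_numpy() + rng.standard_normal(n)
        return y, X

    def test_passive_intercept_always_included(self, rng):
        y, X = self._design(rng)
        rep = bootstrap_stability(y, X, n_boot=50, rng=rng)
        assert rep.loc["const", "inclusion_pct"] == 100.0

    def test_strong_predictor_stable(self, rng):
        y, X = self._design(rng)
        rep = bootstrap_stability(y, X, n_boot=100, rng=rng)
        assert rep.loc["strong", "inclusion_pct"] >= 75.0
        full_b = rep.loc["strong", "full_estimate"]
        full_se = rep.loc["strong", "full_se"]
        assert (
            full_b - 1.96 * full_se
            <= rep.loc["strong", "boot_median"]
            <= full_b + 1.96 * full_se
        )
        assert rep.loc["strong", "boot_p2_5"] <= rep.loc["strong", "boot_p97_5"]

    def test_seed_reproducible(self, rng):
        y, X = self._design(rng)
        a = bootstrap_stability(y, X, n_boot=30, rng=np.random.default_rng(9))
        b = bootstrap_stability(y, X, n_boot=30, rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)


class TestSmdBetweenModel:
    @staticmethod
    def _focal_cohort(seed):
        spec = CohortSpec(
            n_subjects=227,
            seed=seed,
            planted_beta_seg={},
            planted_beta_within={"SomatomotorDorsal": -0.27},
            planted_beta_pair={"SomatomotorLateral": 0.22},
            age_beta_quad=-0.19,
        )
        subj, _ = simulate_metrics_cohort(spec, focal="SomatomotorDorsal")
        z = standardize
        fd = subj["mean_fd"].to_numpy()
        others = [k for k in netseg.ANALYSIS_NETWORKS if k != "SomatomotorDorsal"]
        pairs = pd.DataFrame(
            {
                j: prepare_predictor(
                    subj[f"b_pair_SomatomotorDorsal_{j}"].to_numpy(), fd
                )
                for j in others
            }
        )
        return (
            z(subj["success_true"].to_numpy()),
            prepare_predictor(subj["w_SomatomotorDorsal"].to_numpy(), fd),
            pairs,
            z(subj["age"].to_numpy()),
        )

    def test_report_schema_and_planted_recovery(self):
        s_z, w, pairs, a_z = self._focal_cohort(41)
        rep = smd_between_model(s_z, w, pairs, a_z, n_boot=100, rng=np.random.default_rng(41))
        assert len(rep) == 16  # const + within + 12 pairs + age + age_sq
        assert (rep["boot_p2_5"] <= rep["boot_p97_5"]).all()
        assert rep.loc["const", "inclusion_pct"] == 100.0
        planted = ["within", "age_sq", "b_SomatomotorLateral"]
        assert rep.loc[planted, "inclusion_pct"].min() >= 75.0

    def test_null_generator_selects_nearly_nothing(self, rng):
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, 5)), columns=[f"x{i}" for i in range(5)])
        X.insert(0, "const", 1.0)
        y = rng.standard_normal(n)
        res = abe_select(y, X)
        assert len(res.selected) <= 3


class TestNetworkTtest:
    def _parc(self):
        return pd.DataFrame(
            {"roi_id": [f"R{i}" for i in range(6)], "network": ["A"] * 3 + ["B"] * 3}
        )

    def test_all_zero_betas_give_t_zero(self):
        betas = pd.DataFrame(np.zeros((8, 6)), columns=[f"R{i}" for i in range(6)])
        out = network_contrast_ttest(betas, self._parc(), ["A", "B"])
        assert (out["t"] == 0).all()

    def test_matches_one_sample_formula(self, rng):
        betas = pd.DataFrame(
            rng.standard_normal((5, 6)) + 0.4, columns=[f"R{i}" for i in range(6)]
        )
        out = network_contrast_ttest(betas, self._parc(), ["A"])
        means = betas[["R0", "R1", "R2"]].mean(axis=1).to_numpy()
        t_hand = means.mean() / (means.std(ddof=1) / np.sqrt(5))
        assert out.loc["A", "t"] == pytest.approx(t_hand, abs=1e-10)
        assert out.loc["A", "df"] == 4

    def test_roi_axis_uses_roi_count_for_df(self, rng):
        betas = pd.DataFrame(
            rng.standard_normal((227, 6)), columns=[f"R{i}" for i in range(6)]
        )
        subj_axis = network_contrast_ttest(betas, self._parc(), ["A"], axis="subjects")
        roi_axis = network_contrast_ttest(betas, self._parc(), ["A"], axis="rois")
        assert subj_axis.loc["A", "df"] == 226
        assert roi_axis.loc["A", "df"] == 2
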