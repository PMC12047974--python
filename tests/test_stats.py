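import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from fcgrad.stats import (
    clinical_correlations,
    explained_variance_anova,
    fdr_bh,
    mann_whitney,
    regional_glm,
    residualize,
    screen_and_impute_clinical,
)


class TestResidualize:
    def _cov(self, rng, n=50):
        return pd.DataFrame({
            "age": rng.normal(28, 6, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "mean_fd": np.abs(rng.normal(0.15, 0.05, n)),
        })

    def test_orthogonal_feature_unchanged(self):
        rng = np.random.default_rng(0)
        cov = self._cov(rng)
        x = np.column_stack([np.ones(len(cov)), cov.to_numpy()])
        y = rng.standard_normal(len(cov))
        # project out the covariate span exactly, then add a constant back
        proj = x @ np.linalg.lstsq(x, y, rcond=None)[0]
        y_orth = y - proj + y.mean()
        out = residualize(pd.DataFrame({"f": y_orth}), cov)
        np.testing.assert_allclose(out["f"], y_orth, atol=1e-10)

    def test_perfect_fit_leaves_grand_mean(self):
        rng = np.random.default_rng(1)
        cov = self._cov(rng)
        y = 2.0 * cov["age"].to_numpy()
        out = residualize(pd.DataFrame({"f": y}), cov)
        np.testing.assert_allclose(out["f"], y.mean(), atol=1e-8)

    def test_matches_hat_matrix_closed_form(self):
        rng = np.random.default_rng(2)
        cov = self._cov(rng)
        y = rng.standard_normal((len(cov), 3))
        x = np.column_stack([np.ones(len(cov)), cov.to_numpy()])
        hat = x @ np.linalg.inv(x.T @ x) @ x.T
        expected = y - hat @ y + y.mean(axis=0)
        out = residualize(pd.DataFrame(y), cov)
        np.testing.assert_allclose(out.to_numpy(), expected, atol=1e-10)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        cov = self._cov(rng)
        cov["age2"] = 2 * cov["age"]
        with pytest.raises(ValueError, match="collinear"):
            residualize(pd.DataFrame({"f": rng.standard_normal(len(cov))}), cov)


class TestMannWhitney:
    def test_fully_separated_exact_enumeration(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.estimate == 0.0
        assert res.p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_give_half_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, list(a))
        assert res.estimate == pytest.approx(len(a) * len(a) / 2)

    def test_all_constant_flagged_p_one(self):
        res = mann_whitney([2, 2, 2], [2, 2])
        assert res.p == 1.0
        assert res.effect_size == 0.0
        assert "identical" in res.note

    def test_eta_squared_zero_when_balanced(self):
        res = mann_whitney([1, 4], [2, 3])
        assert res.effect_size == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_and_asymptotic_branches_agree(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(6)
        b = rng.standard_normal(6) + 0.5
        exact = mann_whitney(a, b).p
        approx = mann_whitney(a, b, exact_max_n=0).p
        assert abs(exact - approx) <= 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_u_statistic_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(20)
        b = rng.standard_normal(25) + 0.3
        ours = mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        assert ours.estimate == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestFdrBH:
    def test_hand_worked_step_up(self):
        q = fdr_bh([0.001, 0.008, 0.039, 0.041])
        np.testing.assert_allclose(q, [0.004, 0.016, 0.041, 0.041], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        np.testing.assert_array_equal(fdr_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_never_decreases_and_order_invariant(self, ps):
        q = fdr_bh(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = fdr_bh(np.asarray(ps)[perm])
        np.testing.assert_allclose(np.sort(q_perm), np.sort(q), atol=1e-12)


class TestRegionalGLM:
    def _data(self, rng, n=60, p=50, effect=0.0, effect_parcels=()):
        group = np.array(["HC"] * (n // 2) + ["ROP"] * (n // 2))
        scores = rng.standard_normal((n, p))
        for j in effect_parcels:
            scores[group == "ROP", j] += effect
        cov = pd.DataFrame({
            "age": rng.normal(28, 6, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "mean_fd": np.abs(rng.normal(0.15, 0.05, n)),
        })
        return scores, group, cov

    def test_null_simulation_fdr_controls_rejections(self):
        rng = np.random.default_rng(4)
        scores, group, cov = self._data(rng, n=80, p=1000)
        res = regional_glm(scores, group, ("HC", "ROP"), cov)
        assert (res["q"] < 0.05).mean() <= 0.05

    def test_planted_effect_concentrates_discoveries(self):
        rng = np.random.default_rng(5)
        planted = list(range(40))
        scores, group, cov = self._data(
            rng, n=80, p=200, effect=1.5, effect_parcels=planted
        )
        res = regional_glm(scores, group, ("HC", "ROP"), cov)
        hits = res.loc[res["q"] < 0.05, "parcel_id"]
        assert len(hits) > 0
        assert (hits.isin(planted)).mean() >= 0.8

    def test_covariate_orthogonal_to_group_leaves_t_unchanged(self):
        # a covariate orthogonal to the group indicator and to the responses
        # leaves the group coefficient untouched; t changes only through the
        # residual degrees of freedom (one fewer), an exact OLS identity
        rng = np.random.default_rng(6)
        n = 40
        group = np.array(["HC", "ROP"] * (n // 2))
        g = (group == "ROP").astype(float)
        scores = rng.standard_normal((n, 10))
        raw = rng.standard_normal(n)
        basis = np.column_stack([np.ones(n), g, scores])
        cov_orth = raw - basis @ np.linalg.lstsq(basis, raw, rcond=None)[0]
        with_cov = regional_glm(scores, group, ("HC", "ROP"),
                                pd.DataFrame({"c": cov_orth}))
        without = regional_glm(scores, group, ("HC", "ROP"))
        dof_factor = np.sqrt((n - 3) / (n - 2))
        np.testing.assert_allclose(
            with_cov["t"], without["t"] * dof_factor, atol=1e-8
        )

    def test_pooled_patients_contrast(self):
        rng = np.random.default_rng(7)
        group = np.array(["HC"] * 20 + ["ROP"] * 10 + ["ROD"] * 10)
        scores = rng.standard_normal((40, 5))
        res = regional_glm(scores, group, ("HC", ("ROP", "ROD")))
        assert res.attrs["dof"] == 40 - 2

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            regional_glm(np.zeros((4, 3)), ["HC", "HC", "HC", "ROP"], ("HC", "ROP"))


class TestScreenAndImpute:
    def _cohort(self):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["HC", "HC", "HC", "ROP", "ROP", "ROP"],
            "a": [1.0, 2.0, 3.0, np.nan, 5.0, 6.0],
            "b": [np.nan, 2.0, 4.0, 4.0, 5.0, 6.0],
            "c": [np.nan, 1.0, 1.0, 2.0, 2.0, 2.0],
            "d": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
            "e": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
            "f": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
            "g": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
            "h": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
            "i": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
            "j": [np.nan, 0.0, 0.0, 1.0, 1.0, 1.0],
        })

    def test_over_30_percent_missing_excluded(self):
        cohort = self._cohort()  # subject s0 misses 9/10 clinical values
        out, report = screen_and_impute_clinical(cohort, list("abcdefghij"))
        assert "s0" not in out["subject_id"].tolist()
        assert report["n_dropped"] == 1

    def test_exactly_30_percent_retained(self):
        # strictly-more-than rule: a subject at exactly 30% missing stays
        cohort = self._cohort()
        cohort.loc[1, ["a", "b", "c"]] = np.nan  # s1 misses 3 of 10
        out, _ = screen_and_impute_clinical(cohort, list("abcdefghij"))
        assert "s1" in set(out["subject_id"])

    def test_group_median_imputation(self):
        cohort = pd.DataFrame({
            "group": ["x", "x", "x", "x", "y", "y"],
            "score": [1.0, 2.0, 3.0, np.nan, 10.0, np.nan],
        })
        out, report = screen_and_impute_clinical(cohort, ["score"],
                                                 max_missing_fraction=1.0)
        assert out.loc[3, "score"] == 2.0  # median of (1,2,3)
        assert out.loc[5, "score"] == 10.0
        assert report["n_imputed"] == 2

    def test_entirely_missing_group_column_rejected(self):
        cohort = pd.DataFrame({
            "group": ["x", "x", "y", "y"],
            "score": [np.nan, np.nan, 1.0, 2.0],
        })
        with pytest.raises(ValueError, match="entirely missing"):
            screen_and_impute_clinical(cohort, ["score"], max_missing_fraction=1.0)


class TestClinicalCorrelations:
    def test_identity_column_gives_r_one(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(30)
        out = clinical_correlations(pd.DataFrame({"m": v}), pd.DataFrame({"c": v}))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_monotone_nonlinear_relation_rank_r_one(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal(30)
        out = clinical_correlations(
            pd.DataFrame({"m": v}), pd.DataFrame({"c": np.exp(v)})
        )
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_columns_null(self):
        rng = np.random.default_rng(10)
        out = clinical_correlations(
            pd.DataFrame({"m": rng.standard_normal(100)}),
            pd.DataFrame({"c": rng.standard_normal(100)}),
        )
        assert abs(out["r"].iloc[0]) < 0.3
        assert out["q"].iloc[0] > 0.05

    def test_constant_column_reported_na_excluded_from_fdr(self):
        rng = np.random.default_rng(11)
        out = clinical_correlations(
            pd.DataFrame({"m": rng.standard_normal(20), "const": np.ones(20)}),
            pd.DataFrame({"c": rng.standard_normal(20)}),
        )
        const_row = out[out.metric == "const"]
        assert const_row["r"].isna().all() and const_row["q"].isna().all()
        assert out[out.metric == "m"]["q"].notna().all()

    def test_pearson_option(self):
        rng = np.random.default_rng(12)
        v = rng.standard_normal(30)
        out = clinical_correlations(
            pd.DataFrame({"m": v}), pd.DataFrame({"c": 2 * v + 1}), method="pearson"
        )
        assert out["r"].iloc[0] == pytest.approx(1.0)


class TestExplainedVarianceAnova:
    def test_identical_groups_give_zero_f(self):
        vals = np.tile([0.3, 0.4, 0.5], 2)
        groups = ["a"] * 3 + ["b"] * 3
        res, dfs = explained_variance_anova(vals, groups)
        assert res.estimate == pytest.approx(0.0)
        assert dfs == (1, 4)

    def test_denominator_dof_for_four_groups(self):
        rng = np.random.default_rng(13)
        n = 1071
        groups = np.repeat(["a", "b", "c", "d"], [376, 243, 212, 240])
        _, dfs = explained_variance_anova(rng.standard_normal(n), groups)
        assert dfs == (3, 1067)

    def test_type_one_error_rate_calibrated(self):
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 1000
        groups = np.repeat(["a", "b", "c"], 15)
        for _ in range(n_rep):
            res, _ = explained_variance_anova(rng.standard_normal(45), groups)
            rejections += res.p < 0.05
        assert 0.035 <= rejections / n_rep <= 0.065

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            explained_variance_anova([1.0, 2.0, 3.0], ["a", "a", "b"])
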