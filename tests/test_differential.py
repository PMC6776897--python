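import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from oracles import bh_oracle
from xcikit.chipquant import CountMatrix, SampleInfo
from xcikit.differential import (
    DifferentialModel,
    benjamini_hochberg,
    build_design,
    cluster_samples,
    estimate_moderation,
    filter_expressed_genes,
    fit_weighted_linear_model,
    log2_cpm,
    mixture_log2_ratio,
    moderate_and_test,
    tpm_from_counts,
    voom_weights,
)
from xcikit.simulate import simulate_mixture_counts


def _mix_samples(f1=0.5, f2=0.5):
    return [
        SampleInfo("c1_no", "c1", "noDOX", "RNA", 0.0),
        SampleInfo("c1_do", "c1", "DOX", "RNA", f1),
        SampleInfo("c2_no", "c2", "noDOX", "RNA", 0.0),
        SampleInfo("c2_do", "c2", "DOX", "RNA", f2),
    ]


class TestLog2Cpm:
    def test_zero_count_plugin(self):
        v = log2_cpm(np.array([[0]]), library_sizes=[999_999])
        assert v[0, 0] == pytest.approx(-1.0)

    def test_offset_plugin(self):
        v = log2_cpm(np.array([[99]]), library_sizes=[999_999])
        assert v[0, 0] == pytest.approx(np.log2(99.5), abs=1e-9)

    def test_factor_two_shifts_by_minus_one(self):
        counts = np.array([[100, 100]])
        base = log2_cpm(counts, library_sizes=[1e6, 1e6])
        adj = log2_cpm(counts, library_sizes=[1e6, 1e6], factors=[1.0, 2.0])
        # doubling the effective library halves cpm: shift just under -1
        # because of the +1 library offset
        expected_shift = np.log2((1e6 + 1) / (2e6 + 1))
        assert adj[0, 1] - base[0, 1] == pytest.approx(expected_shift)

    def test_zero_library_error(self):
        with pytest.raises(ValueError):
            log2_cpm(np.array([[1]]), library_sizes=[0])


class TestDesign:
    def test_condition_model_columns_and_rank(self):
        X, cols, contrast = build_design(_mix_samples(), "condition")
        assert X.shape == (4, 4)
        assert np.linalg.matrix_rank(X) == 4
        assert contrast.sum() == pytest.approx(1.0)

    def test_induction_model_slope_columns(self):
        X, cols, contrast = build_design(_mix_samples(0.4, 0.6), "induction")
        slope_cols = [i for i, c in enumerate(cols) if "induction" in c]
        assert sorted(X[:, slope_cols].max(axis=0)) == pytest.approx([0.4, 0.6])

    def test_rank_deficiency_detected(self):
        # one clone never sees DOX: its condition column is all-zero
        samples = [
            SampleInfo("a", "c1", "noDOX", "RNA", 0.0),
            SampleInfo("b", "c1", "DOX", "RNA", 0.5),
            SampleInfo("c", "c2", "noDOX", "RNA", 0.0),
            SampleInfo("d", "c2", "noDOX", "RNA", 0.0),
        ]
        with pytest.raises(ValueError, match="rank"):
            build_design(samples, "condition")


class TestWeightedFit:
    def test_two_point_slope(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        fit = fit_weighted_linear_model(np.array([[0.0, 2.0]]), X)
        assert fit["effect"].iloc[0] == pytest.approx(2.0)

    def test_noiseless_per_clone_interpolation(self):
        samples = _mix_samples(0.5, 0.5)
        X, _, contrast = build_design(samples, "induction")
        y = np.array([[5.0, 4.0, 5.0, 4.0]])  # slope -2 per clone
        fit = fit_weighted_linear_model(y, X, contrast=contrast)
        assert fit["effect"].iloc[0] == pytest.approx(-2.0)

    def test_mixture_closed_form(self):
        samples = _mix_samples(0.5, 0.5)
        X, _, contrast = build_design(samples, "induction")
        y_dox = 10 + mixture_log2_ratio(0.5, -2.0)
        y = np.array([[10.0, y_dox, 10.0, y_dox]])
        fit = fit_weighted_linear_model(y, X, contrast=contrast)
        assert fit["effect"].iloc[0] == pytest.approx(
            mixture_log2_ratio(0.5, -2.0) / 0.5, abs=1e-9
        )
        assert fit["effect"].iloc[0] == pytest.approx(-1.356, abs=1e-3)

    def test_balanced_two_group_equals_mean_difference(self, rng):
        samples = [
            SampleInfo("a", "c1", "noDOX", "RNA", 0.0),
            SampleInfo("b", "c1", "DOX", "RNA", 0.5),
            SampleInfo("c", "c1", "noDOX", "RNA", 0.0),
            SampleInfo("d", "c1", "DOX", "RNA", 0.5),
        ]
        X, _, contrast = build_design(samples, "condition")
        y = rng.normal(size=(20, 4))
        fit = fit_weighted_linear_model(y, X, contrast=contrast)
        expected = y[:, [1, 3]].mean(axis=1) - y[:, [0, 2]].mean(axis=1)
        np.testing.assert_allclose(fit["effect"], expected, atol=1e-10)

    def test_weights_shift_fit(self):
        X = np.array([[1.0], [1.0], [1.0]])
        y = np.array([[0.0, 0.0, 3.0]])
        w = np.array([[1.0, 1.0, 2.0]])
        fit = fit_weighted_linear_model(y, X, weights=w)
        assert fit["effect"].iloc[0] == pytest.approx(6.0 / 4.0)


class TestVoom:
    def _design(self, n):
        X = np.ones((n, 2))
        X[: n // 2, 1] = 0.0
        return X

    def test_homoscedastic_weights_nearly_flat(self, rng):
        n_feat, n_samp = 1000, 8
        y = rng.normal(5.0, 1.0, size=(n_feat, n_samp)) + rng.normal(
            0, 3, size=(n_feat, 1)
        )
        w = voom_weights(y, self._design(n_samp))
        assert w.max() / w.min() < 2.0

    def test_constant_trend_gives_constant_weights(self):
        resid = np.array([1.0, -1.0, 1.0, -1.0, 0.0, 0.0, 0.0, 0.0])
        y = np.arange(12, dtype=float)[:, None] + resid[None, :]
        w = voom_weights(y, self._design(8))
        assert np.allclose(w, w[0, 0])
        s2 = ((resid - resid.mean()) ** 2).sum() / 6  # df = 8 - 2
        assert w[0, 0] == pytest.approx(np.sqrt(np.sqrt(s2)) ** -4, rel=1e-6)

    def test_few_features_fall_back_to_unit_weights(self):
        y = np.ones((3, 8)) + np.arange(8) * 0.1
        with pytest.warns(RuntimeWarning, match="unit"):
            w = voom_weights(y, self._design(8))
        assert np.all(w == 1.0)


class TestModeration:
    def _fits(self, s2, df=4.0, effect=None, se=None):
        n = len(s2)
        return pd.DataFrame(
            {
                "effect": effect if effect is not None else np.zeros(n),
                "se_unscaled": se if se is not None else np.ones(n),
                "s2": s2,
                "df_resid": df,
            }
        )

    def test_d0_zero_keeps_sample_variances(self, rng):
        s2 = rng.chisquare(4, size=50) / 4
        out = moderate_and_test(self._fits(s2), d0=0.0, s0_2=1.0)
        np.testing.assert_allclose(out["s2_post"], s2, atol=1e-12)

    def test_d0_infinite_shrinks_fully(self, rng):
        s2 = rng.chisquare(4, size=50) / 4
        out = moderate_and_test(self._fits(s2), d0=np.inf, s0_2=2.5)
        np.testing.assert_allclose(out["s2_post"], 2.5, atol=1e-12)

    def test_moment_matching_recovers_prior(self, rng):
        # s2 ~ s0^2 * chi2(df)/df scaled by inv-chi2(d0) prior draws
        d0_true, s0_true, df = 8.0, 1.5, 4.0
        var_true = d0_true * s0_true / rng.chisquare(d0_true, size=20000)
        s2 = var_true * rng.chisquare(df, size=20000) / df
        d0, s0_2 = estimate_moderation(s2, df)
        assert d0 == pytest.approx(d0_true, rel=0.15)
        assert s0_2 == pytest.approx(s0_true, rel=0.1)

    def test_underdispersed_variances_give_infinite_prior_df(self):
        s2 = np.full(100, 2.0)  # zero spread in log s2
        d0, s0_2 = estimate_moderation(s2, 4.0)
        assert np.isinf(d0)
        # prior scale includes the chi-square bias correction for log s2
        from scipy.special import digamma

        assert s0_2 == pytest.approx(2.0 * np.exp(np.log(2.0) - digamma(2.0)), rel=1e-6)

    def test_null_type_i_error_calibrated(self, rng):
        # null data through the whole fit+moderation path
        n_feat, n_samp = 2000, 8
        X = np.column_stack([np.ones(n_samp), np.repeat([0, 1], n_samp // 2)])
        contrast = np.array([0.0, 1.0])
        y = rng.normal(size=(n_feat, n_samp)) * rng.uniform(
            0.5, 2.0, size=(n_feat, 1)
        )
        fits = fit_weighted_linear_model(y, X, contrast=contrast)
        out = moderate_and_test(fits)
        frac = float((out["p"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_requires_residual_df(self):
        with pytest.raises(ValueError):
            moderate_and_test(self._fits(np.ones(5), df=0.0))


class TestBenjaminiHochberg:
    def test_stepup_examples(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])
        np.testing.assert_allclose(benjamini_hochberg([0.005, 0.1]), [0.01, 0.1])

    def test_matches_oracle_and_statsmodels(self, rng):
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            q = benjamini_hochberg(p)
            np.testing.assert_allclose(q, bh_oracle(list(p)), atol=1e-12)
            np.testing.assert_allclose(
                q, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=100)
        q = benjamini_hochberg(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestExpressionFilter:
    def test_tpm_single_gene_is_million(self):
        t = tpm_from_counts(np.array([[7, 3]]), [1000.0])
        np.testing.assert_allclose(t, 1e6)

    def test_six_of_twelve_rule(self):
        tpm = pd.DataFrame(
            np.vstack(
                [
                    np.r_[np.full(6, 2.0), np.full(6, 0.5)],  # exactly 6 above
                    np.r_[np.full(5, 2.0), np.full(7, 0.5)],  # only 5 above
                ]
            ),
            index=["keep", "drop"],
        )
        assert filter_expressed_genes(tpm) == ["keep"]

    def test_threshold_is_strict(self):
        tpm = pd.DataFrame(np.full((1, 12), 1.0), index=["g"])
        assert filter_expressed_genes(tpm) == []

    def test_zero_exon_length_error(self):
        with pytest.raises(ValueError):
            tpm_from_counts(np.array([[1]]), [0.0])


class TestClustering:
    def test_identical_samples_merge_at_zero(self, rng):
        x = rng.normal(size=20)
        expr = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=20)})
        res = cluster_samples(expr)
        assert res["Z"][0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(res["Z"][0, :2]) == [0, 1]

    def test_two_groups_separate(self, rng):
        base1 = rng.normal(size=30)
        base2 = rng.normal(size=30)
        expr = pd.DataFrame(
            {
                "a1": base1 + rng.normal(0, 0.01, 30),
                "a2": base1 + rng.normal(0, 0.01, 30),
                "b1": base2 + rng.normal(0, 0.01, 30),
                "b2": base2 + rng.normal(0, 0.01, 30),
            }
        )
        labels = cluster_samples(expr)["labels"](2)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_matches_scipy_ward_through_sqrt_transform(self, rng):
        # the classic Ward update on distances d equals scipy's ward on
        # sqrt(d) (scipy applies the recurrence to squared inputs)
        expr = pd.DataFrame(rng.normal(size=(25, 6)))
        res = cluster_samples(expr)
        d = 1.0 - np.corrcoef(expr.to_numpy().T)
        np.fill_diagonal(d, 0.0)
        Z_ref = linkage(squareform(np.sqrt(d), checks=False), method="ward")
        np.testing.assert_allclose(res["Z"][:, 2], Z_ref[:, 2] ** 2, atol=1e-9)
        for row_mine, row_ref in zip(res["Z"], Z_ref):
            assert sorted(row_mine[:2]) == sorted(row_ref[:2])

    def test_constant_profile_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="a"):
            cluster_samples(expr)


class TestDifferentialModel:
    def test_exact_recovery_on_noiseless_linear_data(self):
        samples = _mix_samples(0.4664, 0.5944)
        counts = CountMatrix(
            ["w0"], [s.sample_id for s in samples], np.array([[8, 8, 8, 8]]), [1e6] * 4
        )
        model = DifferentialModel(counts, samples, model="induction", use_voom=False)
        slope = -1.75
        f = np.array([0.0, 0.4664, 0.0, 0.5944])
        model.log2cpm = np.array([10.0 + slope * f])
        res = model.fit(moderate=False)
        assert res.effect.iloc[0] == pytest.approx(slope, abs=1e-9)

    def test_stochastic_mixture_recovery(self):
        cm, samples = simulate_mixture_counts(
            2000, -2.0, (0.466, 0.594), seed=7
        )
        res = DifferentialModel(cm, samples, model="induction", use_voom=False).fit(
            moderate=False
        )
        expected = 0.5 * (
            mixture_log2_ratio(0.466, -2.0) / 0.466
            + mixture_log2_ratio(0.594, -2.0) / 0.594
        )
        assert res.effect.mean() == pytest.approx(expected, abs=0.1)

    def test_mixture_attenuation_is_concave(self):
        # |corrected logFC| <= |beta| for partial induction, equal at f=1
        beta = -2.0
        for f in np.arange(0.1, 1.0, 0.1):
            slope = mixture_log2_ratio(f, beta) / f
            assert abs(slope) <= abs(beta) + 1e-12
        assert mixture_log2_ratio(1.0, beta) / 1.0 == pytest.approx(beta)

    def test_summary_mentions_model(self):
        cm, samples = simulate_mixture_counts(30, -1.0, (0.5, 0.6), seed=3)
        res = DifferentialModel(cm, samples, model="induction", use_voom=False).fit(
            moderate=False
        )
        text = res.summary()
        assert "induction" in text
        assert "features:   30" in text
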