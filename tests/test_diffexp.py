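"""DE engine: aggregation, normalization, dispersions, GLM, shrinkage, VST."""

import numpy as np
import pandas as pd
import pytest

from hostcomp import diffexp
from hostcomp.diffexp import DesignSpec


class TestAggregateTranscripts:
    def test_one_transcript_per_gene_is_identity(self):
        tx = pd.DataFrame({"s": [5.0, 7.0]}, index=["t1", "t2"])
        out = diffexp.aggregate_transcripts(tx, {"t1": "g1", "t2": "g2"})
        assert out.loc["g1", "s"] == 5 and out.loc["g2", "s"] == 7

    def test_member_counts_summed_then_rounded(self):
        tx = pd.DataFrame({"s": [10.4, 20.3]}, index=["t1", "t2"])
        out = diffexp.aggregate_transcripts(tx, {"t1": "g", "t2": "g"})
        assert out.loc["g", "s"] == 31

    def test_unmapped_transcript_listed(self):
        tx = pd.DataFrame({"s": [1.0]}, index=["tX"])
        with pytest.raises(ValueError, match="tX"):
            diffexp.aggregate_transcripts(tx, {"tY": "g"})

    def test_gene_without_transcripts_absent(self):
        tx = pd.DataFrame({"s": [1.0]}, index=["t1"])
        out = diffexp.aggregate_transcripts(tx, {"t1": "g1"})
        assert list(out.index) == ["g1"]


class TestAggregateOrthologs:
    def _map(self, pairs):
        return pd.DataFrame(pairs, columns=["src", "tgt"])

    def test_bijective_map_permutes(self):
        c = pd.DataFrame({"s": [1, 2]}, index=["a", "b"])
        out = diffexp.aggregate_orthologs(c, self._map([("a", "B"), ("b", "A")]))
        assert out.loc["B", "s"] == 1 and out.loc["A", "s"] == 2

    def test_many_to_one_summed_under_sum_policy(self):
        c = pd.DataFrame({"s": [5, 7]}, index=["a", "b"])
        out = diffexp.aggregate_orthologs(
            c, self._map([("a", "T"), ("b", "T")]), policy="sum"
        )
        assert out.loc["T", "s"] == 12

    def test_drop_ambiguous_removes_target(self):
        c = pd.DataFrame({"s": [5, 7]}, index=["a", "b"])
        out = diffexp.aggregate_orthologs(
            c, self._map([("a", "T"), ("b", "T")]), policy="drop_ambiguous"
        )
        assert "T" not in out.index

    def test_one_to_many_source_dropped_under_sum(self):
        c = pd.DataFrame({"s": [5]}, index=["a"])
        out = diffexp.aggregate_orthologs(
            c, self._map([("a", "T1"), ("a", "T2")]), policy="sum"
        )
        assert out.empty

    def test_disjoint_map_rejected(self):
        c = pd.DataFrame({"s": [5]}, index=["a"])
        with pytest.raises(ValueError, match="common"):
            diffexp.aggregate_orthologs(c, self._map([("x", "T")]))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        c = pd.DataFrame({"s1": [3, 9, 2], "s2": [3, 9, 2]})
        assert np.allclose(diffexp.estimate_size_factors(c), 1.0)

    def test_threefold_column_measured_hand_values(self):
        c = pd.DataFrame({"s1": [10, 20, 5], "s2": [30, 60, 15]})
        assert diffexp.estimate_size_factors(c).to_numpy() == pytest.approx(
            [1 / np.sqrt(3), np.sqrt(3)]
        )

    def test_single_gene_ratios_to_geometric_mean(self):
        c = pd.DataFrame({"s1": [4], "s2": [9]})
        assert diffexp.estimate_size_factors(c).to_numpy() == pytest.approx(
            [4 / 6, 9 / 6]
        )

    def test_gene_order_invariance(self, rng):
        c = pd.DataFrame(rng.integers(1, 100, (40, 5)))
        sf1 = diffexp.estimate_size_factors(c)
        sf2 = diffexp.estimate_size_factors(c.sample(frac=1.0, random_state=3))
        assert np.allclose(sf1, sf2)

    def test_scaling_one_sample_scales_its_factor(self, rng):
        c = pd.DataFrame(rng.integers(1, 100, (60, 4)))
        sf1 = diffexp.estimate_size_factors(c)
        c2 = c.copy()
        c2[0] = c2[0] * 5
        sf2 = diffexp.estimate_size_factors(c2)
        # ratios between samples change only for the scaled one, by the factor
        assert sf2[0] / sf2[1] == pytest.approx(5 * sf1[0] / sf1[1], rel=1e-9)

    def test_no_universally_expressed_gene_rejected(self):
        c = pd.DataFrame({"s1": [1, 0], "s2": [0, 1]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            diffexp.estimate_size_factors(c)


class TestDispersions:
    def test_poisson_data_yields_tiny_dispersion(self, rng):
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), 600))
        c = pd.DataFrame(rng.poisson(mu[:, None], (600, 50)))
        sf = diffexp.estimate_size_factors(c)
        d = diffexp.estimate_dispersions(c, sf)
        assert d.shrunk.median() <= 0.01

    def test_nb_dispersion_recovered(self, null_counts):
        counts, groups = null_counts
        sf = diffexp.estimate_size_factors(counts)
        d = diffexp.estimate_dispersions(counts, sf, groups=groups)
        assert 0.15 <= d.shrunk.median() <= 0.25

    def test_constant_gene_floored(self):
        c = pd.DataFrame(
            {"s1": [50, 10], "s2": [50, 14], "s3": [50, 9], "s4": [50, 12]}
        )
        sf = pd.Series(1.0, index=c.columns)
        d = diffexp.estimate_dispersions(c, sf)
        assert d.genewise.iloc[0] == pytest.approx(diffexp.MIN_DISPERSION)

    def test_all_zero_matrix_rejected(self):
        c = pd.DataFrame(np.zeros((3, 4)))
        sf = pd.Series(1.0, index=c.columns)
        with pytest.raises(ValueError):
            diffexp.estimate_dispersions(c, sf)


class TestGLMFit:
    def test_matches_direct_likelihood_maximization(self, rng):
        """IRLS equals independent NB-likelihood maximization (fixed alpha)."""
        import statsmodels.api as sm
        from scipy.optimize import minimize
        from scipy.special import gammaln

        g, alpha = 20, 0.1
        groups = np.array([0] * 5 + [1] * 5)
        mu = np.exp(rng.uniform(np.log(50), np.log(500), g))
        beta1 = rng.normal(0, 1, g)
        lam = mu[:, None] * np.exp(beta1[:, None] * groups[None, :])
        Y = rng.poisson(rng.gamma(1 / alpha, lam * alpha))
        c = pd.DataFrame(Y)
        sf = pd.Series(1.0, index=c.columns)
        disp = pd.Series(alpha, index=c.index)
        X = pd.DataFrame({"Intercept": 1.0, "grp": groups}, index=c.columns)
        res = diffexp.fit_and_test(c, sf, disp, X, "grp")
        ln2 = np.log(2)

        def nll(b, y):
            m = np.exp(b[0] + b[1] * groups)
            r = 1 / alpha
            return -np.sum(
                gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                + r * np.log(r / (r + m)) + y * np.log(m / (r + m))
            )

        for i in range(g):
            direct = minimize(nll, x0=[np.log(Y[i].mean() + 0.5), 0.0],
                              args=(Y[i],), method="Nelder-Mead",
                              options={"xatol": 1e-8, "fatol": 1e-10}).x
            assert res["lfc_raw"].iloc[i] * ln2 == pytest.approx(direct[1], abs=1e-3)
            sm_fit = sm.GLM(
                Y[i], X.to_numpy(),
                family=sm.families.NegativeBinomial(alpha=alpha),
            ).fit()
            assert res["lfc_raw"].iloc[i] * ln2 == pytest.approx(
                sm_fit.params[1], abs=1e-6
            )

    def test_identical_groups_give_zero_lfc(self, rng):
        half = pd.DataFrame(rng.poisson(50, (30, 3)))
        c = pd.concat([half, half], axis=1)
        c.columns = range(6)
        sf = pd.Series(1.0, index=c.columns)
        disp = pd.Series(0.1, index=c.index)
        X = pd.DataFrame({"Intercept": 1.0, "grp": [0, 0, 0, 1, 1, 1]},
                         index=c.columns)
        res = diffexp.fit_and_test(c, sf, disp, X, "grp")
        assert np.allclose(res["lfc_raw"], 0.0, atol=1e-6)

    def test_padj_at_least_pvalue_and_bh_hand_case(self, null_counts):
        from statsmodels.stats.multitest import multipletests

        counts, groups = null_counts
        sf = diffexp.estimate_size_factors(counts)
        d = diffexp.estimate_dispersions(counts, sf, groups=groups)
        st = pd.DataFrame({"condition": groups}, index=counts.columns)
        X = DesignSpec(factors=["condition"]).build(st)
        res = diffexp.fit_and_test(counts, sf, d.shrunk, X, "condition_B")
        ok = res["pvalue"].notna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "pvalue"] - 1e-12).all()
        # BH on the worked four p-values equalizes them at 0.04
        assert multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1] == pytest.approx(
            [0.04] * 4
        )

    def test_rank_deficient_design_rejected(self):
        c = pd.DataFrame([[1, 2, 3, 4]], columns=range(4))
        sf = pd.Series(1.0, index=c.columns)
        disp = pd.Series(0.1, index=c.index)
        X = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [2.0, 2, 2, 2]}, index=c.columns)
        with pytest.raises(ValueError, match="full rank"):
            diffexp.fit_and_test(c, sf, disp, X, "b")


class TestShrinkage:
    def _de(self, lfc, se):
        return pd.DataFrame({"lfc_raw": lfc, "se": se, "lfc_shrunk": np.nan})

    def test_data_dominate_when_se_vanishes(self):
        out = diffexp.shrink_lfc(self._de([2.0], [1e-6]), prior_sd_grid=[1.0])
        assert out["lfc_shrunk"].iloc[0] == pytest.approx(2.0, abs=1e-5)

    def test_prior_dominates_when_se_explodes(self):
        out = diffexp.shrink_lfc(self._de([2.0], [1e3]), prior_sd_grid=[1.0])
        assert abs(out["lfc_shrunk"].iloc[0]) < 1e-4

    def test_conjugate_normal_normal_posterior_mean(self):
        out = diffexp.shrink_lfc(self._de([2.0], [1.0]), prior_sd_grid=[1.0])
        assert out["lfc_shrunk"].iloc[0] == pytest.approx(1.0)

    def test_never_increases_magnitude_and_preserves_sign(self, rng):
        lfc = rng.normal(0, 2, 200)
        se = rng.uniform(0.1, 2.0, 200)
        out = diffexp.shrink_lfc(self._de(lfc, se))
        assert (out["lfc_shrunk"].abs() <= np.abs(lfc) + 1e-12).all()
        assert (np.sign(out["lfc_shrunk"]) == np.sign(lfc)).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            diffexp.shrink_lfc(self._de([1.0], [1.0]), prior_sd_grid=[])


class TestDifferentialActivation:
    def test_missing_cell_line_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="no samples"):
            diffexp.differential_activation(
                small_bundle.counts["CHO"], small_bundle.sample_table, "NS0"
            )

    def test_null_construction_shows_no_activation(self, rng):
        # "producers" are a fresh draw from the same distribution as controls
        g = 400
        mu = np.exp(rng.uniform(np.log(20), np.log(500), g))
        lam = rng.gamma(5, mu[:, None] / 5, (g, 8))
        c = pd.DataFrame(rng.poisson(lam), columns=[f"s{j}" for j in range(8)])
        st = pd.DataFrame(
            {
                "sample_id": c.columns,
                "cell_line": "CHO",
                "condition": ["control"] * 4 + ["producer"] * 4,
                "r_protein": ["none"] * 4 + ["RP"] * 4,
                "replicate": [1, 2, 3, 4] * 2,
            }
        )
        res = diffexp.differential_activation(c, st, "CHO")
        assert res["lfc_shrunk"].abs().mean() < 0.2
        assert (res["padj"] < 0.05).sum() <= 0.05 * g


class TestVST:
    def test_monotone_in_counts(self):
        c = pd.DataFrame({"s": np.arange(0, 500, 7)})
        sf = pd.Series(1.0, index=c.columns)
        v = diffexp.vst(c, sf, (0.1, 1.0))
        assert (np.diff(v["s"]) > 0).all()

    def test_stabilizes_variance_across_mean_bins(self, rng):
        g, alpha = 2000, 0.1
        mu = np.exp(rng.uniform(np.log(2), np.log(5000), g))
        lam = rng.gamma(1 / alpha, mu[:, None] * alpha, (g, 30))
        c = pd.DataFrame(rng.poisson(lam))
        sf = pd.Series(1.0, index=c.columns)
        v = diffexp.vst(c, sf, (alpha, 0.0))
        bins = pd.qcut(mu, 5, labels=False)
        sd_v = v.std(axis=1).groupby(bins).mean()
        assert sd_v.max() / sd_v.min() < 2.0

    def test_large_count_differences_scale_as_log2_over_sqrt_a0(self):
        a0 = 0.25
        c = pd.DataFrame({"s": [1e4, 2e4]})
        sf = pd.Series(1.0, index=c.columns)
        v = diffexp.vst(c, sf, (a0, 0.0))
        assert v["s"].iloc[1] - v["s"].iloc[0] == pytest.approx(1.0 / np.sqrt(a0), rel=1e-3)

    def test_nonpositive_asymptote_rejected(self):
        c = pd.DataFrame({"s": [1]})
        with pytest.raises(ValueError):
            diffexp.vst(c, pd.Series(1.0, index=c.columns), (0.0, 1.0))


class TestEstimators:
    def test_transformer_fits_and_transforms(self, null_counts):
        counts, groups = null_counts
        vt = diffexp.VarianceStabilizingTransformer(groups=groups).fit(counts)
        v = vt.transform(counts)
        assert v.shape == counts.shape
        assert vt.dispersion_trend_[0] > 0

    def test_estimator_get_set_params_roundtrip(self):
        est = diffexp.NegativeBinomialDE(shrink=False)
        est.set_params(**est.get_params())
        assert est.get_params()["shrink"] is False

    def test_unfitted_test_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            diffexp.NegativeBinomialDE().test("x")
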