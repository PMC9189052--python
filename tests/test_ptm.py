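"""PTM indices, enzyme ES summaries and the Bayesian interaction model."""

import numpy as np
import pandas as pd
import pytest

from hostcomp import enrichment, ptm, simulate
from hostcomp.ptm import BayesianInteractionRegression


def _row(length=400, n=4, o=0, ss=2, gpi=0):
    return pd.Series(
        {"length_aa": length, "n_glyc_sites": n, "o_glyc_sites": o,
         "disulfide_bonds": ss, "gpi_anchor": gpi}
    )


def _balanced_data(n=50, truth=(0.0, 0.0, 0.0, 0.8, 0.1), seed=11):
    """Two-level factorial recovery design: index 0/0.6, enzyme score +-1."""
    half = n // 2
    tab = pd.DataFrame(
        {
            "r_protein": [f"RP{i:02d}" for i in range(n)],
            "length_aa": 200,
            "n_glyc_sites": [0] * half + [120] * (n - half),
            "o_glyc_sites": 0,
            "disulfide_bonds": 0,
            "gpi_anchor": 0,
        }
    )
    enz = pd.Series(np.tile([-1.0, 1.0], n // 2 + 1)[:n], index=tab["r_protein"])
    titers = simulate.generate_titers(tab, enz, truth, seed=seed)
    return pd.DataFrame(
        {
            "lfc_titer": titers.attrs["lfc"],
            "ptm_index": simulate.glycosylation_index(tab).reindex(enz.index),
            "enzyme_expr": enz,
        }
    )


class TestPTMIndex:
    @pytest.mark.parametrize(
        "row,ptype,expect",
        [
            (_row(400, 4, 0), "glycosylation", 0.01),
            (_row(400, 0, 0), "glycosylation", 0.0),
            (_row(160, 2, 2), "glycosylation", 0.025),
            (_row(200, ss=10), "disulfide", 0.05),
            (_row(100, gpi=1), "gpi", 0.01),
        ],
    )
    def test_sites_per_residue(self, row, ptype, expect):
        assert ptm.ptm_index(row, ptype) == pytest.approx(expect)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="ptm_type"):
            ptm.ptm_index(_row(), "phosphorylation")

    def test_scales_inversely_with_length(self):
        assert ptm.ptm_index(_row(200, 4), "glycosylation") == pytest.approx(
            2 * ptm.ptm_index(_row(400, 4), "glycosylation")
        )


class TestEnzymeExpressionScore:
    def test_enzymes_at_top_score_near_one(self, rng):
        metric = np.sort(rng.normal(0, 1, 1000))[::-1]
        ranked = pd.Series(metric, index=[f"g{i:04d}" for i in range(1000)])
        enz = set(ranked.index[rng.choice(25, 20, replace=False)])
        assert ptm.enzyme_expression_score(ranked, enz) >= 0.8

    def test_scattered_enzymes_score_small(self, rng):
        # permutation band for |ES| at N=1000, set size 20, weight 1:
        # 95th percentile ~0.45 (unweighted running sums are tighter, ~0.3)
        metric = np.sort(rng.normal(0, 1, 1000))[::-1]
        ranked = pd.Series(metric, index=[f"g{i:04d}" for i in range(1000)])
        scores = []
        for _ in range(100):
            enz = set(rng.choice(ranked.index.to_numpy(), 20, replace=False))
            scores.append(abs(ptm.enzyme_expression_score(ranked, enz)))
        assert np.mean(np.array(scores) <= 0.5) >= 0.95
        assert np.median(scores) <= 0.35

    def test_delegates_to_single_es_definition(self, rng):
        metric = np.sort(rng.normal(0, 1, 200))[::-1]
        ranked = pd.Series(metric, index=[f"g{i}" for i in range(200)])
        enz = set(ranked.index[5:25])
        assert ptm.enzyme_expression_score(ranked, enz) == enrichment.enrichment_score(
            ranked, enz, weight_p=1.0
        )

    def test_empty_intersection_names_rprotein(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="RPX"):
            ptm.enzyme_expression_score(ranked, {"zz"}, r_protein="RPX")


class TestSampler:
    def test_seeded_determinism(self):
        data = _balanced_data(n=10)
        kw = dict(n_warmup=200, n_draws=300, seed=5)
        p1 = ptm.fit_bayesian_interaction(data, mcmc=kw)
        p2 = ptm.fit_bayesian_interaction(data, mcmc=kw)
        pd.testing.assert_frame_equal(p1.draws, p2.draws)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            ptm.fit_bayesian_interaction(_balanced_data(n=4))

    def test_nonfinite_inputs_rejected(self):
        data = _balanced_data(n=8)
        data.loc[data.index[0], "lfc_titer"] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ptm.fit_bayesian_interaction(data)

    def test_zero_variance_predictor_warns(self):
        data = _balanced_data(n=8)
        data["ptm_index"] = 0.1
        with pytest.warns(UserWarning, match="zero-variance"):
            ptm.fit_bayesian_interaction(
                data, mcmc={"n_warmup": 100, "n_draws": 150, "seed": 0}
            )

    def test_sigma_fixed_posterior_matches_gaussian_closed_form(self):
        """With sigma held fixed the coefficient posterior is Gaussian; the
        sampler must agree with the conjugate closed form within 3 MC-SE."""
        data = _balanced_data(n=30, seed=3)
        est = BayesianInteractionRegression(
            sigma_fixed=0.1, n_warmup=1000, n_draws=2000, n_chains=2, seed=7
        ).fit(data[["ptm_index", "enzyme_expr"]], data["lfc_titer"])
        D = est.X_design_
        y = data["lfc_titer"].to_numpy()
        prec = np.diag([1.0, 16.0, 16.0, 16.0]) + D.T @ D / 0.01
        cf_mean = np.linalg.solve(prec, D.T @ y / 0.01)
        draws = est.posterior_.draws[["a", "b_ptm", "b_enz", "b_int"]]
        n_eff = len(draws) / 10.0  # conservative for a random-walk chain
        for j, name in enumerate(draws.columns):
            mcse = draws[name].std() / np.sqrt(n_eff)
            assert abs(draws[name].mean() - cf_mean[j]) < 3 * mcse

    def test_prior_dominance_with_uninformative_design(self):
        """Near-zero predictors and fixed noise leave the slope posteriors at
        their Normal(0, 0.25) prior."""
        rng = np.random.default_rng(0)
        data = pd.DataFrame(
            {
                "lfc_titer": np.zeros(5),
                "ptm_index": rng.uniform(0, 1e-4, 5),
                "enzyme_expr": rng.uniform(-1e-4, 1e-4, 5),
            }
        )
        post = ptm.fit_bayesian_interaction(
            data,
            mcmc={"sigma_fixed": 1.0, "n_warmup": 1500, "n_draws": 4000, "seed": 2},
        )
        for name in ("b_ptm", "b_enz", "b_int"):
            d = post.draws[name]
            mcse = d.std() / np.sqrt(len(d) / 10.0)
            assert abs(d.mean()) < 2 * mcse + 0.02
            assert d.std() == pytest.approx(0.25, rel=0.2)

    def test_posterior_contracts_with_sample_size(self):
        widths = {n: [] for n in (10, 50, 200)}
        for seed in range(20):
            for n in widths:
                data = _balanced_data(n=n, seed=seed)
                post = ptm.fit_bayesian_interaction(
                    data, mcmc={"n_warmup": 300, "n_draws": 400, "seed": seed}
                )
                q = np.quantile(post.draws["b_int"], [0.025, 0.975])
                widths[n].append(q[1] - q[0])
        means = {n: np.mean(w) for n, w in widths.items()}
        assert means[10] > means[50] > means[200]


class TestSummaries:
    def _degenerate_post(self, values):
        draws = pd.DataFrame(
            np.tile(values, (50, 1)), columns=list(ptm.PARAM_NAMES)
        )
        return ptm.RegressionPosterior(draws=draws, acceptance_rate=1.0, seed=0,
                                       rhat={}, n_chains=1)

    def test_degenerate_draws(self):
        post = self._degenerate_post([1.0, 2.0, 3.0, 4.0, 0.5])
        s = ptm.posterior_summary(post)
        assert s.loc["b_enz", "mean"] == 3.0
        assert s.loc["b_enz", "sd"] == 0.0
        assert s.loc["b_enz", "q2.5"] == s.loc["b_enz", "q97.5"] == 3.0

    def test_symmetric_draws_give_half_probability(self, rng):
        draws = pd.DataFrame(
            rng.normal(0, 1, (20000, 5)), columns=list(ptm.PARAM_NAMES)
        )
        post = ptm.RegressionPosterior(draws=draws, acceptance_rate=1.0, seed=0,
                                       rhat={}, n_chains=1)
        s = ptm.posterior_summary(post)
        assert s.loc["b_int", "p_gt_0"] == pytest.approx(0.5, abs=0.02)
        assert s.loc["b_int", "q2.5"] == pytest.approx(-1.96, abs=0.07)
        assert s.loc["b_int", "q97.5"] == pytest.approx(1.96, abs=0.07)

    def test_conditional_slope_algebra(self):
        post = self._degenerate_post([0.0, 0.0, -0.5, 1.0, 0.1])
        curve = ptm.conditional_effect_curve(post, [0.0, 0.5, 1.0])
        assert curve.loc[0.0, "slope_mean"] == pytest.approx(-0.5)
        assert curve.loc[0.5, "slope_mean"] == pytest.approx(0.0)
        assert curve.loc[1.0, "slope_mean"] == pytest.approx(0.5)
        assert curve.attrs["sign_change_point_mean"] == pytest.approx(0.5)

    def test_slope_at_zero_equals_enzyme_coefficient_draws(self, rng):
        draws = pd.DataFrame(rng.normal(0, 1, (500, 5)), columns=list(ptm.PARAM_NAMES))
        post = ptm.RegressionPosterior(draws=draws, acceptance_rate=1.0, seed=0,
                                       rhat={}, n_chains=1)
        curve = ptm.conditional_effect_curve(post, [0.0])
        assert curve.loc[0.0, "slope_mean"] == pytest.approx(draws["b_enz"].mean())
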