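"""PTM-index scoring and the Bayesian interaction model of titer improvement.

Each r-protein's PTM index is the number of occurrences of a modification
type divided by its amino-acid length (sites per residue).  The expression of
the enzymes responsible for a PTM is summarized per r-protein as the running-
sum enrichment score of the enzyme gene set within a ranked list of
between-host expression changes.  The two are linked to the log2 titer
improvement from CHO to HEK293 by a Bayesian linear regression with an
interaction term,

    LFC_titer[i] ~ Normal(mu[i], sigma)
    mu[i] = a + b_ptm * PTM[i] + b_enz * Enz[i] + b_int * PTM[i] * Enz[i]

with priors a ~ Normal(0, 1), b_* ~ Normal(0, 0.25), sigma ~ Exponential(rate),
sampled by adaptive random-walk Metropolis-within-Gibbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .enrichment import enrichment_score

PARAM_NAMES = ("a", "b_ptm", "b_enz", "b_int", "sigma")

__all__ = [
    "ptm_index",
    "enzyme_expression_score",
    "RegressionPosterior",
    "BayesianInteractionRegression",
    "fit_bayesian_interaction",
    "posterior_summary",
    "conditional_effect_curve",
]


def ptm_index(annotation_row, ptm_type: str) -> float:
    """Sites (or bonds/anchors) per residue for one r-protein.

    ``glycosylation`` counts N- plus O-linked sites; ``disulfide`` counts
    disulfide bonds (interchain included); ``gpi`` the 0/1 anchor flag.
    """
    row = annotation_row
    length = float(row["length_aa"])
    if length <= 0:
        raise ValueError("length_aa must be positive")
    if ptm_type == "glycosylation":
        total = float(row["n_glyc_sites"]) + float(row["o_glyc_sites"])
    elif ptm_type == "disulfide":
        total = float(row["disulfide_bonds"])
    elif ptm_type == "gpi":
        total = float(row["gpi_anchor"])
    else:
        raise ValueError(f"unknown ptm_type {ptm_type!r}")
    return total / length


def enzyme_expression_score(
    de_lfc_ranking: pd.Series, enzyme_set, r_protein: str = "", weight_p: float = 1.0
) -> float:
    """Summarize a PTM-enzyme gene set's expression change as a running-sum ES.

    ``de_lfc_ranking`` is a descending gene -> LFC ranking for one r-protein;
    delegates to the repo-wide enrichment-score definition.
    """
    try:
        return enrichment_score(de_lfc_ranking, enzyme_set, weight_p=weight_p)
    except ValueError as exc:
        if "intersect" in str(exc):
            raise ValueError(
                f"enzyme set does not intersect the ranking for r-protein {r_protein!r}"
            ) from exc
        raise


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class RegressionPosterior:
    """Posterior draws of (a, b_ptm, b_enz, b_int, sigma) plus diagnostics."""

    draws: pd.DataFrame            # (chains * n_draws) x 5
    acceptance_rate: float
    seed: int
    rhat: dict                     # split-Rhat per parameter
    n_chains: int


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat over (C, n) chains: each chain halved, standard formula."""
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.extend([c[:h], c[h : 2 * h]])
    x = np.asarray(halves, dtype=float)
    m, n = x.shape
    means = x.mean(axis=1)
    B = n * means.var(ddof=1)
    W = x.var(axis=1, ddof=1).mean()
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


class BayesianInteractionRegression(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator for the titer-improvement interaction model.

    Parameters
    ----------
    a_sd, b_sd : prior standard deviations of the intercept and slopes.
    sigma_rate : rate of the exponential prior on the residual sd.
    sigma_fixed : if given, sigma is held at this value (the conditional
        posterior of the coefficients is then Gaussian in closed form, used
        as an oracle in validation).
    n_warmup, n_draws : warmup and retained iterations per chain.
    n_chains : independent chains (draws are concatenated).
    standardize : center/scale predictors before fitting (off by default:
        the priors are interpreted on the raw scale).
    """

    def __init__(self, a_sd=1.0, b_sd=0.25, sigma_rate=1.0, sigma_fixed=None,
                 n_warmup=1000, n_draws=2000, n_chains=2, seed=0,
                 standardize=False):
        self.a_sd = a_sd
        self.b_sd = b_sd
        self.sigma_rate = sigma_rate
        self.sigma_fixed = sigma_fixed
        self.n_warmup = n_warmup
        self.n_draws = n_draws
        self.n_chains = n_chains
        self.seed = seed
        self.standardize = standardize

    # -- internals ---------------------------------------------------------

    def _design(self, ptm: np.ndarray, enz: np.ndarray) -> np.ndarray:
        if self.standardize:
            ptm = (ptm - ptm.mean()) / (ptm.std() or 1.0)
            enz = (enz - enz.mean()) / (enz.std() or 1.0)
        return np.column_stack([np.ones_like(ptm), ptm, enz, ptm * enz])

    def fit(self, X, y):
        """X: DataFrame with columns ptm_index, enzyme_expr (or (n,2) array);
        y: per-r-protein log2 titer changes."""
        if isinstance(X, pd.DataFrame):
            ptm = X["ptm_index"].to_numpy(dtype=float)
            enz = X["enzyme_expr"].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            ptm, enz = arr[:, 0], arr[:, 1]
        y = np.asarray(y, dtype=float)
        if not (np.isfinite(ptm).all() and np.isfinite(enz).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in regression inputs")
        if len(y) < 5:
            raise ValueError("need at least 5 r-proteins")
        if np.ptp(ptm) == 0 or np.ptp(enz) == 0:
            import warnings

            warnings.warn("zero-variance predictor: interaction is not identifiable")
        D = self._design(ptm, enz)
        self.posterior_ = self._sample(D, y)
        self.X_design_ = D
        return self

    def _log_post(self, beta, log_sigma, D, y):
        sigma = np.exp(log_sigma)
        r = y - D @ beta
        ll = -0.5 * np.sum(r**2) / sigma**2 - len(y) * log_sigma
        prior_sd = np.array([self.a_sd, self.b_sd, self.b_sd, self.b_sd])
        lp = -0.5 * np.sum((beta / prior_sd) ** 2)
        # exponential prior on sigma plus log-Jacobian of the log transform
        lp += -self.sigma_rate * sigma + log_sigma
        return ll + lp

    def _sample(self, D, y) -> RegressionPosterior:
        n_params = 4 + (self.sigma_fixed is None)
        chains = np.empty((self.n_chains, self.n_draws, 5))
        acc_total = 0
        prop_total = 0
        rng_root = np.random.default_rng(self.seed)
        chain_seeds = rng_root.integers(0, 2**31 - 1, size=self.n_chains)
        for c in range(self.n_chains):
            rng = np.random.default_rng(chain_seeds[c])
            beta = rng.normal(0.0, 0.1, size=4)
            log_sigma = (
                np.log(self.sigma_fixed) if self.sigma_fixed is not None
                else float(rng.normal(-1.0, 0.3))
            )
            steps = np.full(n_params, 0.1)
            acc_win = np.zeros(n_params)
            n_win = 0
            lp = self._log_post(beta, log_sigma, D, y)
            total = self.n_warmup + self.n_draws
            for it in range(total):
                for j in range(n_params):
                    if j < 4:
                        prop = beta.copy()
                        prop[j] += rng.normal(0.0, steps[j])
                        lp_new = self._log_post(prop, log_sigma, D, y)
                        if np.log(rng.random()) < lp_new - lp:
                            beta, lp = prop, lp_new
                            acc_win[j] += 1
                    else:
                        prop_ls = log_sigma + rng.normal(0.0, steps[j])
                        lp_new = self._log_post(beta, prop_ls, D, y)
                        if np.log(rng.random()) < lp_new - lp:
                            log_sigma, lp = prop_ls, lp_new
                            acc_win[j] += 1
                    if it >= self.n_warmup:
                        prop_total += 1
                n_win += 1
                if it < self.n_warmup and n_win == 50:
                    rate = acc_win / n_win
                    steps[rate < 0.30] *= 0.7
                    steps[rate > 0.45] *= 1.3
                    acc_win[:] = 0.0
                    n_win = 0
                elif it == self.n_warmup - 1:
                    acc_win[:] = 0.0
                    n_win = 0
                if it >= self.n_warmup:
                    chains[c, it - self.n_warmup, :4] = beta
                    chains[c, it - self.n_warmup, 4] = np.exp(log_sigma)
            acc_total += acc_win.sum()
        acceptance = float(acc_total / prop_total) if prop_total else 0.0
        rhat = {}
        for i, name in enumerate(PARAM_NAMES):
            if name == "sigma" and self.sigma_fixed is not None:
                rhat[name] = 1.0
                continue
            rhat[name] = _split_rhat(chains[:, :, i])
        if any(r > 1.05 for r in rhat.values()):
            import warnings

            warnings.warn(f"MCMC convergence warning: split-Rhat {rhat}")
        draws = pd.DataFrame(chains.reshape(-1, 5), columns=list(PARAM_NAMES))
        return RegressionPosterior(
            draws=draws, acceptance_rate=acceptance, seed=self.seed,
            rhat=rhat, n_chains=self.n_chains,
        )

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            ptm = X["ptm_index"].to_numpy(dtype=float)
            enz = X["enzyme_expr"].to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            ptm, enz = arr[:, 0], arr[:, 1]
        D = self._design(ptm, enz)
        mean = self.posterior_.draws[["a", "b_ptm", "b_enz", "b_int"]].mean().to_numpy()
        return D @ mean


def fit_bayesian_interaction(
    data: pd.DataFrame,
    priors: dict = None,
    mcmc: dict = None,
) -> RegressionPosterior:
    """Fit the titer-improvement interaction model.

    ``data`` needs columns ``lfc_titer``, ``ptm_index``, ``enzyme_expr``.
    ``priors`` may override ``a_sd`` (default 1), ``b_sd`` (default 0.25) and
    ``sigma_rate`` (default 1); ``mcmc`` may override ``n_warmup``,
    ``n_draws``, ``n_chains``, ``seed`` and ``sigma_fixed``.
    """
    priors = priors or {}
    mcmc = mcmc or {}
    est = BayesianInteractionRegression(
        a_sd=priors.get("a_sd", 1.0),
        b_sd=priors.get("b_sd", 0.25),
        sigma_rate=priors.get("sigma_rate", 1.0),
        sigma_fixed=mcmc.get("sigma_fixed"),
        n_warmup=mcmc.get("n_warmup", 1000),
        n_draws=mcmc.get("n_draws", 2000),
        n_chains=mcmc.get("n_chains", 2),
        seed=mcmc.get("seed", 0),
        standardize=mcmc.get("standardize", False),
    )
    est.fit(data[["ptm_index", "enzyme_expr"]], data["lfc_titer"])
    return est.posterior_


def posterior_summary(post: RegressionPosterior) -> pd.DataFrame:
    """Mean, sd, central 89%/95% intervals and P(>0) per parameter."""
    rows = {}
    for name in PARAM_NAMES:
        d = post.draws[name].to_numpy()
        rows[name] = {
            "mean": d.mean(),
            "sd": d.std(ddof=0),
            "q5.5": np.quantile(d, 0.055),
            "q94.5": np.quantile(d, 0.945),
            "q2.5": np.quantile(d, 0.025),
            "q97.5": np.quantile(d, 0.975),
            "p_gt_0": float(np.mean(d > 0)),
        }
    return pd.DataFrame(rows).T


def conditional_effect_curve(post: RegressionPosterior, ptm_index_values) -> pd.DataFrame:
    """Posterior slope of titer LFC on enzyme expression at given PTM indices.

    At PTM index v the slope is ``b_enz + b_int * v`` per draw; the sign-flip
    point is ``-b_enz / b_int`` for draws with nonzero interaction.
    """
    b_enz = post.draws["b_enz"].to_numpy()
    b_int = post.draws["b_int"].to_numpy()
    rows = []
    for v in ptm_index_values:
        slopes = b_enz + b_int * v
        rows.append(
            {
                "ptm_index": v,
                "slope_mean": slopes.mean(),
                "slope_q2.5": np.quantile(slopes, 0.025),
                "slope_q97.5": np.quantile(slopes, 0.975),
                "p_slope_gt_0": float(np.mean(slopes > 0)),
            }
        )
    out = pd.DataFrame(rows).set_index("ptm_index")
    nz = b_int != 0
    if nz.any():
        out.attrs["sign_change_point_mean"] = float(np.mean(-b_enz[nz] / b_int[nz]))
    return out
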