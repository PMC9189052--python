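"""Negative-binomial differential-expression engine.

Implements the standard bulk RNA-seq testing stack on a gene x sample count
matrix: median-of-ratios size factors, gene-wise method-of-moments dispersion
estimates shrunk toward a parametric trend ``alpha(mu) = a0 + a1/mu``, an IRLS
negative-binomial GLM with Wald tests against arbitrary contrasts, empirical
normal-prior shrinkage of log2 fold changes, and a closed-form
variance-stabilizing transformation (VST).

The NB model is parameterized by mean and dispersion, ``Var = mu + alpha mu^2``.
All fold changes are reported in log2 units.  A pseudocount of 1 is applied
only to descriptive log2 fold changes of normalized counts, never inside the
GLM likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
MIN_DISPERSION = 1e-8

__all__ = [
    "DesignSpec",
    "aggregate_transcripts",
    "aggregate_orthologs",
    "estimate_size_factors",
    "estimate_dispersions",
    "DispersionFit",
    "fit_glm",
    "wald_test",
    "fit_and_test",
    "shrink_lfc",
    "differential_activation",
    "vst",
    "NegativeBinomialDE",
    "VarianceStabilizingTransformer",
]


# ---------------------------------------------------------------------------
# count aggregation
# ---------------------------------------------------------------------------

def aggregate_transcripts(tx_abundance: pd.DataFrame, tx2gene) -> pd.DataFrame:
    """Sum transcript-level estimated counts into gene-level integer counts.

    Parameters
    ----------
    tx_abundance : DataFrame, transcripts x samples, estimated (float) counts.
    tx2gene : mapping transcript id -> gene id (dict or Series).

    Gene counts are the sum of member transcript counts rounded to the
    nearest integer.  Every transcript must be mapped to exactly one gene.
    """
    tx2gene = pd.Series(dict(tx2gene) if not isinstance(tx2gene, pd.Series) else tx2gene)
    unmapped = tx_abundance.index.difference(tx2gene.index)
    if len(unmapped):
        raise ValueError(f"unmapped transcripts: {sorted(unmapped)}")
    genes = tx2gene.reindex(tx_abundance.index)
    out = tx_abundance.groupby(genes.to_numpy()).sum()
    out = pd.DataFrame(
        np.rint(out.to_numpy()).astype(np.int64), index=out.index, columns=out.columns
    )
    out.index.name = "gene_id"
    return out


def aggregate_orthologs(
    counts: pd.DataFrame, ortholog_map: pd.DataFrame, policy: str = "sum"
) -> pd.DataFrame:
    """Convert a count matrix from source gene ids to ortholog target ids.

    ``ortholog_map`` has two columns (source id, target id).  Source genes
    with no mapping are dropped (logged).  Under policy ``"sum"``, several
    sources mapping to one target are summed and any source gene with more
    than one target is dropped; under ``"drop_ambiguous"`` every gene touching
    a non-1:1 relation is removed.
    """
    if policy not in ("sum", "drop_ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    omap = ortholog_map.iloc[:, :2].drop_duplicates()
    omap.columns = ["source", "target"]
    omap = omap[omap["source"].isin(counts.index)]
    if omap.empty:
        raise ValueError("ortholog map has no genes in common with the count matrix")

    src_multi = omap["source"].duplicated(keep=False)  # one source -> many targets
    tgt_multi = omap["target"].duplicated(keep=False)  # many sources -> one target
    if policy == "sum":
        keep = ~src_multi
    else:
        keep = ~(src_multi | tgt_multi)
    dropped_ambiguous = omap.loc[~keep, "source"].nunique()
    omap = omap[keep]
    n_unmapped = counts.shape[0] - omap["source"].nunique()
    if n_unmapped or dropped_ambiguous:
        logger.info(
            "ortholog conversion: %d unmapped source genes dropped, "
            "%d ambiguous source genes dropped (policy=%s)",
            n_unmapped, dropped_ambiguous, policy,
        )
    sub = counts.loc[omap["source"]]
    out = sub.groupby(omap["target"].to_numpy()).sum()
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each gene expressed in every sample, the ratio of its count to its
    across-sample geometric mean is formed; a sample's factor is the median
    of these ratios.
    """
    arr = np.asarray(counts, dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; median-of-ratios is "
            "undefined (consider a pseudo-reference fallback)"
        )
    logc = np.log(arr[all_pos])
    log_geo = logc.mean(axis=1)
    sf = np.exp(np.median(logc - log_geo[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Per-gene dispersion estimates and the fitted parametric trend."""

    genewise: pd.Series
    trend: tuple[float, float]          # (a0, a1) in alpha(mu) = a0 + a1/mu
    shrunk: pd.Series
    prior_var: float
    base_mean: pd.Series

    def trend_at(self, mu) -> np.ndarray:
        a0, a1 = self.trend
        mu = np.maximum(np.asarray(mu, dtype=float), 1e-8)
        return a0 + a1 / mu


def _pooled_within_group_variance(q: np.ndarray, groups: np.ndarray):
    """Pooled within-group sample variance per gene and residual df."""
    m = q.shape[1]
    labels = pd.unique(groups)
    ss = np.zeros(q.shape[0])
    df = 0
    for lab in labels:
        idx = groups == lab
        n = int(idx.sum())
        if n < 2:
            continue
        sub = q[:, idx]
        ss += sub.var(axis=1, ddof=1) * (n - 1)
        df += n - 1
    if df == 0:
        raise ValueError("dispersion estimation needs >=2 replicates in >=1 condition")
    return ss / df, m - df  # variance, number of fitted group means


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by iteratively reweighted least squares.

    Gamma-GLM-style weights (1/fitted^2) with iterative exclusion of genes
    whose ratio to the trend is extreme, as is standard for dispersion-trend
    fitting on RNA-seq data.
    """
    use = (alpha > 10 * MIN_DISPERSION) & (mu > 0.5) & np.isfinite(alpha)
    if use.sum() < 10:
        # too few informative genes: fall back to a flat trend at the median
        a0 = float(max(np.median(alpha[np.isfinite(alpha)]), MIN_DISPERSION))
        return a0, 1e-8
    x, y = 1.0 / mu[use], alpha[use]
    keep = np.ones(x.size, dtype=bool)
    a0, a1 = float(np.median(y)), 0.0
    for _ in range(12):
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        fitted0 = np.maximum(a0 + a1 * x[keep], 1e-10)
        w = 1.0 / fitted0**2
        coef, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], y[keep] * np.sqrt(w), rcond=None)
        new_a0 = max(float(coef[0]), MIN_DISPERSION)
        new_a1 = max(float(coef[1]), 0.0)
        if abs(new_a0 - a0) < 1e-8 and abs(new_a1 - a1) < 1e-8:
            a0, a1 = new_a0, new_a1
            break
        a0, a1 = new_a0, new_a1
        ratio = y / np.maximum(a0 + a1 * x, 1e-10)
        keep = (ratio > 1e-4) & (ratio < 15.0)
        if keep.sum() < 10:
            break
    return a0, a1


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    groups=None,
) -> DispersionFit:
    """Gene-wise NB dispersions with trend fitting and empirical-Bayes shrinkage.

    Method of moments on normalized counts gives gene-wise estimates
    ``alpha = (var - mu * xi) / mu^2`` with ``xi = mean(1/size_factor)``
    (the Poisson component of the variance of a scaled count).  A parametric
    trend ``a0 + a1/mu`` is fit through the estimates, and log dispersions are
    shrunk toward the trend with a prior variance estimated from the spread of
    residuals in excess of the expected sampling variance.

    Parameters
    ----------
    groups : optional per-sample labels; variances are pooled within groups
        so condition effects do not inflate dispersion estimates.
    """
    arr = np.asarray(counts, dtype=float)
    if not (arr.sum(axis=1) > 0).any():
        raise ValueError("all genes have zero counts")
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    q = arr / sf
    xi = float(np.mean(1.0 / sf))
    mu = q.mean(axis=1)

    if groups is None:
        groups = np.zeros(arr.shape[1], dtype=int)
    else:
        groups = np.asarray(groups)
    v, n_params = _pooled_within_group_variance(q, groups)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (v - mu * xi) / mu**2
    alpha_mom = np.where(mu > 0, alpha_mom, np.nan)
    alpha_mom = np.where(np.isfinite(alpha_mom), alpha_mom, MIN_DISPERSION)
    floored = alpha_mom <= MIN_DISPERSION
    alpha_mom = np.maximum(alpha_mom, MIN_DISPERSION)

    a0, a1 = _fit_dispersion_trend(mu, alpha_mom)
    trend_val = a0 + a1 / np.maximum(mu, 1e-8)

    # sampling variance of a log dispersion estimate at m samples, p fitted means
    m = arr.shape[1]
    df = max(m - n_params, 1)
    samp_var = float(special.polygamma(1, df / 2.0))
    informative = ~floored & (mu > 0.5)
    if informative.sum() >= 10:
        resid = np.log(alpha_mom[informative]) - np.log(trend_val[informative])
        prior_var = max(float(np.var(resid)) - samp_var, 0.0625)
    else:
        prior_var = 0.0625

    w_data = 1.0 / samp_var
    w_prior = 1.0 / prior_var
    log_shrunk = (w_data * np.log(alpha_mom) + w_prior * np.log(trend_val)) / (
        w_data + w_prior
    )
    shrunk = np.exp(log_shrunk)
    # genes whose moment estimate hit the floor carry no usable gene-wise
    # signal; they take the trend value rather than being dragged to the floor
    shrunk = np.where(floored, trend_val, shrunk)
    shrunk = np.maximum(shrunk, MIN_DISPERSION)

    idx = counts.index
    return DispersionFit(
        genewise=pd.Series(alpha_mom, index=idx, name="dispersion_genewise"),
        trend=(a0, a1),
        shrunk=pd.Series(shrunk, index=idx, name="dispersion"),
        prior_var=prior_var,
        base_mean=pd.Series(mu, index=idx, name="baseMean"),
    )


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Model-matrix specification over a sample table.

    ``factors`` are columns of the sample table entering as treatment-coded
    main effects (reference level dropped).  ``interaction_cellline_rprotein``
    builds the producer-indicator parameterization used for differential
    activation across hosts: one producer dummy per r-protein (its
    coefficient is the within-reference-cell-line activation for that
    r-protein) plus one cell_line x r-protein column per r-protein (its
    coefficient is the activation difference between cell lines).
    """

    factors: list = field(default_factory=list)
    interaction_cellline_rprotein: bool = False
    reference: dict = field(default_factory=dict)

    def build(self, sample_table: pd.DataFrame) -> pd.DataFrame:
        st = sample_table
        cols = {"Intercept": np.ones(len(st))}
        for f in self.factors:
            levels = sorted(st[f].astype(str).unique())
            ref = self.reference.get(f, levels[0])
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{f}_{lev}"] = (st[f].astype(str) == lev).to_numpy(float)
        if self.interaction_cellline_rprotein:
            cl_levels = sorted(st["cell_line"].astype(str).unique())
            ref_cl = self.reference.get("cell_line", cl_levels[0])
            alt = [c for c in cl_levels if c != ref_cl]
            producers = st["condition"].astype(str) == "producer"
            for rp in sorted(st.loc[producers, "r_protein"].astype(str).unique()):
                is_rp = (producers & (st["r_protein"].astype(str) == rp)).to_numpy(float)
                cols[f"producer_{rp}"] = is_rp
                for cl in alt:
                    cols[f"act_diff_{cl}:{rp}"] = is_rp * (
                        st["cell_line"].astype(str) == cl
                    ).to_numpy(float)
        X = pd.DataFrame(cols, index=st.index)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design matrix is not full rank on these samples")
        return X


# ---------------------------------------------------------------------------
# GLM fitting and Wald testing
# ---------------------------------------------------------------------------

def _irls_nb(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-7,
    ridge: float = 1e-8,
):
    """Vectorized IRLS for NB log-link GLMs, one model per row of Y.

    Returns (beta (g,p), cov (g,p,p), converged (g,)).  ``offset`` holds
    log size factors.  The linear predictor (minus offset) is clamped to
    +-30 natural-log units for stability of genes with empty groups.
    Converged genes leave the active set, so the cost is dominated by the
    few slow genes only in late iterations.
    """
    g, m = Y.shape
    p = X.shape[1]
    # precompute the m x p^2 outer-product matrix so XtWX is one BLAS matmul
    XX = (X[:, :, None] * X[:, None, :]).reshape(m, p * p)
    # initialize from OLS on log normalized counts with half pseudocount
    z0 = np.log((Y + 0.5) / np.exp(offset)[None, :])
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    converged = np.zeros(g, dtype=bool)
    eye = ridge * np.eye(p)
    active = np.arange(g)
    for _ in range(max_iter):
        B = beta[active]
        lin = np.clip(B @ X.T, -30.0, 30.0)
        mu = np.maximum(np.exp(lin + offset[None, :]), 1e-10)
        W = mu / (1.0 + alpha[active, None] * mu)
        z = lin + (Y[active] - mu) / mu
        XtWX = (W @ XX).reshape(-1, p, p) + eye[None, :, :]
        XtWz = (W * z) @ X
        new_B = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(new_B - B).max(axis=1)
        beta[active] = new_B
        done = delta < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    lin = np.clip(beta @ X.T, -30.0, 30.0)
    mu = np.maximum(np.exp(lin + offset[None, :]), 1e-10)
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = (W @ XX).reshape(g, p, p) + eye[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def _resolve_contrast(contrast, columns) -> np.ndarray:
    if isinstance(contrast, str):
        if contrast not in columns:
            raise ValueError(f"contrast {contrast!r} not among coefficients {list(columns)}")
        c = np.zeros(len(columns))
        c[list(columns).index(contrast)] = 1.0
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (len(columns),):
        raise ValueError("contrast vector length does not match design columns")
    return c


@dataclass
class _GLMFit:
    """Cached per-gene GLM fit, reusable across contrasts."""

    design: pd.DataFrame
    gene_index: pd.Index
    nonzero: np.ndarray
    base_mean: np.ndarray
    beta: np.ndarray
    cov: np.ndarray
    converged: np.ndarray


def fit_glm(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    design: pd.DataFrame,
) -> _GLMFit:
    """Fit per-gene NB log-link GLMs by IRLS (all-zero genes skipped)."""
    X = design.reindex(counts.columns).to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank on these samples")
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    alpha = dispersions.reindex(counts.index).to_numpy(dtype=float)
    Y = np.asarray(counts, dtype=float)
    nonzero = Y.sum(axis=1) > 0
    base_mean = (Y / sf[None, :]).mean(axis=1)
    if nonzero.any():
        beta, cov, conv = _irls_nb(Y[nonzero], X, alpha[nonzero], np.log(sf))
        if (~conv).any():
            logger.warning(
                "%d gene fits did not converge; p set missing", int((~conv).sum())
            )
    else:
        p = X.shape[1]
        beta = np.zeros((0, p)); cov = np.zeros((0, p, p)); conv = np.zeros(0, bool)
    return _GLMFit(
        design=design, gene_index=counts.index, nonzero=nonzero,
        base_mean=base_mean, beta=beta, cov=cov, converged=conv,
    )


def wald_test(fit: _GLMFit, contrast) -> pd.DataFrame:
    """Wald test of a contrast on a cached GLM fit (BH-adjusted)."""
    c = _resolve_contrast(contrast, fit.design.columns)
    res = pd.DataFrame(
        {
            "baseMean": fit.base_mean,
            "lfc_raw": np.nan,
            "lfc_shrunk": np.nan,
            "se": np.nan,
            "stat": np.nan,
            "pvalue": np.nan,
            "padj": np.nan,
        },
        index=fit.gene_index,
    )
    nonzero = fit.nonzero
    if nonzero.any():
        est = fit.beta @ c
        var = np.einsum("p,gpq,q->g", c, fit.cov, c)
        se = np.sqrt(np.maximum(var, 0.0))
        stat = np.where(se > 0, est / se, 0.0)
        pval = 2.0 * stats.norm.sf(np.abs(stat))
        pval = np.where(fit.converged, pval, np.nan)
        res.loc[nonzero, "lfc_raw"] = est / LN2
        res.loc[nonzero, "se"] = se / LN2
        res.loc[nonzero, "stat"] = stat
        res.loc[nonzero, "pvalue"] = pval
    tested = res["pvalue"].notna()
    if tested.any():
        res.loc[tested, "padj"] = multipletests(
            res.loc[tested, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    res.attrs["contrast"] = contrast if isinstance(contrast, str) else list(map(float, c))
    res.attrs["pseudocount_policy"] = (
        "pseudocount of 1 applies only to descriptive log2 fold changes of "
        "normalized counts, never inside the GLM"
    )
    res.attrs["excluded_simplifications"] = (
        "no Cook's-distance outlier replacement; no independent-filtering optimization"
    )
    return res


def fit_and_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    design: pd.DataFrame,
    contrast,
) -> pd.DataFrame:
    """Fit per-gene NB GLMs and Wald-test one contrast.

    Convenience wrapper over :func:`fit_glm` and :func:`wald_test`; use those
    directly to test several contrasts on one fit.  Returns a DataFrame
    indexed by gene with columns ``baseMean``, ``lfc_raw`` (log2),
    ``lfc_shrunk`` (NaN until :func:`shrink_lfc`), ``se`` (log2), ``stat``,
    ``pvalue``, ``padj``.  Genes with all-zero counts or non-converged fits
    get missing p-values and are excluded from the BH denominator.
    """
    fit = fit_glm(counts, size_factors, dispersions, design)
    return wald_test(fit, contrast)


def shrink_lfc(de: pd.DataFrame, prior_sd_grid=None) -> pd.DataFrame:
    """Shrink raw log2 fold changes toward zero under a normal prior.

    The prior standard deviation is chosen by maximizing the marginal
    likelihood of the observed LFCs (``lfc_raw ~ N(0, s^2 + se^2)``) over a
    grid; the posterior mode under a zero-centered normal prior with known
    observation variance is the precision-weighted estimate
    ``lfc * s^2 / (s^2 + se^2)``, so ``|lfc_shrunk| <= |lfc_raw|`` always.
    """
    if prior_sd_grid is None:
        prior_sd_grid = np.logspace(np.log10(0.05), np.log10(8.0), 30)
    prior_sd_grid = np.asarray(prior_sd_grid, dtype=float)
    if prior_sd_grid.size == 0:
        raise ValueError("prior_sd_grid is empty")
    ok = de["lfc_raw"].notna() & de["se"].notna() & (de["se"] > 0)
    lfc = de.loc[ok, "lfc_raw"].to_numpy()
    se = de.loc[ok, "se"].to_numpy()
    tot_var = prior_sd_grid[:, None] ** 2 + se[None, :] ** 2
    marg = -0.5 * (np.log(2 * np.pi * tot_var) + lfc[None, :] ** 2 / tot_var).sum(axis=1)
    s2 = float(prior_sd_grid[int(np.argmax(marg))]) ** 2
    out = de.copy()
    out.loc[ok, "lfc_shrunk"] = lfc * s2 / (s2 + se**2)
    out.attrs.update(de.attrs)
    out.attrs["shrinkage_prior_sd"] = float(np.sqrt(s2))
    return out


def differential_activation(
    counts: pd.DataFrame, sample_table: pd.DataFrame, cell_line: str
) -> pd.DataFrame:
    """Producers vs empty-vector controls within one cell line.

    The shrunken LFC is the gene's "activation" upon transgene expression.
    """
    st = sample_table[sample_table["cell_line"].astype(str) == str(cell_line)]
    if st.empty:
        raise ValueError(f"no samples for cell line {cell_line!r}")
    conds = set(st["condition"].astype(str))
    if not {"producer", "control"} <= conds:
        raise ValueError(f"cell line {cell_line!r} lacks producer or control samples")
    sub = counts[st["sample_id"]]
    sf = estimate_size_factors(sub)
    disp = estimate_dispersions(sub, sf, groups=st["condition"].to_numpy())
    design = DesignSpec(factors=["condition"], reference={"condition": "control"}).build(
        st.set_index("sample_id")
    )
    res = fit_and_test(sub, sf, disp.shrunk, design, "condition_producer")
    return shrink_lfc(res)


# ---------------------------------------------------------------------------
# variance-stabilizing transformation
# ---------------------------------------------------------------------------

def vst(
    counts: pd.DataFrame, size_factors: pd.Series, dispersion_trend: tuple[float, float]
) -> pd.DataFrame:
    """Closed-form VST for NB counts under the trend ``alpha(mu)=a0+a1/mu``.

    Integrating ``1/sqrt(mu + alpha(mu) mu^2)`` gives, with ``b = 1 + a1``,

        v(q) = log2( (2 a0 q + b + 2 sqrt(a0 q (a0 q + b))) / b ) / sqrt(a0)

    applied to normalized counts ``q``.  The transform is monotone, zero at
    zero, and for large ``q`` differences approach log2 differences divided
    by ``sqrt(a0)``, so variance is approximately constant across the mean
    range.
    """
    a0, a1 = dispersion_trend
    if a0 <= 0:
        raise ValueError("dispersion trend asymptote a0 must be positive")
    sf = size_factors.reindex(counts.columns).to_numpy(dtype=float)
    q = np.asarray(counts, dtype=float) / sf[None, :]
    b = 1.0 + a1
    t = np.log((2 * a0 * q + b + 2 * np.sqrt(a0 * q * (a0 * q + b))) / b)
    out = t / (np.sqrt(a0) * LN2)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


# ---------------------------------------------------------------------------
# estimator facades
# ---------------------------------------------------------------------------

class VarianceStabilizingTransformer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying the NB VST to genes x samples counts.

    ``fit`` estimates size factors and the dispersion trend from the count
    matrix; ``transform`` applies the closed-form VST.  Note the matrix
    orientation follows the field convention (genes as rows).
    """

    def __init__(self, groups=None):
        self.groups = groups

    def fit(self, X: pd.DataFrame, y=None):
        X = _as_count_frame(X)
        self.size_factors_ = estimate_size_factors(X)
        fitres = estimate_dispersions(X, self.size_factors_, groups=self.groups)
        self.dispersion_trend_ = fitres.trend
        self.dispersion_fit_ = fitres
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "dispersion_trend_"):
            raise ValueError("transformer is not fitted")
        X = _as_count_frame(X)
        sf = self.size_factors_.reindex(X.columns)
        if sf.isna().any():
            sf = estimate_size_factors(X)
        return vst(X, sf, self.dispersion_trend_)


class NegativeBinomialDE(BaseEstimator):
    """Estimator facade over the NB GLM testing stack.

    ``fit(counts, sample_table)`` estimates size factors and dispersions and
    fits per-gene GLMs for the configured design; ``test(contrast)`` returns
    the Wald-test table (with shrunken LFCs when ``shrink=True``).
    """

    def __init__(self, design: DesignSpec = None, shrink: bool = True,
                 prior_sd_grid=None, dispersion_groups: str = None):
        self.design = design
        self.shrink = shrink
        self.prior_sd_grid = prior_sd_grid
        self.dispersion_groups = dispersion_groups

    def fit(self, X: pd.DataFrame, y: pd.DataFrame = None):
        """X: genes x samples counts; y: sample table with sample_id column."""
        if y is None:
            raise ValueError("a sample table is required")
        counts = _as_count_frame(X)
        st = y.set_index("sample_id") if "sample_id" in y.columns else y
        st = st.loc[counts.columns]
        self.sample_table_ = st
        self.size_factors_ = estimate_size_factors(counts)
        groups = None
        if self.dispersion_groups is not None:
            groups = st[self.dispersion_groups].to_numpy()
        self.dispersion_fit_ = estimate_dispersions(counts, self.size_factors_, groups=groups)
        self.dispersions_ = self.dispersion_fit_.shrunk
        spec = self.design if self.design is not None else DesignSpec(factors=["condition"])
        self.design_matrix_ = spec.build(st)
        self.glm_fit_ = fit_glm(counts, self.size_factors_, self.dispersions_,
                                self.design_matrix_)
        self.counts_ = counts
        return self

    def test(self, contrast) -> pd.DataFrame:
        if not hasattr(self, "glm_fit_"):
            raise ValueError("estimator is not fitted")
        res = wald_test(self.glm_fit_, contrast)
        if self.shrink:
            res = shrink_lfc(res, self.prior_sd_grid)
        return res


def _as_count_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X))
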