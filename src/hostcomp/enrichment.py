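"""Running-sum gene-set enrichment and hypergeometric over-representation.

The enrichment score (ES) of a gene set in a ranked list is the signed
maximum deviation of the classic running sum: hits increment by the
normalized ``|metric|^p`` weight, misses decrement by ``1/(N - K)``.  The
normalized score (NES) divides ES by the mean magnitude of same-sign null
scores from random same-size gene sets, with an accompanying permutation
p-value.  Over-representation of a set among a chosen subset uses the exact
hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "nes_and_pvalue",
    "hypergeometric_test",
    "rank_genes",
]


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p_perm: float
    n_permutations: int
    seed: int
    at_resolution_limit: bool = False  # no same-sign permutation was at least as extreme


def rank_genes(metric: pd.Series) -> pd.Series:
    """Sort a gene -> metric series descending, ties broken by gene id."""
    df = pd.DataFrame({"g": metric.index.astype(str), "m": metric.to_numpy(float)})
    df = df.sort_values(["m", "g"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["m"].to_numpy(), index=df["g"].to_numpy())


def _check_ranked(ranked: pd.Series) -> pd.Series:
    ranked = pd.Series(ranked)
    vals = ranked.to_numpy(dtype=float)
    if np.any(np.diff(vals) > 1e-12):
        raise ValueError("ranking metric must be sorted in descending order")
    return ranked


def enrichment_score(ranked: pd.Series, gene_set, weight_p: float = 1.0) -> float:
    """Signed maximum deviation of the running sum for one gene set.

    ``ranked`` is a Series (gene -> metric) sorted descending.  Hit
    increments are ``|metric|^weight_p`` normalized over in-set genes
    (equal weights if all in-set metrics are zero); misses decrement by
    ``1/(N - K)``.
    """
    if weight_p < 0:
        raise ValueError("weight_p must be >= 0")
    ranked = _check_ranked(ranked)
    genes = ranked.index
    hit = genes.isin(set(gene_set))
    n, k = len(genes), int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if k == n:
        raise ValueError("gene set equals the whole ranked list (miss step undefined)")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    w = np.where(hit, w, 0.0)
    total = w.sum()
    if total == 0:
        w = hit.astype(float)
        total = w.sum()
    step = w / total - (~hit).astype(float) / (n - k)
    running = np.cumsum(step)
    return float(running[int(np.argmax(np.abs(running)))])


def _null_es_batch(weights: np.ndarray, n: int, k: int, positions: np.ndarray) -> np.ndarray:
    """ES for many same-size random sets given their (B, k) sorted positions.

    The running sum is piecewise linear between hits, so its extremes occur
    just before and just after hits (plus the final value 0); this evaluates
    only those candidates, O(k) per set.
    """
    d = 1.0 / (n - k)
    w = weights[positions]                          # (B, k)
    tot = w.sum(axis=1, keepdims=True)
    zero = (tot == 0).ravel()
    if zero.any():
        w[zero] = 1.0
        tot = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / tot                # value contribution of hits
    i = np.arange(k)
    after = cum - d * (positions + 1 - (i + 1))     # value right after hit i
    before = np.concatenate(
        [np.zeros((positions.shape[0], 1)), cum[:, :-1]], axis=1
    ) - d * (positions - i)                          # value right before hit i
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    return np.where(hi >= -lo, hi, lo)


def nes_and_pvalue(
    ranked: pd.Series,
    gene_set,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    perm_mode: str = "gene_label",
    seed: int = 0,
    name: str = "",
) -> EnrichmentResult:
    """ES, NES and permutation p-value for one gene set.

    The null distribution comes from ``n_perm`` random gene sets of the same
    size (gene-label permutation).  NES = ES / mean(|null ES| of matching
    sign); p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign
    null).  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if perm_mode != "gene_label":
        raise ValueError(f"unsupported permutation mode {perm_mode!r}")
    ranked = _check_ranked(ranked)
    es = enrichment_score(ranked, gene_set, weight_p)
    n = len(ranked)
    k = int(ranked.index.isin(set(gene_set)).sum())
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.to_numpy(dtype=float)) ** weight_p
    positions = np.sort(
        rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)[:, :k], axis=1
    )
    null = _null_es_batch(weights, n, k, positions)

    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    flag = False
    if n_same == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
        flag = True
    else:
        denom = float(np.mean(np.abs(null[same_sign])))
        nes = es / denom if denom > 0 else np.nan
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1.0 + extreme) / (1.0 + n_same)
        flag = extreme == 0
    return EnrichmentResult(
        name=name, es=es, nes=float(nes), p_perm=float(p),
        n_permutations=n_perm, seed=seed, at_resolution_limit=flag,
    )


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))
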