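"""Secretory-pathway outlier discovery between expression hosts.

Compares per-gene mean variance-stabilized expression between CHO and HEK293,
classifies extreme genes into three groups relative to an identity band
(I: silent in CHO, high in HEK293; II: moderate in CHO, higher in HEK293;
III: higher in CHO), ranks genes by activation disparity between hosts, and
correlates per-r-protein differential activation with titer changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import hypergeometric_test

__all__ = [
    "classify_outlier_groups",
    "rank_activation_disparity",
    "top_set_enrichment",
    "activation_titer_correlation",
]


def classify_outlier_groups(
    vst_cho: pd.Series,
    vst_hek: pd.Series,
    band_halfwidth: float = 2.0,
    low_thresh: float = 2.0,
    high_thresh: float = 6.0,
) -> pd.DataFrame:
    """Classify genes by joint expression level in the two hosts.

    A gene is inside the identity band when ``|hek - cho| <= band_halfwidth``.
    Outside the band: group I if CHO is below ``low_thresh`` and HEK at or
    above ``high_thresh``; group II if CHO is moderate (between thresholds)
    and HEK exceeds it by more than the band; group III if CHO exceeds HEK by
    more than the band.  Thresholds are in the (log2-like) units of the VST.
    """
    if low_thresh >= high_thresh:
        raise ValueError("low_thresh must be strictly below high_thresh")
    if not vst_cho.index.equals(vst_hek.index):
        vst_hek = vst_hek.reindex(vst_cho.index)
        if vst_hek.isna().any():
            raise ValueError("gene sets differ between the two expression vectors")
    cho = vst_cho.to_numpy(dtype=float)
    hek = vst_hek.to_numpy(dtype=float)
    in_band = np.abs(hek - cho) <= band_halfwidth
    group = np.full(cho.shape, "none", dtype=object)
    gi = ~in_band & (cho < low_thresh) & (hek >= high_thresh)
    gii = ~in_band & ~gi & (cho >= low_thresh) & (cho < high_thresh) & (hek - cho > band_halfwidth)
    giii = ~in_band & (hek < cho - band_halfwidth)
    group[gi] = "I"
    group[gii] = "II"
    group[giii] = "III"
    return pd.DataFrame(
        {
            "vst_cho": cho,
            "vst_hek": hek,
            "in_identity_band": in_band,
            "group": group,
        },
        index=vst_cho.index,
    )


def rank_activation_disparity(
    act_cho: pd.DataFrame, act_hek: pd.DataFrame, top_k: int
) -> pd.DataFrame:
    """Top-k genes by absolute difference of activation LFCs between hosts.

    Activation is the shrunken producer-vs-control log2 fold change from each
    host's differential-activation fit.  Ties are broken by gene id, making
    the ranking deterministic.
    """
    shared = act_cho.index.intersection(act_hek.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between activation results")
    if top_k > len(shared):
        raise ValueError(f"top_k={top_k} exceeds the {len(shared)}-gene universe")
    lc = act_cho.loc[shared, "lfc_shrunk"].to_numpy(dtype=float)
    lh = act_hek.loc[shared, "lfc_shrunk"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "lfc_act_CHO": lc,
            "lfc_act_HEK": lh,
            "disparity": np.abs(lh - lc),
        },
        index=shared.astype(str),
    )
    order = np.lexsort((out.index.to_numpy(), -out["disparity"].to_numpy()))
    out = out.iloc[order].head(top_k).copy()
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_set_enrichment(top_genes, secretory_genes, universe) -> float:
    """Hypergeometric p for secretory genes among a chosen top list."""
    top, sec, uni = set(top_genes), set(secretory_genes), set(universe)
    if not top <= uni or not sec <= uni:
        raise ValueError("top and secretory sets must be subsets of the universe")
    return hypergeometric_test(
        k=len(top & sec), n=len(top), K=len(sec), N=len(uni)
    )


def activation_titer_correlation(
    act_diff: pd.DataFrame, titer_lfc: pd.Series
) -> pd.DataFrame:
    """Per-gene Pearson correlation of differential activation with titer LFC.

    ``act_diff`` is genes x r-proteins (the cell_line x r-protein interaction
    LFCs); ``titer_lfc`` is the per-r-protein log2 titer change.  Genes with a
    zero-variance activation vector have undefined correlation and are
    excluded from the ranking (returned with NaN, rank 0).
    """
    shared = [rp for rp in act_diff.columns if rp in titer_lfc.index]
    if len(shared) < 3:
        raise ValueError("need >=3 r-proteins with both activation and titer data")
    A = act_diff[shared].to_numpy(dtype=float)
    t = titer_lfc.reindex(shared).to_numpy(dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    tc = t - t.mean()
    denom = np.sqrt((Ac**2).sum(axis=1) * (tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Ac * tc).sum(axis=1) / denom, np.nan)
    out = pd.DataFrame({"r": r}, index=act_diff.index.astype(str))
    defined = out["r"].notna()
    order = np.lexsort(
        (out.index[defined].to_numpy(), -out.loc[defined, "r"].to_numpy())
    )
    ranked = out[defined].iloc[order].copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    undef = out[~defined].copy()
    undef["rank"] = 0
    return pd.concat([ranked, undef])
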