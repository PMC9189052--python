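"""Transcriptome-usage decomposition, QC fractions and titer fold changes.

The transcriptome usage of a sample is the fraction of its length-normalized
expression mass (TPM) falling in each functional group, optionally after
excluding the transgene; the mitochondrial fraction is a normalization QC;
titer fold changes use a +1 pseudocount so undetected proteins are
comparable.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tpm",
    "transcriptome_usage",
    "mito_fraction",
    "titer_log2fc",
    "classify_improved",
    "secretory_subgroup_means",
]


def compute_tpm(counts: pd.DataFrame, gene_lengths=None) -> pd.DataFrame:
    """Transcripts-per-million from counts and gene lengths (bases).

    TPM_g is proportional to count_g / length_g, scaled so each sample sums
    to 1e6.  When no lengths are given every gene defaults to 1 kb (logged),
    which makes TPM a pure library-size normalization.
    """
    if gene_lengths is None:
        logger.warning("no gene lengths supplied; defaulting every gene to 1 kb")
        lengths = pd.Series(1000.0, index=counts.index)
    else:
        lengths = pd.Series(gene_lengths)
        missing = counts.index.difference(lengths.index)
        if len(missing):
            raise ValueError(f"missing gene length for: {sorted(missing)[:10]}")
        lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    if (total <= 0).any():
        bad = total.index[total <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return rate.div(total, axis=1) * 1e6


def transcriptome_usage(
    tpm: pd.DataFrame, annotation: pd.DataFrame, exclude=()
) -> pd.DataFrame:
    """Per-sample fraction of TPM mass in each functional group.

    ``annotation`` needs columns ``gene_id`` and ``group``.  Genes listed in
    ``exclude`` (e.g. the transgene) contribute zero mass and fractions are
    renormalized over the rest; unannotated genes fall into an explicit
    ``unassigned`` group so fractions stay compositionally closed.
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty functional annotation")
    sub = tpm.drop(index=[g for g in exclude if g in tpm.index])
    groups = (
        annotation.drop_duplicates("gene_id").set_index("gene_id")["group"]
        .reindex(sub.index)
        .fillna("unassigned")
    )
    mass = sub.groupby(groups.to_numpy()).sum()
    total = mass.sum(axis=0)
    if (total <= 0).any():
        raise ValueError("a sample has zero mass after exclusion")
    usage = mass.div(total, axis=1)
    usage.index.name = "group"
    return usage


def mito_fraction(tpm: pd.DataFrame, mito_genes) -> pd.Series:
    """Fraction of each sample's TPM mass on mitochondrial genes."""
    mito = [g for g in mito_genes if g in tpm.index]
    frac = tpm.loc[mito].sum(axis=0) / tpm.sum(axis=0)
    return frac.rename("mito_fraction")


def titer_log2fc(titer_a: float, titer_b: float) -> float:
    """log2((a+1)/(b+1)) — the pseudocount keeps undetected titers finite."""
    if titer_a < 0 or titer_b < 0:
        raise ValueError("titers must be non-negative")
    return float(np.log2((titer_a + 1.0) / (titer_b + 1.0)))


def classify_improved(lfc: float) -> bool:
    """More-than-two-fold improvement: strictly lfc > 1."""
    return bool(lfc > 1.0)


def secretory_subgroup_means(
    vst_expr: pd.DataFrame, subsystem_annotation
) -> pd.DataFrame:
    """Per-sample arithmetic mean of transformed expression per subsystem.

    ``subsystem_annotation`` maps gene id -> subsystem name.  Subsystems with
    no genes in the matrix are excluded with a warning.
    """
    ann = pd.Series(dict(subsystem_annotation)
                    if not isinstance(subsystem_annotation, pd.Series)
                    else subsystem_annotation)
    present = ann[ann.index.isin(vst_expr.index)]
    empty = set(ann.unique()) - set(present.unique())
    for sub in sorted(empty):
        warnings.warn(f"subsystem {sub!r} has no genes in the matrix; excluded")
    if present.empty:
        raise ValueError("no annotated genes present in the expression matrix")
    out = vst_expr.loc[present.index].groupby(present.to_numpy()).mean()
    out.index.name = "subsystem"
    return out
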