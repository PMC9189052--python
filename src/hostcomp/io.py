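"""Readers and writers for the pipeline's plain-text formats.

Tabular dialects: TSV with a header row, gene ids in the first column, UTF-8,
'.' decimal separator.  Gene sets use the standard GMT layout (name,
description, then member genes, tab-separated).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SAMPLE_SHEET_COLUMNS = ("sample_id", "cell_line", "condition", "r_protein", "replicate")
TITER_COLUMNS = ("r_protein", "cell_line", "titer_ug_ml")
PTM_COLUMNS = (
    "r_protein", "length_aa", "n_glyc_sites", "o_glyc_sites",
    "disulfide_bonds", "gpi_anchor",
)

__all__ = [
    "read_counts", "write_counts", "read_gmt", "write_gmt",
    "read_sample_sheet", "write_sample_sheet", "read_titers", "write_titers",
    "read_ptm_table", "write_ptm_table", "read_ortholog_map", "write_ortholog_map",
]


def _check_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.where(bad)[0][0])
            raise ValueError(
                f"{path}: malformed numeric cell at row {i + 2}, column {j + 2} "
                f"({df[col].iloc[i]!r})"
            )
        df[col] = coerced
    return df


def read_counts(path) -> pd.DataFrame:
    """Gene x sample count TSV; first column holds gene ids (must be unique)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return _check_numeric(df, path)


def write_counts(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: GMT line {lineno} defines an empty set")
            sets[name] = set(genes)
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name in gene_sets:
            genes = sorted(gene_sets[name])
            fh.write("\t".join([name, descriptions.get(name, "na"), *genes]) + "\n")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing column(s) {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_sample_sheet(st: pd.DataFrame, path) -> None:
    st.to_csv(path, index=False)


def read_titers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TITER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: titer table missing column(s) {missing}")
    if (df["titer_ug_ml"] < 0).any():
        raise ValueError(f"{path}: negative titer")
    if "detected" not in df.columns:
        df["detected"] = df["titer_ug_ml"] > 0
    return df


def write_titers(titers: pd.DataFrame, path) -> None:
    titers.to_csv(path, index=False)


def read_ptm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PTM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: PTM table missing column(s) {missing}")
    if (df["length_aa"] <= 0).any():
        raise ValueError(f"{path}: non-positive protein length")
    counts = df[["n_glyc_sites", "o_glyc_sites", "disulfide_bonds", "gpi_anchor"]]
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative PTM site count")
    return df


def write_ptm_table(ptm: pd.DataFrame, path) -> None:
    ptm.to_csv(path, index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ortholog map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["cho_gene_id", "human_gene_id"]
    return df.drop_duplicates()


def write_ortholog_map(omap: pd.DataFrame, path) -> None:
    omap.to_csv(path, sep="\t", index=False)
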