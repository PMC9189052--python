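"""Synthetic-data generator for the two-host comparison pipeline.

Emulates the statistical structure the downstream analysis assumes: two
negative-binomial count matrices (a CHO-like and a HEK293-like host) joined
by a partial ortholog map, producer-induced gene activation that differs by
cell line, a small set of planted extreme expression outliers inside the
secretory pathway, one transgene transcript per producer sample, a
mitochondrial library-mass fraction near a configured level, and secreted
titers drawn from the interaction regression model
``LFC_titer ~ Normal(a + b_ptm*PTM + b_enz*Enz + b_int*PTM*Enz, sigma)``.

All generators are pure functions of (config, seed): the same configuration
reproduces bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

CELL_LINES = ("CHO", "HEK293")

SECRETORY_SUBSYSTEMS = (
    "translocation",
    "protein folding",
    "ER glycosylation",
    "Golgi glycosylation",
    "vesicle trafficking",
    "UPR",
    "ERAD",
    "signal peptidase",
    "sorting and secretion",
    "proteostasis",
    "quality control",
)

NON_SECRETORY_GROUPS = (
    "translation",
    "transcription",
    "biosynthesis",
    "central carbon metabolism",
    "signaling",
    "other",
)

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "SimTruth",
    "generate_annotations",
    "generate_counts",
    "generate_titers",
    "simulate_bundle",
    "CELL_LINES",
    "SECRETORY_SUBSYSTEMS",
]


@dataclass
class SimConfig:
    """Study-level parameters of the synthetic two-host experiment.

    Defaults mirror the design being emulated: two cell lines, producer
    samples for every r-protein plus empty-vector controls in duplicate,
    a mitochondrial transcriptome share near 10%, a transgene transcript
    holding ~2% of a producer library, and a DESeq2-style dispersion trend
    ``alpha(mu) = a0 + a1/mu``.
    """

    n_genes: int = 2000
    n_secretory_genes: int = 300
    n_mito_genes: int = 20
    n_rproteins: int = 4
    replicates_per_condition: int = 2
    baseline_mean_log_range: tuple = (np.log(5.0), np.log(2000.0))
    dispersion_trend: tuple = (0.05, 2.0)
    cellline_effect_sd: float = 1.0
    activation_effect_sd_per_cellline: dict = field(
        default_factory=lambda: {"CHO": 0.3, "HEK293": 0.3}
    )
    n_planted_outliers: int = 0
    outlier_lfc: float = 10.0
    ortholog_coverage: float = 0.9
    mito_fraction_target: float = 0.10
    regression_truth: tuple = (0.0, 0.0, 0.0, 0.8, 0.1)  # (a, bPTM, bEnz, bInt, sigma)
    seed: int = 0
    # structural extras
    transgene_fraction: float = 0.02
    many_to_one_fraction: float = 0.05
    library_size_log_sd: float = 0.15
    # optional planted effects exercised by downstream recovery checks
    n_planted_activation: int = 0
    planted_activation_lfc: float = 0.0
    planted_activation_cellline: str = "HEK293"
    n_titer_tracking_genes: int = 0
    titer_tracking_noise_sd: float = 0.1

    def validate(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2 (DE needs replication)")
        if self.n_secretory_genes + self.n_mito_genes > self.n_genes:
            raise ValueError("n_secretory_genes + n_mito_genes must not exceed n_genes")
        if not (0.0 < self.mito_fraction_target < 1.0):
            raise ValueError("mito_fraction_target must be in (0, 1)")
        if not (0.0 < self.ortholog_coverage <= 1.0):
            raise ValueError("ortholog_coverage must be in (0, 1]")
        if self.cellline_effect_sd < 0:
            raise ValueError("cellline_effect_sd must be non-negative")
        if any(v < 0 for v in self.activation_effect_sd_per_cellline.values()):
            raise ValueError("activation effect sd must be non-negative")
        if self.regression_truth[4] <= 0:
            raise ValueError("regression truth sigma must be positive")
        if self.n_planted_outliers < 0 or self.n_planted_outliers > self.n_secretory_genes:
            raise ValueError("n_planted_outliers must be in [0, n_secretory_genes]")


@dataclass
class SimTruth:
    """Record of all planted effects, for recovery checks."""

    outlier_genes: list
    cellline_lfc: pd.Series          # per human gene, log2 HEK/CHO baseline effect
    activation_lfc: dict             # cell line -> per-gene log2 activation
    planted_activation_genes: list
    tracking_genes: list
    regression_coefficients: tuple
    enzyme_scores: pd.Series         # per r-protein true enzyme-expression score
    titer_lfc: pd.Series             # per r-protein realized log2 titer change


@dataclass
class SyntheticBundle:
    counts: dict                     # cell line -> genes x samples DataFrame
    sample_table: pd.DataFrame
    ortholog_map: pd.DataFrame       # columns cho_gene_id, human_gene_id
    functional_annotation: pd.DataFrame
    gene_sets: dict                  # set name -> set of human gene ids
    titers: pd.DataFrame
    ptm_annotations: pd.DataFrame
    gene_lengths: pd.Series
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# annotations, gene sets, ortholog map, PTM table
# ---------------------------------------------------------------------------

def _gene_ids(config: SimConfig):
    human = np.array([f"HG{i:05d}" for i in range(config.n_genes)])
    cho = np.array([f"CG{i:05d}" for i in range(config.n_genes)])
    return human, cho


def generate_annotations(config: SimConfig, seed: int = None):
    """Functional groups, secretory/PTM gene sets, ortholog map and PTM table.

    Functional groups partition all genes; the secretory subsystem sets are
    disjoint within the secretory group.  The ortholog map covers
    ``ortholog_coverage`` of CHO genes, with a configurable many-to-one
    fraction to exercise the aggregation policy.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    human, cho = _gene_ids(config)
    ns, nm = config.n_secretory_genes, config.n_mito_genes

    sec_genes = human[:ns]
    mito_genes = human[ns : ns + nm]
    other_genes = human[ns + nm :]

    subgroup = np.empty(config.n_genes, dtype=object)
    group = np.empty(config.n_genes, dtype=object)
    group[:ns] = "secretory pathway"
    subgroup[:ns] = rng.choice(SECRETORY_SUBSYSTEMS, size=ns)
    group[ns : ns + nm] = "mitochondrion"
    subgroup[ns : ns + nm] = "mitochondrion"
    group[ns + nm :] = rng.choice(NON_SECRETORY_GROUPS, size=other_genes.size)
    subgroup[ns + nm :] = group[ns + nm :]
    annotation = pd.DataFrame({"gene_id": human, "group": group, "subgroup": subgroup})

    gene_sets = {"secretory_pathway": set(sec_genes)}
    for sub in SECRETORY_SUBSYSTEMS:
        members = set(human[:ns][subgroup[:ns] == sub])
        if members:
            gene_sets[f"secretory:{sub}"] = members
    glyco = gene_sets.get("secretory:ER glycosylation", set()) | gene_sets.get(
        "secretory:Golgi glycosylation", set()
    )
    if glyco:
        gene_sets["glycosyltransferases"] = glyco
    folding = sorted(gene_sets.get("secretory:protein folding", set()))
    if folding:
        gene_sets["disulfide_enzymes"] = set(folding[: max(len(folding) // 2, 1)])

    n_mapped = int(round(config.ortholog_coverage * config.n_genes))
    mapped_idx = np.sort(rng.choice(config.n_genes, size=n_mapped, replace=False))
    targets = human[mapped_idx].copy()
    # redirect a fraction of mapped genes onto their predecessor's target,
    # creating many-to-one relations (and leaving their own target unmapped)
    if n_mapped > 1 and config.many_to_one_fraction > 0:
        n_m2o = int(round(config.many_to_one_fraction * n_mapped))
        if n_m2o:
            pos = rng.choice(np.arange(1, n_mapped), size=min(n_m2o, n_mapped - 1),
                             replace=False)
            targets[pos] = targets[pos - 1]
    ortholog_map = pd.DataFrame(
        {"cho_gene_id": cho[mapped_idx], "human_gene_id": targets}
    ).drop_duplicates()

    rproteins = [f"RP{i:02d}" for i in range(config.n_rproteins)]
    length = rng.integers(100, 400, size=config.n_rproteins)
    # zero-inflated glycosylation site counts spanning index ~ [0, 0.6]
    glyc_density = np.where(
        rng.random(config.n_rproteins) < 0.15, 0.0,
        rng.uniform(0.05, 0.6, config.n_rproteins),
    )
    n_glyc_total = np.rint(glyc_density * length).astype(int)
    o_share = rng.uniform(0.0, 0.5, config.n_rproteins)
    o_glyc = np.rint(n_glyc_total * o_share).astype(int)
    n_glyc = n_glyc_total - o_glyc
    ptm = pd.DataFrame(
        {
            "r_protein": rproteins,
            "length_aa": length,
            "n_glyc_sites": n_glyc,
            "o_glyc_sites": o_glyc,
            "disulfide_bonds": rng.poisson(length / 60.0),
            "gpi_anchor": (rng.random(config.n_rproteins) < 0.2).astype(int),
        }
    )
    return annotation, gene_sets, ortholog_map, ptm


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    rproteins = [f"RP{i:02d}" for i in range(config.n_rproteins)]
    for cl in CELL_LINES:
        for rp in rproteins:
            for rep in range(1, config.replicates_per_condition + 1):
                rows.append((f"{cl}_{rp}_rep{rep}", cl, "producer", rp, rep))
        for rep in range(1, config.replicates_per_condition + 1):
            rows.append((f"{cl}_ctrl_rep{rep}", cl, "control", "none", rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_line", "condition", "r_protein", "replicate"]
    )


def _nb_draw(rng, mean, alpha):
    """NB counts with Var = mu + alpha mu^2 (gamma-Poisson mixture)."""
    mean = np.maximum(mean, 1e-12)
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate_counts(
    config: SimConfig, activation_overrides: dict = None
) -> tuple[dict, pd.DataFrame, dict]:
    """NB count matrices for both cell lines plus the planted-effect record.

    Returns ``(counts_by_cellline, sample_table, truth_parts)``.  Planted
    outliers are secretory genes silent in CHO and highly expressed in
    HEK293 with the configured between-cell-line LFC; mitochondrial genes
    jointly receive about ``mito_fraction_target`` of the library mass.

    ``activation_overrides`` maps ``(human_gene, cell_line, r_protein)`` to a
    log2 activation, letting callers couple a gene's per-r-protein activation
    to an external signal (used for titer-tracking genes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    human, cho = _gene_ids(config)
    ns = config.n_secretory_genes
    a0, a1 = config.dispersion_trend

    baseline = np.exp(rng.uniform(*config.baseline_mean_log_range, size=config.n_genes))
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[ns : ns + config.n_mito_genes] = True
    t = config.mito_fraction_target
    other_mass = baseline[~mito_mask].sum()
    mito_mass = baseline[mito_mask].sum()
    if mito_mass > 0:
        baseline[mito_mask] *= t * other_mass / ((1.0 - t) * mito_mass)

    # mean-centered multiplicative effect (E[2^lfc] = 1) keeps total library
    # mass comparable between hosts; mitochondrial genes carry no cell-line or
    # activation effect, mirroring their role as a stable normalization control
    sd = config.cellline_effect_sd
    cellline_lfc = rng.normal(-0.5 * sd**2 * np.log(2.0), sd, size=config.n_genes)
    cellline_lfc[mito_mask] = 0.0
    outlier_genes = []
    if config.n_planted_outliers:
        idx = rng.choice(ns, size=config.n_planted_outliers, replace=False)
        outlier_genes = list(human[idx])
        # high HEK baseline, CHO side lower by 2^outlier_lfc (effectively silent)
        hek_mean = np.exp(rng.uniform(np.log(800.0), np.log(3000.0),
                                      size=config.n_planted_outliers))
        baseline[idx] = hek_mean * 2.0 ** (-config.outlier_lfc)
        cellline_lfc[idx] = config.outlier_lfc

    activation = {}
    for cl in CELL_LINES:
        sd_a = config.activation_effect_sd_per_cellline.get(cl, 0.0)
        activation[cl] = rng.normal(0.0, sd_a, size=config.n_genes)
        activation[cl][mito_mask] = 0.0
    planted_act_genes = []
    if config.n_planted_activation:
        # plant among non-outlier, non-mito genes
        pool = np.setdiff1d(
            np.arange(config.n_genes),
            np.concatenate([
                np.where(mito_mask)[0],
                np.array([int(g[2:]) for g in outlier_genes], dtype=int)
                if outlier_genes else np.array([], dtype=int),
            ]),
        )
        idx = rng.choice(pool, size=config.n_planted_activation, replace=False)
        planted_act_genes = list(human[idx])
        activation[config.planted_activation_cellline][idx] = config.planted_activation_lfc

    st = _sample_table(config)
    overrides = activation_overrides or {}
    counts = {}
    for cl in CELL_LINES:
        # HEK side carries the between-cell-line effect; CHO is the reference
        mean_cl = baseline * (2.0 ** (cellline_lfc * (cl == "HEK293")))
        cols = {}
        sub = st[st["cell_line"] == cl]
        gene_index = list(human if cl == "HEK293" else cho)
        transgenes = [f"transgene_{rp}" for rp in sorted(sub.loc[sub["condition"] == "producer", "r_protein"].unique())]
        for _, row in sub.iterrows():
            mu = mean_cl.copy()
            if row["condition"] == "producer":
                mu = mu * (2.0 ** activation[cl])
                for gi, g in enumerate(human):
                    key = (g, cl, row["r_protein"])
                    if key in overrides:
                        mu[gi] = mean_cl[gi] * (2.0 ** overrides[key])
            lib = np.exp(rng.normal(0.0, config.library_size_log_sd))
            mu = mu * lib
            tg = np.zeros(len(transgenes))
            if row["condition"] == "producer" and config.transgene_fraction > 0:
                f = config.transgene_fraction
                tgi = transgenes.index(f"transgene_{row['r_protein']}")
                tg[tgi] = f / (1.0 - f) * mu.sum()
            mu_full = np.concatenate([mu, tg])
            alpha = a0 + a1 / np.maximum(mu_full, 1e-8)
            cols[row["sample_id"]] = _nb_draw(rng, mu_full, alpha)
        mat = pd.DataFrame(cols, index=gene_index + transgenes)
        mat.index.name = "gene_id"
        counts[cl] = mat

    truth_parts = {
        "outlier_genes": outlier_genes,
        "cellline_lfc": pd.Series(cellline_lfc, index=human, name="cellline_lfc"),
        "activation_lfc": {
            cl: pd.Series(activation[cl], index=human, name=f"activation_{cl}")
            for cl in CELL_LINES
        },
        "planted_activation_genes": planted_act_genes,
    }
    return counts, st, truth_parts


# ---------------------------------------------------------------------------
# titers
# ---------------------------------------------------------------------------

def glycosylation_index(ptm: pd.DataFrame) -> pd.Series:
    """Total glycosylation sites per residue, per r-protein."""
    return pd.Series(
        (ptm["n_glyc_sites"] + ptm["o_glyc_sites"]).to_numpy()
        / ptm["length_aa"].to_numpy(dtype=float),
        index=ptm["r_protein"].to_numpy(),
        name="ptm_index",
    )


def generate_titers(
    ptm_annotations: pd.DataFrame,
    enzyme_scores,
    truth: tuple,
    seed: int,
) -> pd.DataFrame:
    """Draw per-r-protein titers from the interaction regression model.

    For each r-protein the log2 titer change (with the +1 pseudocount)
    from CHO to HEK293 is drawn from
    ``Normal(a + b_ptm*PTM + b_enz*Enz + b_int*PTM*Enz, sigma)``; a CHO
    titer is drawn on an arbitrary lognormal ug/ml scale and the HEK293 titer
    is set so that ``log2((hek+1)/(cho+1))`` equals the drawn LFC exactly.
    """
    a, b_ptm, b_enz, b_int, sigma = truth
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    for v in (a, b_ptm, b_enz, b_int):
        if not np.isfinite(v):
            raise ValueError("regression coefficients must be finite")
    rng = np.random.default_rng(seed)
    enz = pd.Series(enzyme_scores)
    ptm_idx = glycosylation_index(ptm_annotations).reindex(enz.index)
    mu = a + b_ptm * ptm_idx + b_enz * enz + b_int * ptm_idx * enz
    lfc = rng.normal(mu.to_numpy(), sigma)
    cho = rng.lognormal(np.log(5.0), 1.0, size=len(enz))
    hek = (cho + 1.0) * (2.0 ** lfc) - 1.0
    # keep titers non-negative while preserving the exact LFC
    neg = hek < 0
    hek = np.where(neg, 0.0, hek)
    cho = np.where(neg, 2.0 ** (-lfc) - 1.0, cho)
    rows = []
    for i, rp in enumerate(enz.index):
        rows.append((rp, "CHO", float(cho[i]), cho[i] > 0))
        rows.append((rp, "HEK293", float(hek[i]), hek[i] > 0))
    titers = pd.DataFrame(rows, columns=["r_protein", "cell_line", "titer_ug_ml", "detected"])
    titers.attrs["lfc"] = pd.Series(lfc, index=enz.index, name="titer_lfc")
    return titers


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Generate every pipeline input with internally consistent planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    annotation, gene_sets, ortholog_map, ptm = generate_annotations(config)

    rproteins = list(ptm["r_protein"])
    enzyme_scores = pd.Series(
        rng.uniform(-1.0, 1.0, size=len(rproteins)), index=rproteins, name="enzyme_score"
    )
    titers = generate_titers(ptm, enzyme_scores, config.regression_truth,
                             seed=config.seed + 2)
    titer_lfc = titers.attrs["lfc"]

    overrides = {}
    tracking_genes = []
    if config.n_titer_tracking_genes:
        human, _ = _gene_ids(config)
        start = config.n_secretory_genes + config.n_mito_genes
        cand = human[start : start + config.n_titer_tracking_genes]
        tracking_genes = list(cand)
        for g in cand:
            noise = rng.normal(0.0, config.titer_tracking_noise_sd, size=len(rproteins))
            for j, rp in enumerate(rproteins):
                overrides[(g, "HEK293", rp)] = float(titer_lfc[rp] + noise[j])
                overrides[(g, "CHO", rp)] = 0.0

    counts, st, truth_parts = generate_counts(config, activation_overrides=overrides)

    # planted outlier and tracking genes must survive ortholog conversion 1:1
    if truth_parts["outlier_genes"] or tracking_genes:
        out_h = set(truth_parts["outlier_genes"]) | set(tracking_genes)
        out_c = {f"CG{g[2:]}" for g in out_h}
        keep = ~(
            ortholog_map["human_gene_id"].isin(out_h)
            | ortholog_map["cho_gene_id"].isin(out_c)
        )
        repaired = pd.DataFrame(
            {
                "cho_gene_id": sorted(out_c),
                "human_gene_id": [f"HG{g[2:]}" for g in sorted(out_c)],
            }
        )
        ortholog_map = pd.concat([ortholog_map[keep], repaired], ignore_index=True)

    truth = SimTruth(
        outlier_genes=truth_parts["outlier_genes"],
        cellline_lfc=truth_parts["cellline_lfc"],
        activation_lfc=truth_parts["activation_lfc"],
        planted_activation_genes=truth_parts["planted_activation_genes"],
        tracking_genes=tracking_genes,
        regression_coefficients=config.regression_truth,
        enzyme_scores=enzyme_scores,
        titer_lfc=titer_lfc,
    )
    gene_lengths = pd.Series(1000.0, index=pd.Index(
        list(counts["HEK293"].index) + list(counts["CHO"].index)).unique(),
        name="length")
    # annotate transgenes so usage profiles stay compositionally closed
    extra = [g for g in gene_lengths.index if str(g).startswith("transgene_")]
    if extra:
        annotation = pd.concat(
            [annotation, pd.DataFrame({"gene_id": extra, "group": "transgene",
                                       "subgroup": "transgene"})],
            ignore_index=True,
        )
    cho_ids = pd.DataFrame({
        "gene_id": [f"CG{i:05d}" for i in range(config.n_genes)],
        "group": annotation.set_index("gene_id").reindex(
            [f"HG{i:05d}" for i in range(config.n_genes)])["group"].to_numpy(),
        "subgroup": annotation.set_index("gene_id").reindex(
            [f"HG{i:05d}" for i in range(config.n_genes)])["subgroup"].to_numpy(),
    })
    annotation = pd.concat([annotation, cho_ids], ignore_index=True)
    return SyntheticBundle(
        counts=counts,
        sample_table=st,
        ortholog_map=ortholog_map,
        functional_annotation=annotation,
        gene_sets=gene_sets,
        titers=titers,
        ptm_annotations=ptm,
        gene_lengths=gene_lengths,
        truth=truth,
        config=config,
    )
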