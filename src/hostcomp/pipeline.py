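"""End-to-end report: chain every analysis stage on one input bundle.

Stages: simulate -> usage -> differential expression (three contrasts) ->
enrichment -> outlier classification -> activation-titer correlation ->
PTM interaction model.  Every stage output is written under the output
directory and recorded in a manifest with the parameters, seeds and file
hashes, so a rerun with the same configuration reproduces identical hashes
for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp, enrichment, io, outliers, ptm, simulate, usage

logger = logging.getLogger(__name__)

__all__ = ["run_report"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merge_host_counts(bundle):
    """Ortholog-convert CHO counts and align both hosts on shared human genes."""
    cho = diffexp.aggregate_orthologs(
        bundle.counts["CHO"],
        bundle.ortholog_map[["cho_gene_id", "human_gene_id"]],
        policy="sum",
    )
    hek = bundle.counts["HEK293"]
    hek = hek.loc[[g for g in hek.index if not str(g).startswith("transgene_")]]
    shared = cho.index.intersection(hek.index)
    merged = pd.concat([cho.loc[shared], hek.loc[shared]], axis=1)
    return merged


def run_report(config: dict, out_dir) -> dict:
    """Run the full synthetic-data pipeline and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs.setdefault("seed", seed)
    sim_kwargs.setdefault("n_planted_outliers", 20)
    sim_kwargs.setdefault("n_titer_tracking_genes", 1)
    cfg = simulate.SimConfig(**sim_kwargs)

    manifest = {"seed": seed, "parameters": sim_kwargs, "stages": {}}

    def record(stage, paths, t0, extra=None):
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in paths},
            "seconds": round(time.time() - t0, 2),
        }
        if extra:
            manifest["stages"][stage].update(extra)
        logger.info("stage %s done (%.1fs)", stage, time.time() - t0)

    # 1. simulate ----------------------------------------------------------
    t0 = time.time()
    bundle = simulate.simulate_bundle(cfg)
    paths = []
    for cl, mat in bundle.counts.items():
        p = out / f"counts_{cl}.tsv"
        io.write_counts(mat, p)
        paths.append(p)
    p = out / "samples.csv"; io.write_sample_sheet(bundle.sample_table, p); paths.append(p)
    p = out / "orthologs.tsv"; io.write_ortholog_map(bundle.ortholog_map, p); paths.append(p)
    p = out / "gene_sets.gmt"; io.write_gmt(bundle.gene_sets, p); paths.append(p)
    p = out / "titers.csv"; io.write_titers(bundle.titers, p); paths.append(p)
    p = out / "ptm.csv"; io.write_ptm_table(bundle.ptm_annotations, p); paths.append(p)
    record("simulate", paths, t0)

    # 2. usage -------------------------------------------------------------
    t0 = time.time()
    paths = []
    for cl, mat in bundle.counts.items():
        tpm = usage.compute_tpm(mat, bundle.gene_lengths)
        transgenes = [g for g in mat.index if str(g).startswith("transgene_")]
        prof = usage.transcriptome_usage(tpm, bundle.functional_annotation,
                                         exclude=transgenes)
        p = out / f"usage_{cl}.tsv"
        prof.to_csv(p, sep="\t")
        paths.append(p)
        mf = usage.mito_fraction(tpm, bundle.functional_annotation.loc[
            bundle.functional_annotation["group"] == "mitochondrion", "gene_id"])
        p = out / f"mito_fraction_{cl}.tsv"
        mf.to_csv(p, sep="\t")
        paths.append(p)
    # titer log2 fold changes per r-protein
    wide = bundle.titers.pivot(index="r_protein", columns="cell_line",
                               values="titer_ug_ml")
    lfc = pd.Series(
        [usage.titer_log2fc(h, c) for h, c in zip(wide["HEK293"], wide["CHO"])],
        index=wide.index, name="titer_lfc",
    )
    improved = lfc.map(usage.classify_improved).rename("improved")
    p = out / "titer_lfc.csv"
    pd.concat([lfc, improved], axis=1).to_csv(p)
    paths.append(p)
    record("usage", paths, t0)

    # 3. differential expression (three contrasts) --------------------------
    t0 = time.time()
    paths = []
    merged = _merge_host_counts(bundle)
    st = bundle.sample_table
    producers = st[st["condition"] == "producer"]
    prod_counts = merged[producers["sample_id"]]
    de_cl = diffexp.NegativeBinomialDE(
        design=diffexp.DesignSpec(factors=["cell_line"], reference={"cell_line": "CHO"}),
        dispersion_groups="cell_line",
    ).fit(prod_counts, producers)
    res_cl = de_cl.test("cell_line_HEK293")
    p = out / "de_cellline.tsv"; res_cl.to_csv(p, sep="\t"); paths.append(p)

    act = {}
    for cl in simulate.CELL_LINES:
        host = bundle.counts[cl]
        host = host.loc[[g for g in host.index if not str(g).startswith("transgene_")]]
        if cl == "CHO":
            host = diffexp.aggregate_orthologs(
                host, bundle.ortholog_map[["cho_gene_id", "human_gene_id"]], policy="sum")
        act[cl] = diffexp.differential_activation(host, st, cl)
        p = out / f"de_activation_{cl}.tsv"
        act[cl].to_csv(p, sep="\t")
        paths.append(p)

    # interaction design: one activation-difference coefficient per r-protein
    interaction = diffexp.NegativeBinomialDE(
        design=diffexp.DesignSpec(
            factors=["cell_line"], interaction_cellline_rprotein=True,
            reference={"cell_line": "CHO"},
        ),
        dispersion_groups="condition",
    ).fit(merged, st)
    rproteins = sorted(producers["r_protein"].unique())
    act_diff = pd.DataFrame(
        {rp: interaction.test(f"act_diff_HEK293:{rp}")["lfc_shrunk"] for rp in rproteins}
    )
    p = out / "de_interaction.tsv"; act_diff.to_csv(p, sep="\t"); paths.append(p)
    record("de", paths, t0, extra={"contrasts": ["cellline", "activation", "interaction"]})

    # 4. enrichment ---------------------------------------------------------
    t0 = time.time()
    ranked = enrichment.rank_genes(res_cl["lfc_shrunk"].dropna())
    rows = []
    for name, members in bundle.gene_sets.items():
        if not set(members) & set(ranked.index):
            continue
        r = enrichment.nes_and_pvalue(ranked, members, n_perm=500, seed=seed, name=name)
        rows.append({"set": name, "es": r.es, "nes": r.nes, "p_perm": r.p_perm})
    p = out / "enrichment.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    record("enrich", [p], t0)

    # 5. outliers -----------------------------------------------------------
    t0 = time.time()
    vt = diffexp.VarianceStabilizingTransformer(groups=None).fit(merged)
    vmat = vt.transform(merged)
    cho_samples = st.loc[st["cell_line"] == "CHO", "sample_id"]
    hek_samples = st.loc[st["cell_line"] == "HEK293", "sample_id"]
    scale = 1.0 / np.sqrt(vt.dispersion_trend_[0])
    cls = outliers.classify_outlier_groups(
        vmat[cho_samples].mean(axis=1), vmat[hek_samples].mean(axis=1),
        band_halfwidth=2.0 * scale, low_thresh=2.0 * scale, high_thresh=6.0 * scale,
    )
    p = out / "outlier_groups.tsv"; cls.to_csv(p, sep="\t"); paths = [p]
    disparity = outliers.rank_activation_disparity(act["CHO"], act["HEK293"], top_k=20)
    p = out / "activation_disparity.tsv"; disparity.to_csv(p, sep="\t"); paths.append(p)
    universe = set(act["CHO"].index.intersection(act["HEK293"].index))
    sec = bundle.gene_sets["secretory_pathway"] & universe
    p_enrich = outliers.top_set_enrichment(set(disparity.index) & universe, sec, universe)
    record("outliers", paths, t0, extra={"top20_secretory_hypergeom_p": p_enrich})

    # 6. activation-titer correlation --------------------------------------
    t0 = time.time()
    corr = outliers.activation_titer_correlation(act_diff, lfc)
    p = out / "activation_titer_corr.tsv"
    corr.to_csv(p, sep="\t")
    record("activation-corr", [p], t0)

    # 7. PTM interaction model ----------------------------------------------
    t0 = time.time()
    glyc_set = bundle.gene_sets.get("glycosyltransferases", set())
    enz_scores = {}
    for rp in rproteins:
        ranking = enrichment.rank_genes(act_diff[rp].dropna())
        enz_scores[rp] = ptm.enzyme_expression_score(ranking, glyc_set, r_protein=rp)
    data = pd.DataFrame(
        {
            "lfc_titer": lfc.reindex(rproteins),
            "ptm_index": [
                ptm.ptm_index(row, "glycosylation")
                for _, row in bundle.ptm_annotations.set_index("r_protein")
                .loc[rproteins].reset_index().iterrows()
            ],
            "enzyme_expr": pd.Series(enz_scores).reindex(rproteins),
        }
    )
    if len(data) >= 5:
        post = ptm.fit_bayesian_interaction(
            data, mcmc={"seed": seed, "n_warmup": 500, "n_draws": 1000}
        )
        summary = ptm.posterior_summary(post)
        p1 = out / "posterior_draws.csv"; post.draws.to_csv(p1, index=False)
        p2 = out / "posterior_summary.json"
        p2.write_text(json.dumps(summary.to_dict(), indent=2, default=float))
        record("ptm-model", [p1, p2], t0, extra={"rhat": post.rhat})
    else:
        record("ptm-model", [], t0, extra={"skipped": "fewer than 5 r-proteins"})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
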