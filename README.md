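# hostcomp

Comparative transcriptomics of recombinant-protein expression hosts.

Some human proteins that are difficult to secrete from CHO cells express
markedly better from HEK293. `hostcomp` implements the analysis stack for
asking *why*, starting from gene-level count matrices of producer and
empty-vector control samples in the two hosts:

- **Transcriptome usage** — the fraction of length-normalized expression
  (TPM) devoted to each functional group per sample, with the transgene
  excluded and a mitochondrial-fraction QC.
- **Differential expression / activation** — a negative-binomial GLM engine:
  median-of-ratios size factors, dispersion trend `α(μ) = a₀ + a₁/μ` with
  empirical-Bayes shrinkage, Wald tests on arbitrary contrasts (between-host,
  producer-vs-control "activation", and a cell-line × r-protein interaction
  design), normal-prior shrinkage of log₂ fold changes, and a closed-form
  variance-stabilizing transformation (VST). Cross-species comparison goes
  through an ortholog conversion table.
- **Gene-set enrichment** — the classic running-sum enrichment score
  (hits weighted by |metric|ᵖ, misses by 1/(N−K)), normalized against
  same-size random gene sets (NES) with a permutation p-value, plus exact
  hypergeometric over-representation tests.
- **Secretory outliers** — classification of genes into groups I/II/III by
  joint VST expression in the two hosts, ranking by activation disparity
  |LFC_HEK − LFC_CHO|, and per-gene correlation of differential activation
  with titer changes across r-proteins.
- **PTM interaction model** — a Bayesian linear regression of the log₂ titer
  improvement from CHO to HEK293 (pseudocount +1):

      LFC_titer[i] ~ Normal(μ[i], σ)
      μ[i] = a + b_ptm·PTM[i] + b_enz·Enz[i] + b_int·PTM[i]·Enz[i]

  with priors a ~ Normal(0, 1), b ~ Normal(0, 0.25), σ ~ Exponential(1),
  where PTM[i] is the PTM index (modification sites per residue) and Enz[i]
  the enrichment-score summary of the PTM-enzyme set in the per-r-protein
  expression-change ranking. Sampled by adaptive Metropolis-within-Gibbs
  with split-R̂ diagnostics.

A synthetic-data module generates every pipeline input (two-host NB counts
joined by a partial ortholog map, producer activation, planted outliers,
transgene transcripts, titers drawn from the interaction model above) so the
whole pipeline is testable with no downloads.

## Worked example

Simulate a two-host experiment with 20 planted secretory outliers (silent in
CHO, high in HEK293), convert CHO genes to their human orthologs, and test
the between-host contrast:

```python
from hostcomp import diffexp, simulate
from hostcomp.pipeline import _merge_host_counts

cfg = simulate.SimConfig(n_genes=2000, n_rproteins=4, replicates_per_condition=3,
                         n_planted_outliers=20, outlier_lfc=10.0, seed=7)
bundle = simulate.simulate_bundle(cfg)
merged = _merge_host_counts(bundle)          # ortholog-mapped, both hosts
st = bundle.sample_table
producers = st[st["condition"] == "producer"]

de = diffexp.NegativeBinomialDE(
    design=diffexp.DesignSpec(factors=["cell_line"], reference={"cell_line": "CHO"}),
    dispersion_groups="cell_line",
).fit(merged[producers["sample_id"]], producers)
res = de.test("cell_line_HEK293")
print(res.sort_values("padj").head(5)[["baseMean", "lfc_raw", "lfc_shrunk", "pvalue", "padj"]].round(3))
```

```
         baseMean  lfc_raw  lfc_shrunk  pvalue  padj
gene_id
HG00042  2190.668   10.937      10.611     0.0   0.0
HG00133  1651.528    9.767       9.533     0.0   0.0
HG00111  1277.481    9.600       9.342     0.0   0.0
HG00241  1452.386    9.706       9.435     0.0   0.0
HG00769   787.717   -6.544      -6.460     0.0   0.0
```

Positive `lfc_shrunk` is higher expression in HEK293 (log₂ units); the top
rows are planted outliers recovered at close to their true +10 effect, with
the shrinkage pulling noisy estimates slightly toward zero. On this run all
20 planted outliers land in the top 40 genes by |shrunken LFC|.

The same stages are exposed as a CLI:

```sh
hostcomp simulate --out sim/ --seed 3
hostcomp de --counts sim/counts_HEK293.tsv --samples sim/samples.csv \
            --contrast activation --cell-line HEK293 --out act.tsv
hostcomp enrich --gmt sim/gene_sets.gmt --rank rank.tsv --nperm 1000 --seed 7 --out enr.tsv
hostcomp report --out report/ --seed 1       # all stages end to end
```

## Layout

```
src/hostcomp/
  simulate.py    synthetic two-host experiment generator
  usage.py       TPM, usage decomposition, titer fold changes
  diffexp.py     NB GLM engine, shrinkage, VST (sklearn-style estimators)
  enrichment.py  running-sum ES/NES, hypergeometric tests
  outliers.py    group I/II/III classification, disparity, correlations
  ptm.py         PTM indices, enzyme ES summaries, Bayesian model
  io.py          TSV/CSV/GMT readers and writers
  pipeline.py    end-to-end report with manifest
  cli.py         `hostcomp` command line
docs/methods.md  model assumptions, parameter choices, limitations
```
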