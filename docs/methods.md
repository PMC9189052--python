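# Methods

This note documents the statistical models behind `hostcomp`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical details that matter when interpreting output.

## Count model and differential expression

Counts are modeled as negative binomial with mean/dispersion
parameterization, `Var(K) = μ + α μ²`, and a parametric dispersion trend
`α(μ) = a₀ + a₁/μ` (a Poisson-like extra term at low means decaying to an
asymptotic biological coefficient of variation √a₀ at high means).

**Size factors** are median-of-ratios: for genes expressed in every sample,
the median of count/geometric-mean ratios per sample. They are undefined
when no gene is expressed everywhere; the error suggests the usual
pseudo-reference fallback rather than silently applying one.

**Dispersion estimation** proceeds in three steps. (1) A gene-wise
method-of-moments estimate `α̂ = (v − μ̄·ξ)/μ̄²`, where `v` is the pooled
within-group variance of normalized counts (so condition effects do not
inflate it) and `ξ = mean(1/s)` accounts for the Poisson variance of scaled
counts. Estimates at or below the floor (1e−8) carry no usable signal.
(2) The trend is fit by iteratively reweighted least squares with
gamma-style weights (1/fitted²) and iterative exclusion of genes far from
the trend. (3) Log dispersions are shrunk toward the log trend with a
normal prior whose variance is the excess of the residual spread over the
expected sampling variance `ψ′((m−p)/2)` (floored at 0.0625); floored genes
take the trend value outright, since shrinking from the floor would drag
them to meaninglessly small dispersions.

**Testing** uses a log-link NB GLM fit by IRLS (linear predictor clamped to
±30 natural-log units so genes with empty groups stay finite; non-converged
genes are flagged, their p-values set missing, and excluded from the BH
denominator). Wald statistics use a normal reference. At small sample sizes
(3+3) this plug-in-dispersion Wald test is mildly anti-conservative — in
null simulations the empirical type-I rate at nominal 0.05 sits near
0.055–0.065 — which is the standard behavior of this test family, not a
defect of the implementation; the calibration checks assert the 0.03–0.07
band.

**LFC shrinkage** is a zero-centered normal prior applied to the Wald
estimate treating `lfc_raw ~ N(β, se²)`: the posterior mode is
`lfc·s²/(s²+se²)` with the prior width `s` chosen once per result table by
maximizing the marginal likelihood `Π N(lfc; 0, s²+se²)` over a log-spaced
grid (0.05–8, 30 points). This is a stated approximation of heavier-tailed
shrinkage estimators: a single global width means genes with large true
effects are shrunk somewhat more than a mixture prior would, which matters
when the bulk effect spread is small relative to per-gene standard errors
(see the recovery-experiment sizes below). Shrinkage never changes sign and
never increases magnitude. A pseudocount of 1 is used only for descriptive
log₂ fold changes of normalized counts, never inside the GLM.

**VST.** Integrating `1/√(μ + α(μ)μ²)` with the trend above gives, with
`b = 1 + a₁`,

    v(q) = log2( (2a₀q + b + 2√(a₀q(a₀q + b))) / b ) / √a₀

applied to normalized counts. It is zero at zero, monotone, and for large
counts differences approach log₂ differences divided by √a₀ — so VST values
live on a "log₂/√a₀" scale. Consumers that take thresholds in these units
(outlier classification, below) should scale thresholds by 1/√a₀ when the
fitted asymptote differs materially from 1; the pipeline's report stage does
this automatically.

**Ortholog conversion** happens before cross-host model fitting
(conversion-then-aggregation). Unmapped source genes are dropped and
logged. Default policy: many-to-one source genes are summed into their
shared target; one-to-many source genes are dropped. `drop_ambiguous`
removes every gene touching a non-1:1 relation.

**Design matrices.** Three canned comparisons mirror the study design:
producers-only between hosts (`~ cell_line`), producer-vs-control within a
host (`~ condition`, the "activation"), and the interaction design, which
uses one producer dummy per r-protein (its coefficient is that r-protein's
activation in the reference host) plus one cell_line × r-protein column
(its coefficient is the activation difference between hosts for that
r-protein). That last coefficient set feeds the activation–titer
correlation.

## Enrichment

The running-sum enrichment score increments at in-set genes by
`|metric|^p` (normalized over the set; equal weights if all in-set metrics
are zero) and decrements at misses by `1/(N−K)`; the ES is the signed
maximum deviation. `weight_p` defaults to 1; `p = 0` gives the unweighted,
rank-only statistic. Ties in the ranking metric are broken by gene id, so
rankings are deterministic.

The null for NES and the permutation p-value is **gene-label permutation**
(random same-size sets), not sample permutation — shrunken-LFC rankings have
no per-sample replicates to permute. NES divides ES by the mean |null ES| of
matching sign; p = (1 + #{same-sign null ≥ |ES|}) / (1 + #same-sign null),
so p is never zero and is reproducible under a fixed seed. Null ES values
are computed by an O(K)-per-set path evaluating the running sum only at
hit-adjacent positions; a property test pins its exact equality to the full
running sum. Note the permutation band of the weighted (p = 1) statistic is
wider than the unweighted one: for 20-gene sets in a 1000-gene standard
normal ranking the 95% band of |ES| is ≈0.45 (vs ≈0.3 unweighted).

Over-representation uses the exact hypergeometric upper tail
(`P[X ≥ k]`), verified against exhaustive enumeration of all draws for
universes up to N = 12.

## PTM interaction model

The PTM index of an r-protein is the number of occurrences of a
modification type divided by its amino-acid length (sites per residue);
glycosylation counts N- plus O-linked sites, disulfide counts bonds
(interchain included), and a 0/1 GPI index is kept as an optional third
type. Phosphosite-type modifications are out of scope. The length
denominator is the expressed construct's length as supplied — lengths are
never inferred from molecular weight.

Enzyme expression per r-protein is the running-sum ES (weight 1) of the
PTM-enzyme gene set in that r-protein's between-host expression-change
ranking (shrunken LFCs, for consistency with the DE engine's ranking
policy). There is a single ES definition in the package; the enzyme
summarizer delegates to it.

The regression links the log₂ titer change CHO→HEK293 (computed with a +1
pseudocount so undetected proteins are usable) to PTM index, enzyme score
and their interaction, with priors a ~ N(0,1), slopes ~ N(0,0.25), and
σ ~ Exponential(rate 1) — the rate is exposed as configuration since only
the family is conventional. Predictors are not standardized by default (the
priors are interpreted on the raw scale); a standardize option exists and is
recorded in output metadata.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs: one Gaussian
proposal per coordinate (σ on the log scale with the Jacobian term), step
sizes adapted every 50 warmup iterations toward a 0.30–0.45 acceptance
rate, two chains by default, concatenated after warmup. Split-R̂ is computed
per parameter; values above 1.05 raise a warning. With σ fixed, the
coefficient posterior is Gaussian in closed form, which serves as the
sampler's oracle in tests (agreement within 3 Monte-Carlo standard errors,
with effective sample size conservatively taken as draws/10 for the
random-walk chain).

**Identifiability of the interaction.** Because a PTM index is
non-negative, `PTM·Enz` is strongly collinear with `Enz` under random
designs (correlation ≈0.85 for index ~ U(0, 0.6), score ~ U(−1, 1)), and
under the N(0, 0.25) slope prior the interaction coefficient is then
substantially shrunk no matter how small σ is. Parameter-recovery
experiments therefore use a balanced two-level design — glycosylation index
0 or 0.6, enzyme score ±1 — which makes the interaction column nearly
orthogonal to the main effects (expected posterior mean ≈0.77 for a true
0.8 at n = 50, σ = 0.1). Observational analyses should expect the random-
design shrinkage, not the designed-experiment behavior. A related
degeneracy: an exactly-zero response vector makes the likelihood collapse
(σ → 0 pins all coefficients); prior-dominance behavior is only well posed
with σ fixed or noisy data.

The conditional effect curve reports the posterior slope of titer change on
enzyme expression at chosen PTM indices, `b_enz + b_int·v`, whose sign flip
across glycosylation load is the model's central qualitative output; the
per-draw sign-change point is `−b_enz/b_int`.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
genome. Per host: NB counts with the configured dispersion trend; gene
baselines log-uniform over means 5–2000; a mean-centered per-gene
between-host effect (sd 1 log₂ by default) so total library mass stays
comparable; per-(gene, host) activation effects on producer samples (sd 0.3
log₂ by default); per-sample lognormal library-size variation (sd 0.15);
one transgene transcript per producer sample holding 2% of the library;
mitochondrial genes scaled to a 10% mass target and exempt from host and
activation effects, mirroring their role as a stability control.
Functional groups partition all genes; eleven secretory subsystems are
disjoint within the secretory group; the ortholog map covers 90% of CHO
genes with a 5% many-to-one fraction (planted outlier/tracking genes are
kept 1:1 so they remain analyzable). Replicates default to 2 per condition,
matching duplicate-well experimental practice; recovery experiments
configure more (below). Titers are generated from the interaction model
itself on an arbitrary lognormal µg/ml scale anchored on the CHO side; the
HEK293 titer is set so the +1-pseudocount LFC is exact (clipped at zero
titer with the CHO side adjusted, preserving exactness).

Synthetic PTM indices span ~0–0.6 sites per residue (15% of proteins
unglycosylated). That range is wider than typical real protein site
densities (~0–0.05) and is a deliberate scale choice: it makes the
interaction term carry enough likelihood information for the
parameter-recovery tolerances to be meaningful under the raw-scale priors.

**What passing tests do not show.** The generator has no sequencing-depth
biases, no correlated gene modules, no batch effects, no isoform-level
ambiguity, and its ortholog errors are structural (missing/many-to-one)
rather than evolutionary. Recovery results here bound what the methods can
do under their own assumptions; real cross-species data will be harder.

**Recovery-experiment sizes.** Planted-outlier recovery: 2000 genes, 20
outliers at +10 log₂, 3 replicates. Activation recovery: 6 replicates and
bulk activation sd 0.5 — with duplicate wells the global shrinkage prior
pulls a planted +2 activation to ≈1.5, so recovery at the stated tolerance
requires this stronger design. Activation–titer tracking: 20 r-proteins,
3 replicates, titer σ = 1.0 (titer changes spanning several log₂ units, as
real panels do); with σ = 0.1 the titer spread is below interaction-LFC
estimation noise and no method could rank the tracking gene highly.
Null calibration: 2000 genes, α = 0.2, 3+3. These sizes are the package's
desk-scale defaults for its own validation runs.

## Outlier classification

Genes are classified on mean VST expression per host: inside the identity
band when |HEK − CHO| ≤ band half-width; group I (silent in CHO, high in
HEK: CHO < low, HEK ≥ high), group II (moderate CHO, HEK above it by more
than the band), group III (CHO above HEK by more than the band). Defaults
band = 2, low = 2, high = 6 are qualitative choices in VST log₂-like units
and are configurable; the report stage multiplies them by 1/√a₀ to follow
the VST scale. The activation-disparity ranking takes the top-k genes by
|LFC_HEK − LFC_CHO| of shrunken activation LFCs, ties broken by gene id.
The activation–titer correlation is Pearson across r-proteins (the
correlation unit is the r-protein, matching per-r-protein interaction
coefficients); genes with zero-variance activation vectors are reported as
undefined and excluded from the ranking.

## Known limitations

- No Cook's-distance outlier handling or independent-filtering
  optimization in the DE engine (recorded in result metadata).
- The single-width normal shrinkage understates very large effects
  relative to mixture/heavy-tailed priors.
- Gene-label permutation nulls ignore inter-gene correlation, so
  enrichment p-values are anti-conservative on strongly co-expressed sets.
- The sampler is a random-walk scheme: adequate for this 5-parameter
  posterior (checked by split-R̂ and the Gaussian oracle) but not meant for
  larger models.
- `run_report` operates on an in-memory synthetic bundle; file-based
  stage inputs are validated by the individual CLI subcommands instead.
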