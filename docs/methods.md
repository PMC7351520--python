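# Methods

This note documents the statistical models, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## Differential expression (`ncnet.de`)

**Model.** Counts for feature *f* in sample *j* of group *g* are modelled as
negative binomial, `Y_fj ~ NB(mean μ_fg·N_j, dispersion φ)` with
`Var = μ + φμ²` and a single dispersion φ shared by all features. With a
common φ and *equal* effective library sizes, the group sum of a feature is
itself NB, and the distribution of the group-A sum conditional on the
feature's total is free of the unknown mean — the basis of the conditional
exact test (the overdispersed analogue of Fisher's exact test, and the
classic exact-test formulation for two-group RNA-seq comparisons).

**Normalization.** Upper-quartile factors: for sample *j*, `q_j` is the
0.75-quantile (linear interpolation) of the counts over features nonzero in
at least one sample, divided by the library size (column sum unless supplied
externally); factors are `q_j` divided by the geometric mean of all `q`, so
they multiply to 1. Effective library size is `library_size × factor`.

**Library-size equalization.** The exact test requires equal sizes, so
counts are rescaled to the geometric mean of the effective sizes and rounded
half-to-even (`numpy.rint`) to stay integral. This is a pragmatic stand-in
for quantile-adjusted pseudo-counts; at the 6-vs-6 design and the depths
used here the rounding perturbation is negligible relative to NB noise.

**Dispersion.** φ maximizes the conditional (on per-group totals)
log-likelihood summed over features and groups, by bounded scalar
minimization on the log scale over φ ∈ [1e−6, 5] (`xatol` 1e−8). A maximum
at the lower bound is reported as φ = 0 (Poisson); the lower bound itself
avoids catastrophic cancellation in `lgamma` differences at extreme `1/φ`.
Groups with a single replicate are rejected with instructions to supply a
fixed φ. Only the common-dispersion mode is implemented — no tagwise
empirical-Bayes shrinkage; with hundreds of features and a shared protocol
this is the minimal faithful setting, and per-feature moderation is out of
scope.

**Test and fold change.** For each feature the two-sided p-value sums the
conditional probabilities of all group-sum splits whose probability does not
exceed the observed split's (ties included, relative tolerance 1e−12); a
zero-total feature has p = 1. At φ = 0 the conditional law is
`Binomial(z, n_A/(n_A+n_B))` and the test coincides with the exact binomial
test. `log2FC = log2((z_B/n_B + c)/(z_A/n_A + c))` with prior count
c = 0.125 per sample (library sizes are equal after equalization, so the
prior is flat), keeping presence/absence features large but finite — the
published tables contain |log2FC| > 20, i.e. on/off transcripts, and the
pipeline must not overflow on them.

**Multiplicity and calls.** Benjamini–Hochberg step-up (via statsmodels)
across the tested features; calls are boundary-inclusive (`fdr ≤ threshold`,
matching the stated "≤ 0.05" / "≤ 0.06" conventions) with the sign of
log2FC; a zero log2FC is never called.

## Overlap analysis (`ncnet.setops`)

Tables list transcripts; overlap statements are about genes. Collapse keeps
one entry per gene symbol with direction up/down when all transcript signs
agree and "mixed" otherwise; mixed genes count once everywhere (the
published counts treat an inversely modulated gene as one DEL). Venn
partitions are exact 7-region set algebra over gene names; the
obesity∩cancer statistic is the union of the lncRNA and miRNA
triple-intersection regions (the two namespaces must not collide). Gene
symbols are case-sensitive opaque strings — any identifier harmonization is
assumed done upstream.

Shipped fixtures: the published DEL/DEM tables are stored per contrast (a
contrast is the pipeline's unit of work), with row absence — not sentinels —
encoding "not differential here". Where the transcribed wide table and the
results text disagree on membership, the fixtures follow the text's explicit
shared-gene lists; the per-row adjusted p-values are not printed in the
source tables, so the fixture `fdr` column carries the stated column bound
(0.05 / 0.06). Transcript identifiers are likewise not printed;
multi-transcript genes get `.t1`, `.t2`, … suffixes.

## Tripartite networks (`ncnet.network`)

Edges come from typed evidence tables. Layer rules: miRNA→mRNA and
lncRNA–mRNA admit experimentally validated rows only; lncRNA–miRNA admits
validated rows plus predictions with score ≥ 0.6 (boundary inclusive), the
union deduplicated with validated evidence taking precedence. Every layer is
filtered to features differential in the contrast at hand. "Degree" is the
incident-edge count of the undirected integrated graph ("directed edges" in
figure-legend parlance is read as degree — regulatory orientation is unused
downstream); hubs are nodes with degree ≥ 6. Display filtering keeps nodes
by *full-network* degree and never recomputes degrees after removal, so it
is idempotent. One node per symbol: a gene targeted by both miRNAs and
lncRNAs is a single mRNA node with edges in both layers. The published
network sizes and hub lists depend on specific external database snapshots
and are deliberately not reproduction targets; the graph stage is instead
validated exactly against planted synthetic evidence.

## Enrichment (`ncnet.enrich`)

Over-representation of a direction-annotated query against GMT collections,
universe = the contrast's differential transcripts (a defensible, explicit
background; configurable). Two-sided p by doubling the smaller
hypergeometric tail, capped at 1 — "two-sided" is the stated setting and the
doubled-tail rule is the simplest symmetric combination. BH across all
tested terms, significance strict (`p_adj < 0.05`). Terms are grouped by
Cohen's kappa between binary overlap-membership vectors over the query
(κ ≥ 0.4 joins; connected components; representative = smallest adjusted p,
ties by term id) — the flat statistical core of GUI-tool kappa grouping,
without term fusion or ontology leveling. Identical all-zero or all-one
vectors (expected agreement 1) are defined as κ = 1.

## qPCR (`ncnet.qpcr`)

ΔCt = Ct(target) − Ct(reference assay); ΔΔCt centers on the *mean* control
ΔCt (group-mean calibration rather than a designated calibrator sample,
matching a "normalized to healthy lean control" presentation), and
fold = 2^−ΔΔCt, so control folds have geometric mean exactly 1. ANOVA/LSD
runs on ΔΔCt (log scale) by default — fold values are log-normal-ish and
the log scale is where the normality assumption is defensible — with the
fold scale available via the returned per-sample table. The omnibus F and
the LSD t statistics (pooled within-group mean square, residual df,
unadjusted two-sided p) are computed from the textbook formulas so that
degenerate inputs behave sensibly (all values identical → F = 0, p = 1);
unbalanced groups are supported (one published group has n = 5). Stars: *
for p ≤ 0.05, ** for p ≤ 0.005. Spearman concordance uses mid-ranks; for
n ≤ 8 the p-value enumerates all n! permutations, otherwise the t
approximation on n − 2 df. No amplification-efficiency correction is
applied (pure 2^−ΔΔCt).

## Synthetic data (`ncnet.synth`)

The generators emulate the study conditions: 4 groups × 6 replicates;
heavy-tailed baseline abundances (log-normal, σ = 1.5); NB counts with
φ = 0.15 by default; planted miRNA fold changes uniform in
|log2FC| ∈ [0.48, 1.56] (the span of the published miRNA table) at a 10% DE
fraction; lncRNAs in a separate regime (|log2FC| ∈ [2, 8], 20% DE) with 30%
of the planted lncRNAs made on/off — rate zero on one side, with "on"
features kept exclusive to one disease group so other contrasts' ground
truth stays clean. Default depth is 200,000 reads/sample, a scaled-down
choice keeping the exact test's O(total-count) enumeration fast; type-I
error and FDR calibration are insensitive to depth at this scale, and the
sequenced libraries this emulates are simply deeper.

Interaction evidence plants prescribed hub degrees (miRNA hubs 12/9/8
validated targets; lncRNA hubs 8/7/6 miRNA links) and one lncRNA with 264
validated mRNA interactions (the XIST pattern); all other ncRNAs are capped
below the hub threshold by construction, so planted hub sets are exact, and
decoy rows (non-differential endpoints; sub-threshold prediction scores)
must be removed by the filters. The planted-truth survivorship of predicted
lncRNA–miRNA edges applies the same score ≥ 0.6 rule as the pipeline
default. The default differential-transcript universe is 1,000 genes —
the scale of the emulated per-contrast mRNA lists — so network queries
stay a proper subset of the enrichment universe.

qPCR plates realize planted per-group folds as
`Ct = baseline − log2(fold) + N(0, σ)` with σ = 0.2 cycles (a typical
replicate SD) against a stable reference assay; at σ = 0 the 2^−ΔΔCt
computation inverts the planted folds exactly.

Every generator is a pure function of `SynthConfig`; per-stage RNG streams
derive as `seed + stage index` (counts 0, interactions 1, qPCR 2, gene
sets 3).

**What the generators do not emulate** — and hence what green tests do not
establish about real data: read-level artifacts (mapping, adapter and
multi-mapping biases), compositional coupling beyond a shared library-size
constraint, tagwise dispersion variation, correlated expression between
interacting molecules (evidence edges are planted independently of the
simulated counts), database incompleteness/bias in interaction evidence,
and amplification-efficiency differences between qPCR assays.

## Verification strategy

Statistical primitives are checked against independent oracles: the exact
test at φ = 0 against exact binomial enumeration on all totals ≤ 50; the
two-sided hypergeometric p against exhaustive rational-arithmetic
enumeration for all universes N ≤ 12; BH against hand step-up vectors;
Spearman p against full 4! permutation enumeration; ANOVA/LSD against
scipy's omnibus F and the pooled-variance t-test in the two-group reduction.
Calibration: null NB simulations (1,000 features, 6 vs 6, φ = 0.15) keep
the raw-p type-I error within [0.03, 0.07] (median over 20 seeds); planted
DE at |log2FC| = 1.5 yields median empirical FDR ≤ 0.10 at nominal 0.05 and
median sensitivity ≥ 0.5; null qPCR plates keep the ANOVA rejection rate in
[0.03, 0.07] over 1,000 seeded replicates. Graph stages are exact against
planted ground truth (zero tolerance), including the 0.59/0.60 score
boundary and the 264-target lncRNA.

## Known limitations

* Common dispersion only; features with genuinely heterogeneous dispersion
  will be mis-calibrated at the tails.
* The upper-quartile/equalization interplay is one defensible composition of
  the stated normalization and the exact test's equal-size requirement, not
  the only one; downstream stages therefore treat the shipped differential
  tables, not re-called DE, as the source of truth for the published data.
* Venn algebra is specialized to the three-contrast design; no >3-set
  generalization and no overlap-significance testing.
* Enrichment reproduces flat term testing plus kappa components only — no
  term fusion, GO-tree leveling, or live pathway-database access.
* Interaction evidence is consumed as-is; no attempt is made to model
  database version drift, which is why published network sizes are not
  comparison targets.
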