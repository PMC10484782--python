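# Methods

## Variant classification

One transcript per gene is an input contract; exons are stored 0-based,
half-open, ordered 5'→3' in the coding direction. Protein-truncating
variants (PTVs) are stop-gained, frameshift, splice-donor and
splice-acceptor consequences; splice-region and start-lost are deliberately
left in `OTHER` — the four classes above are the conventional
loss-of-function set. A PTV is excluded as NMD-escaping when it lies in the
last exon or within the final 50 bases of the penultimate exon. The window
is measured in transcript-forward coordinates and is inclusive: for a
variant at 0-based position `pos` in the penultimate exon `[start, end)`,
the distance to the 3' end is `end − pos` (the last base has distance 1)
and the variant escapes iff that distance ≤ 50. The boundary convention
matches the common "within 50 nt" NMD heuristic and is configurable
(`Thresholds.nmd_window`). Single-exon transcripts escape everywhere: their
only exon is the last exon.

Rare missense status requires allele frequency strictly below 0.001 in
*both* the reference panel and the analysis cohort; the deleterious tiers
additionally require CADD ≥ 20 (inclusive) or Helix > 0.5 (exclusive).
These comparisons are applied exactly as written — a variant at AF 0.001
exactly is not rare; CADD 20.0 exactly is deleterious; Helix 0.5 exactly is
not.

Collapsing treats missing genotypes as non-carriers, which keeps samples
but can fabricate carrier-frequency differences when missingness is
batch-structured; `missingness_report` exposes per-gene missingness so such
artifacts can be screened before scanning. Cohort allele frequencies divide
by twice the non-missing sample count, with a female-only denominator for
chromosome-X genes (passed as a sample filter).

## Burden test

The test is a logistic regression with the carrier indicator as outcome and
the weighted phenotype `d + ½f` as predictor, plus covariates (dummy-coded
categoricals, constant columns dropped, residual rank deficiency reported
with the offending column named). By odds-ratio symmetry the weighted-
phenotype coefficient estimates the per-carrier log odds ratio for disease;
`exp(beta)` is reported and interpreted as the carrier OR. p-values are the
two-sided normal tail of the Wald z (`z = beta/se`), matching the z-score
pipeline the meta-analysis consumes.

Maximum likelihood is attempted first (statsmodels Newton); non-convergence,
divergence (|beta| > 15) or exploding standard errors trigger Firth's
bias-reduced logistic regression (Jeffreys-prior penalty, implemented here
because no installed package provides it), which yields finite estimates
under complete separation; such genes carry `converged = False`. Missing
family history is treated as `f = 0` (conservative, keeps the sample).

Scan semantics: one result per gene with ≥ 1 carrier after restriction;
subtype restrictions (`er_pos`, `er_neg`, `pr_pos`, `pr_neg`, `tn`) and the
age restriction (`age_lt50`) filter cases only and drop cases with missing
markers rather than imputing; chromosome-X genes are tested in females
only. Skipped genes and reasons are returned alongside the results.

At realistic rare-carrier counts (~100 carriers in 20,000 samples) the Wald
test is mildly conservative: across 20,000 simulated null genes the z-score
standard deviation is ≈ 0.98 and the empirical P < 0.05 rate ≈ 0.048, with
inflation λ ≈ 1.0 and p-values passing a Kolmogorov–Smirnov uniformity
test. Calibration experiments therefore pool several independently
simulated cohorts — z-scores of genes scanned against a shared phenotype
vector are weakly correlated, which would otherwise inflate the Monte-Carlo
variance of the rejection-rate estimate beyond its binomial value.

## Meta-analysis

`z_M = Σ_j w_j z_j / √(Σ_j w_j²)`; the denominator sums the squared weights
— the only reading under which `z_M` is standard normal for any positive
weights — and the statistic is invariant to rescaling all weights. Anchor
weights require every anchor z-score to be positive in every study (an
anchor that fails to replicate cannot calibrate anything) and, with several
anchor genes, use the ratio of summed z-scores, which reduces to the
single-gene ratio rule. Genes absent from a study are combined over the
available studies with that study's weight dropped and flagged
(`all_studies = False`). Inflation λ is median(z²) divided by the χ²(1df)
median (0.45494); ranked-list export sorts by descending z with
lexicographic tie-breaks so output is deterministic.

## FRR decomposition

Single-gene contribution, for risk-allele frequency `p` and carrier
relative risk `e^β` under dominance:

    λ_j = 1 + p(e^β − 1)² / (2p(e^β − 1) + 1)²,   λ = 1 + Σ_j (λ_j − 1).

Recessive effects are ignored; contributions are additive across genes.
The formula is validated against a Monte-Carlo family oracle: probands
carry at frequency `2p`, a first-degree relative shares a transmitted
allele with probability ½ and otherwise carries at the population carrier
frequency, and both are affected with probability `K·e^β·carrier` (capped
at 1). This transmission model is a sibling-like approximation — the exact
parent-offspring complement probability would be the allele frequency
rather than the carrier frequency — and agrees with λ_j to first order in
`p`, the regime (p ≤ 0.005, OR ≤ 5) in which the 5%-relative-error oracle
check applies. The baseline lifetime risk `K` is a free parameter
(default 0.10, a round value of the right order for female breast cancer);
λ_j itself does not depend on `K`.

Effect-size mixture: `P(assoc) = α`, `β | assoc ~ Exp(η)`. The per-gene
evidence is by default a normal likelihood on the empirical log-OR from the
2×2 carrier table (0.5 continuity correction when any cell is zero, Woolf
variance), whose mixture marginal is closed-form:

    ∫₀^∞ N(β̂; β, s²) η e^{−ηβ} dβ = η exp(η²s²/2 − ηβ̂) Φ(β̂/s − ηs),

cross-checked against adaptive quadrature to 1e-8 relative. The alternative
`likelihood="binomial"` uses the exact conditional likelihood of the 2×2
table (Fisher's noncentral hypergeometric given the carrier total), which
removes the nuisance carrier frequency without approximation; the prior
integral is then taken numerically on the same fixed rule. The summed log
marginal is maximized over (α, η) by bounded L-BFGS-B from five
deterministic starts (α from 1e-4 to 0.2, η from 0.5 to 8); the fit is
seedless and deterministic.

Posterior quantities use a fixed 256-node Gauss–Legendre rule on
β ∈ [0, 5] (OR up to ~148; posterior mass beyond is negligible whenever
per-gene standard errors are below ~1). Per-gene FRR contributions are
`E[λ_j − 1 | data] = P(assoc | data) · E_post[λ(p_adj, β) − 1]`, and a gene
set's percentage share is `100 · Σ E[λ_j − 1] / (λ_obs − 1)` with the
observed first-degree FRR defaulting to λ_obs = 2.0, the conventional
breast-cancer value; it is configurable because the right denominator is a
property of the disease, not of the data being fitted.

Frequencies `p_j` come from cases and controls combined,
`(a+b)/(2(n1+n0))`, plus the structural-variant allele frequency (additive:
SV and PTV carriers are disjoint rare events to first order). In balanced
designs with strong effects the combined estimator is biased upward by case
enrichment; `controls_only_freq=True` switches to `b/(2n0)`, and the
truth-based validation scenarios use it for exactly that reason.

A caution on the exponential prior: for η ≤ 2 the implied OR distribution
has infinite second moment, so simulated datasets drawn from the prior
occasionally contain genes with enormous ORs whose λ_j legitimately
dominates the total. Truth-based FRR checks therefore plant genes with
fixed, moderate ORs instead of drawing them from the prior.

## Synthetic cohorts

Disease follows a logistic model with intercept logit(K) and per-carrier
log-ORs summed over genes; carriers are generated directly as 0/1
indicators (the analysis collapses to carrier status anyway; allele
frequency = carrier_freq/2 under the rare-variant approximation). Family
history comes from one simulated relative per proband (transmission model
above) plus an independent background rate (default 0.05) representing
non-genetic family history. Study ascertainment (family-history and
early-onset oversampling) is rejection sampling of cases with acceptance
weights proportional to the oversampling multipliers. Covariates — ten
principal components, country, library preparation, sex — are noise with
zero true effect by default, so covariate-adjusted scans can be checked for
calibration; subtype markers (ER/PR/HER2) are assigned to cases only at
fixed marginal rates, and an optional youth-specific log-OR supports
age-restricted scan tests.

What the generator does *not* emulate: linkage disequilibrium, diploid
genotypes and de-novo calling artifacts, age-at-onset hazards, polygenic
background, and covariate confounding (available but off by default).
Passing tests therefore demonstrate the statistical machinery — collapsing,
weighting, combination, mixture fitting — under the model's own
assumptions, not robustness to real-data artifacts such as batch-structured
missingness (which the missingness report is designed to surface, not fix).

## Problem sizes and numerical conventions

Default validation sizes are chosen to give tight Monte-Carlo error at
desk scale: 2×10⁶ proband-relative pairs for the FRR oracle, five
independent cohorts of 1,000 null genes at 10,000 cases / 10,000 controls
(carrier frequency 0.005) for scan calibration, and 5,000 genes at
50,000/50,000 with carrier frequency 1e-3 for mixture recovery, where the
fitted α is reproducibly within ±0.02 of 0.05 and η within ±30% of 2.0.
All floating-point output is written at six significant digits so pipeline
reruns are byte-identical; every run writes a manifest with the
configuration hash, seed and per-file checksums. Exit codes of the CLI:
0 success, 1 validation error, 2 runtime error.
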