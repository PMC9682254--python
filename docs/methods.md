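# Methods

## The CFR statistic

The package quantifies the balance between cytotoxic infiltrate and
fibrotic stroma in a bulk tumor expression profile.  Each cell
population is represented by a marker-gene signature scored per sample
with single-sample gene set enrichment (ssGSEA), and the CD8+ T cell /
cancer-associated fibroblast ratio (CFR) is

    CFR_j = ES_j(CD8 signature) − ES_j(CAF signature),

a *difference*, not a quotient: enrichment scores are already on a
common bounded scale after normalization, and a difference remains
stable when either score is near zero.  The same construction applied
to any immune cell type is called an ICFR.  For immunohistochemistry
data the CFR is the *ratio* of CD8-stained to α-SMA-stained area
(areas from multiple regions of one sample are summed before the ratio
is formed; a sample with zero CAF area is unevaluable, never infinite).
The two functional forms are deliberate and recorded in every result
object (`form` field), because the score-space and area-space
quantities are not interchangeable.

## ssGSEA scoring

For sample *j*, all *G* genes are ranked by expression.  Walking the
genes from highest to lowest, the enrichment score of signature *S*
accumulates the difference between the weighted running fraction of
signature genes seen so far (gene weights are ascending expression
midranks raised to α, default α = 0.25) and the unweighted running
fraction of non-signature genes:

    ES(S, j) = Σ_i [ P_in^w(i) − P_out(i) ].

Numerical choices:

* **Ties.**  Tied expression values receive midranks, and the walk
  order within a tie block is alphabetical by gene symbol.  Scores are
  therefore deterministic, independent of input row order, and defined
  even for a constant expression column.
* **Normalization.**  By default every ES in a score table is divided
  by the global range max(ES) − min(ES) over all samples and
  signatures (the usual cross-sample convention); a per-signature range
  mode is a flag.  Normalization is skipped with a warning when the
  range is degenerate.  Because the divisor depends on the whole table,
  CFR values from separate scoring runs are not comparable; cohorts
  must be scored jointly.
* **Coverage.**  Signature genes absent from the matrix are dropped
  (never zero-filled) and a matched/total coverage report is always
  emitted.  A signature with fewer than two matched genes yields an
  all-missing column plus an error-level log entry; a signature
  covering every gene has no out-of-set ECDF and is an error.
* **Missing values.**  A gene missing in a sample is excluded from that
  sample's ranking only, with a logged count.  Rank methods admit no
  natural imputation, and silent imputation would bias the ES.

ES is a rank statistic, so it is invariant to any strictly increasing
per-sample transform; whether the input is TPM or log-TPM is
immaterial, and `fpkm_to_tpm` / `log2_transform` exist for
interpretability and interface parity rather than necessity.  The
composite immune score is the ssGSEA ES of a broad immune
meta-signature (default: the union of the immune-cell signatures; the
published ESTIMATE immune gene list may be substituted).

## Gene signatures

The built-in registry holds 24 immune-cell signatures, the 8-gene
MCP-counter CAF panel, and a 36-gene CD8 T-cell list.  The CD8 list is
shipped verbatim after removing exact duplicates — legacy symbols
(C4orf15, MYST3, SFRS7, …) are **not** modernized, because scoring is
exact identifier matching and silent symbol updating would change
scores irreproducibly; users needing alias handling apply their own
mapping before scoring.  Matching is case-sensitive.  The 23 immune
lists other than CD8 are synthetic curated stand-ins (canonical lineage
markers; see `_synthetic_bindea_standins.py`), adequate for pipeline
runs and tests but configurable input rather than ground truth — a
reference set should be loaded from GMT for any reproduction of
published scores.

## Survival-optimal dichotomization

A continuous marker is dichotomized by maximally selected rank
statistics: every observed marker value whose split keeps both groups
inside a quantile band (default 10–90%, equivalently a 10% minimum
group fraction) is a candidate; the standardized two-group log-rank
statistic is computed for each; the cut maximizing |z| wins, with ties
broken toward the candidate nearest the marker median.  The selection
maximizes over many correlated tests, so the naive log-rank p-value is
anticonservative; the reported `p_approx` is the Lausen–Schumacher
improved-Bonferroni bound for the supremum of a standardized Brownian
bridge over the searched band.  That approximation is itself
anticonservative at small n, so a seeded permutation p-value
(marker permuted, maximal |z| recomputed) is available.  Boundary
convention: a value exactly at the cut is "low" — arbitrary but fixed.
The scan is invariant under strictly increasing marker transforms.

The four-class comparator crosses two independently selected cutpoints
(CD8 and CAF) into CD8^hi/lo × CAF^hi/lo labels with the same boundary
convention.  Immune-infiltration clusters use k-means (k = 3,
k-means++, 50 restarts, fixed recorded seed) on the immune score
matrix, relabeled high/medium/low by descending cluster mean score.

## Survival and association statistics

Kaplan–Meier, log-rank, and Cox models are computed with lifelines.
Cox fits use the Efron tie correction (the standard modern default)
with Newton–Raphson convergence tightened to effectively machine
precision; monotone likelihood (perfect separation) and non-convergence
are reported as errors with diagnostics.  The median-survival CI comes
from inverting the survival curve's log-log (Greenwood) confidence
band.  All times are months; a median the curve never reaches is
reported as not-reached.

The association battery fixes conventions the analyses depend on:

* Spearman correlation CI by Fisher z with the rank-correlation
  variance correction (1 + ρ²/2)/(n − 3).
* Mann–Whitney U (normal approximation with tie correction; exact
  method available), Wilcoxon signed-rank for paired data,
  Kruskal–Wallis above two groups.
* Contingency tests select their method as a pure function of the
  counts: Fisher's exact when the table is 2×2 and any expected count
  < 1 or n < 20; Yates-corrected chi-square for 2×2 with any expected
  count < 5; plain chi-square otherwise.  Fisher beyond 2×2 is not
  offered; wider sparse tables fall back to chi-square.
* ORR = (CR+PR)/n, DCR = (CR+PR+SD)/n as proportions; rounding to the
  percent scale happens only at the reporting layer (one decimal).
* ROC AUC is the Mann–Whitney statistic U/(n₁n₀) with ties counted ½.
* Biomarker combination is a maximum-likelihood logistic model; perfect
  separation is an error, not a divergent fit.
* Mutation enrichment runs a per-gene 2×2 Fisher test with
  Benjamini–Hochberg adjustment (the only multiple-testing procedure
  offered); genes mutated in no sample are skipped with a note.

## Synthetic cohorts

The generator draws per-sample latent CD8 and CAF infiltration
fractions from a bivariate Gaussian (default correlation ρ = 0.4)
mapped through the logistic function so fractions live in (0, 1).
Signature-gene expression is baseline + β·(latent fraction) + Gaussian
noise, floored at zero (β = 2, noise SD = 1, baseline = 5); all immune
cell types share the CD8 latent as a common immune-infiltration axis,
CAF genes follow the CAF latent, and 5 000 background genes carry noise
only — signature blocks stay a small fraction of the genome, as in a
real transcriptome.  Survival is Weibull proportional hazards (shape 1
= exponential, scale 12 months) with log hazard −γ·d for latent CFR
d = a_CD8 − a_CAF (γ = 2, protective) and uniform administrative
censoring on (0, 36) months.  Response is Bernoulli with log odds
η₀ + η₁·d + η_tps·t (η₀ = −1 so the baseline response rate is ≈ 27%,
η₁ = 3), where t is an independent PD-L1/TPS axis — predictive of
response but uncorrelated with CFR, so biomarker combination has
something to gain.  Responders are labeled PR; non-responders split
SD/PD 60/40.  One global seed drives deterministically spawned
substreams; identical configs give bit-identical cohorts.  The
tumor-type panel draws independent cohorts whose latent CD8 mean varies
across types and an ORR from a binomial whose probability is a monotone
link of the type's mean latent CFR.

What the generator does *not* emulate: real gene-level expression
distributions, batch effects, signature co-expression beyond the
two-latent model, or cohort-specific censoring patterns.  Passing
recovery tests therefore demonstrates that the pipeline extracts the
structure it assumes, not that real cohorts satisfy those assumptions.
One attenuation is worth knowing: because ssGSEA is competitive
(signature vs all other genes), the measured CAF-score-vs-immune-score
correlation is systematically smaller than the latent ρ — large immune
blocks rising push CAF gene ranks down.  The latent correlation is the
generator's knob; the score-level correlation is an output.

## Problem sizes and calibration checks

The statistical validation suite uses: 200 random small matrices
(≤ 20 genes) against a step-by-step ECDF-difference oracle at 1e-10;
50 monotone-transform/permutation invariance cases; cutpoint recovery
on 100 change-point cohorts of n = 400 (hazard ratio 0.4 above the
60th marker percentile, recovery required inside the 50th–70th
percentile band in ≥ 90%); log-rank type-I error on 2 000 null
replicates of n = 200 (0.05 ± 0.01); Cox recovery over 50 replicates of
n = 500 (mean log-HR within ±0.1 of log 0.5) plus grid-search equality
of the Efron partial likelihood on a tied toy dataset; and 50-seed
end-to-end runs at the generator defaults (protective γ: dichotomized
CFR must give HR < 1 with CI excluding 1 in ≥ 90%; γ = 0: a
prespecified median split must reject at ≈ α — the null calibration
deliberately does *not* reuse the optimized cutpoint, whose naive
log-rank p is anticonservative by construction; the optimized analysis
reports the corrected `p_approx` instead).

## Known limitations

* No batch correction: multi-batch inputs must be corrected upstream.
* No GSVA/PLAGE/z-score kernels, stromal/purity scores, or
  deconvolution; no MAF/VCF parsing (mutations enter as a binary
  matrix); no time-varying covariates or competing risks.
* Cross-cohort CFR values are only comparable when the cohorts are
  scored in one invocation (global normalization).
* The cohort summary table of the clinical validation dataset is taken
  as authoritative where its prose disagrees with it (the prose says
  "54 patients (72%) were male" against the table's 44 (72%) of 61,
  and gives inverted TPS percentages); the package recomputes from the
  table's counts and makes no attempt to guess the prose's intent.
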