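# cfratio

Tumor-microenvironment scoring and the **CD8+ T cell / cancer-associated
fibroblast ratio (CFR)** — a single-number biomarker of the balance
between cytotoxic infiltrate and fibrotic stroma in bulk tumor
expression profiles, built for prognostic and immunotherapy-response
stratification.

Cancer-associated fibroblasts (CAFs) restrict T-cell trafficking into
tumor islands and suppress cytotoxic function, so two tumors with the
same CD8+ T-cell content can respond very differently to checkpoint
blockade depending on their stromal context.  `cfratio` quantifies both
populations per sample with single-sample gene set enrichment (ssGSEA)
and forms

```
CFR_j = ES_j(CD8 signature) − ES_j(CAF signature)
```

(in score space; for immunohistochemistry, the CD8/α-SMA stained-area
ratio).  The same construction for any immune cell type is an ICFR.
Cohorts are dichotomized at a survival-optimal cutpoint by maximally
selected rank statistics, and the downstream battery covers
Kaplan–Meier / log-rank / Cox models, RECIST response rates, logistic
biomarker combination with ROC AUC, and per-gene mutation enrichment.
A synthetic cohort generator with known latent infiltration fractions
makes the whole pipeline testable end to end without any data download.

Intended users: computational oncologists and biostatisticians working
with bulk RNA-seq / array cohorts (genes × samples matrices, GMT
signatures, tab-separated clinical tables) or quantified IHC areas.

## Worked example

The `cfratio` command chains the stages; every stage writes a manifest
(parameters, seed, output checksums) so runs are reproducible.

```
$ cfratio simulate --out-dir cohort --seed 11 --n-samples 200
wrote synthetic cohort (200 samples) to cohort

$ cfratio score --expression cohort/expression.tsv \
                --gmt cohort/signatures.gmt --out-dir scores
scored 25 signatures x 200 samples

$ cfratio stratify --scores scores/scores.tsv \
                   --clinical cohort/clinical.tsv --out-dir strat
cutpoint -0.3431; groups low/high = (20, 180)

$ cfratio survive --scores scores/scores.tsv \
                  --clinical cohort/clinical.tsv --out-dir surv
CFR HR (high vs low) = 0.30
```

Reading the output: the scoring step produced 24 immune-cell columns
plus a CAF column of normalized enrichment scores.  `stratify` scanned
the observed CFR values (inside the 10–90% quantile band) for the split
maximizing the standardized log-rank statistic; `strat/cutpoint.json`
records the selected cut (−0.343), the maximal statistic (5.06) and its
selection-corrected p-value (2.4e-05).  `survive` then fits a Cox model
to the dichotomized CFR: this cohort was generated with a protective
latent CFR, and the pipeline recovers a hazard ratio of 0.30 — high-CFR
patients die at less than a third of the low-CFR rate.  The forest
table `surv/forest.tsv` holds one row per immune-cell score and per
ICFR (marker, cutpoint, HR, CI, p) for forest-plot rendering.

The response battery compares RECIST outcomes across CFR groups and
combines CFR with PD-L1 TPS in a logistic model:

```
$ cfratio response --labels strat/labels.tsv --clinical cohort/clinical.tsv \
                   --cfr strat/cfr.tsv --out-dir resp
```

`resp/response.json` from the run above reports ORR 40.6% (high) vs
30.0% (low) and AUCs of 0.609 (CFR), 0.716 (TPS) and 0.753 (combined)
— the combination dominates either marker alone, as expected when both
carry independent signal.

The same functions are importable directly
(`cfratio.ssgsea_score`, `cfratio.optimal_cutpoint`, `cfratio.cox_fit`,
…) for use in notebooks and scripts.

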