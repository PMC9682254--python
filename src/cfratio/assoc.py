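"""Non-survival association battery for biomarker evaluation.

Correlation (Spearman with Fisher-z interval), rank-based group
comparisons, RECIST response rates (ORR/DCR), contingency tests with a
fixed chi-square / Yates / Fisher selection rule, the logistic
CFR + PD-L1 combiner, non-parametric ROC AUC, and per-gene mutation
enrichment with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")


@dataclass
class SpearmanResult:
    rho: float
    ci_lower: float
    ci_upper: float
    p: float
    n: int


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str


def spearman(x, y, ci_level: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    The interval uses the rank-correlation variance correction
    (1 + rho^2 / 2) / (n - 3) on the z scale (Bonett-Wright); the p-value
    is the usual t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    z = np.arctanh(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    se = np.sqrt((1 + rho**2 / 2) / (n - 3))
    zq = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = np.tanh(z - zq * se), np.tanh(z + zq * se)
    return SpearmanResult(rho=float(rho), ci_lower=float(lo), ci_upper=float(hi),
                          p=float(p), n=n)


def group_difference(values, labels, paired: bool = False, method: str = "asymptotic") -> TestResult:
    """Rank-based comparison of a continuous variable across groups.

    Two unpaired groups: Mann-Whitney U (normal approximation with tie
    correction by default; ``method="exact"`` for small tie-free
    samples).  Paired two-group data: Wilcoxon signed-rank.  More than
    two groups: Kruskal-Wallis.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    parts = [values[labels == g] for g in groups]
    if any(p.size == 0 for p in parts):
        raise ValueError("every group must be non-empty")

    if paired:
        if len(groups) != 2 or parts[0].size != parts[1].size:
            raise ValueError("paired comparison needs exactly 2 groups of equal length")
        stat, p = stats.wilcoxon(parts[0], parts[1])
        return TestResult(float(stat), float(p), "wilcoxon-signed-rank")
    if len(groups) == 2:
        res = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided", method=method)
        return TestResult(float(res.statistic), float(res.pvalue), "mann-whitney-u")
    stat, p = stats.kruskal(*parts)
    return TestResult(float(stat), float(p), "kruskal-wallis")


def response_rates(responses, groups=None) -> pd.DataFrame:
    """RECIST response counts and rates per group plus an overall row.

    ORR = (CR + PR) / n and DCR = (CR + PR + SD) / n, reported as
    proportions in [0, 1]; rounding to the printed percent convention is
    a concern of the reporting layer only.
    """
    responses = pd.Series(responses, name="response").reset_index(drop=True)
    if responses.empty:
        raise ValueError("empty response table")
    bad = set(responses.dropna()) - set(RECIST_CATEGORIES)
    if bad:
        raise ValueError(f"invalid RECIST categories: {sorted(bad)}")
    groups = (pd.Series(["overall"] * len(responses)) if groups is None
              else pd.Series(groups, name="group").reset_index(drop=True))

    def _one(resp: pd.Series) -> dict:
        counts = resp.value_counts()
        n = int(resp.notna().sum())
        row = {c: int(counts.get(c, 0)) for c in RECIST_CATEGORIES}
        row["n"] = n
        row["orr"] = (row["CR"] + row["PR"]) / n if n else np.nan
        row["dcr"] = (row["CR"] + row["PR"] + row["SD"]) / n if n else np.nan
        return row

    rows = {}
    for g in pd.unique(groups.dropna()):
        rows[g] = _one(responses[groups == g])
    rows["overall"] = _one(responses)
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    for c in [*RECIST_CATEGORIES, "n"]:
        out[c] = out[c].astype(int)
    return out


def contingency_test(table) -> TestResult:
    """Chi-square / Yates / Fisher test of a 2 x C count table.

    Method selection is a fixed function of the counts: for 2 x 2
    tables, Fisher's exact test when any expected count < 1 or total
    n < 20; the continuity-corrected (Yates) chi-square when any expected
    count < 5; otherwise the plain chi-square.  Wider tables use the
    plain chi-square.  The chosen method is recorded in the result.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x C count table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    n = table.sum()
    if n == 0:
        raise ValueError("all-zero table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if table.shape == (2, 2):
        if (expected < 1).any() or n < 20:
            odds, p = stats.fisher_exact(table.astype(int))
            return TestResult(float(odds), float(p), "fisher-exact")
        if (expected < 5).any():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
            return TestResult(float(chi2), float(p), "chi-square-yates")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(p), "chi-square")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit (intercept included)."""

    coef: pd.Series
    se: pd.Series
    p: pd.Series
    predicted: pd.Series                # per-sample P(response = 1)
    deviance: float
    null_deviance: float


def logistic_combiner(response, predictors) -> LogisticFit:
    """Logistic model combining biomarkers (e.g. CFR + PD-L1 TPS).

    Fits by iteratively reweighted least squares / Newton; perfect
    separation is reported as an error rather than returning divergent
    coefficients.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(response, dtype=float)
    if not np.isin(y, [0, 1]).all():
        raise ValueError("response must be 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame(predictors).reset_index(drop=True).astype(float)
    X = sm.add_constant(X, prepend=True)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(f"perfect separation: {exc}") from exc
    pred = fit.predict(X)
    if np.max(np.abs(fit.params.iloc[1:])) > 50:
        raise ValueError("perfect (or quasi-perfect) separation: diverging coefficients")
    return LogisticFit(
        coef=fit.params, se=fit.bse, p=fit.pvalues,
        predicted=pd.Series(pred, name="p_response"),
        deviance=float(-2 * fit.llf), null_deviance=float(-2 * fit.llnull),
    )


def roc_auc(score, label) -> float:
    """Non-parametric AUC: Mann-Whitney U / (n1 * n0), ties counted 1/2."""
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    if not np.isin(label, [0, 1]).all():
        raise ValueError("labels must be 0/1")
    n1 = int((label == 1).sum())
    n0 = int((label == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)           # ascending midranks
    u = ranks[label == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def mutation_enrichment(mm: pd.DataFrame, labels, top_k: int | None = None) -> pd.DataFrame:
    """Per-gene mutation enrichment between two groups (Fisher + BH).

    ``mm`` is a binary genes x samples indicator matrix.  Each gene gets
    a 2 x 2 Fisher exact test of mutated/wild-type against group, an odds
    ratio, and a Benjamini-Hochberg q-value across all tested genes.
    Genes mutated in no sample are skipped with a note.  Output is sorted
    by p; ``top_k`` truncates for reporting.
    """
    from statsmodels.stats.multitest import multipletests

    labels = pd.Series(labels).reset_index(drop=True)
    groups = pd.unique(labels.dropna())
    if len(groups) != 2:
        raise ValueError("mutation enrichment needs exactly 2 groups")
    vals = mm.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("mutation matrix must be binary 0/1")
    g1 = (labels == groups[0]).to_numpy()
    g2 = (labels == groups[1]).to_numpy()

    rows = []
    for gene, row in zip(mm.index, vals):
        if row.sum() == 0:
            logger.info("gene %r mutated in no sample; skipped", gene)
            continue
        a, b = int(row[g1].sum()), int(g1.sum() - row[g1].sum())
        c, d = int(row[g2].sum()), int(g2.sum() - row[g2].sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append({"gene": gene, f"mut_{groups[0]}": a, f"mut_{groups[1]}": c,
                     "odds_ratio": odds, "p": p})
    if not rows:
        raise ValueError("no gene is mutated in any sample")
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values("p", kind="stable")
    return out.head(top_k) if top_k is not None else out


def cfr_orr_correlation(cfr_by_tumor, orr_by_tumor) -> tuple[SpearmanResult, dict]:
    """Spearman correlation of per-tumor-type mean CFR against ORR.

    Inputs are keyed by tumor type (Series or single-column frames); the
    statistic is computed on the inner join, and a join report lists the
    matched and dropped keys.
    """
    cfr = pd.Series(cfr_by_tumor).dropna()
    orr = pd.Series(orr_by_tumor).dropna()
    matched = cfr.index.intersection(orr.index)
    report = {
        "n_matched": len(matched),
        "unmatched_cfr": sorted(set(cfr.index) - set(matched)),
        "unmatched_orr": sorted(set(orr.index) - set(matched)),
    }
    if len(matched) < 4:
        raise ValueError(f"only {len(matched)} matched tumor types; need >= 4")
    res = spearman(cfr.loc[matched].to_numpy(), orr.loc[matched].to_numpy())
    return res, report
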