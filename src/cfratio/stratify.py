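"""CFR/ICFR computation and survival-driven cohort stratification.

The CD8+ T cell / CAF ratio is deliberately dual-form: in ssGSEA score
space it is the *difference* of the two enrichment scores (scores are
already on a common bounded scale, and a difference is stable when either
score is near zero); for immunohistochemistry it is the *ratio* of
CD8-positive to alpha-SMA-positive area.  Both forms are recorded in
:class:`CfrResult` so downstream reports can state which was used.

Dichotomization uses maximally selected rank statistics: every observed
marker value inside a feasible quantile band is a candidate cutpoint, the
standardized two-group log-rank statistic is computed for the split at
each candidate, and the cut maximizing |statistic| is selected.  Because
the maximum is taken over many correlated statistics, the naive log-rank
p-value is anticonservative; the reported ``p_approx`` uses the
Lausen-Schumacher improved Bonferroni bound, and a seeded permutation
p-value is available for small cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

FOUR_CLASS_LABELS = ("CD8hiCAFhi", "CD8loCAFhi", "CD8hiCAFlo", "CD8loCAFlo")


@dataclass
class CfrResult:
    """Per-sample CFR values with their components and functional form."""

    cfr: pd.Series                      # indexed by sample id; NaN = unevaluable
    form: str                           # "score-difference" | "area-ratio"
    components: pd.DataFrame | None = None  # e.g. cd8_score / caf_score columns

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cfr.index)

    def write(self, path) -> None:
        out = pd.DataFrame({"cfr": self.cfr})
        if self.components is not None:
            out = self.components.join(out)
        out.insert(0, "form", self.form)
        out.to_csv(path, sep="\t", index_label="sample")


@dataclass
class Cutpoint:
    """A survival-optimal marker cutpoint and its selection statistics."""

    value: float
    statistic: float                    # standardized log-rank statistic at the optimum
    p_approx: float                     # improved-Bonferroni approximation
    candidate_range: tuple[float, float]  # quantile band searched
    group_sizes: tuple[int, int]        # (n at or below cut, n above)
    p_permutation: float | None = None

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "statistic": self.statistic,
            "p_approx": self.p_approx,
            "candidate_range": list(self.candidate_range),
            "group_sizes": list(self.group_sizes),
            "p_permutation": self.p_permutation,
        }


@dataclass
class StratifiedCohort:
    """Per-sample group labels under one stratification scheme."""

    labels: pd.Series                   # categorical, indexed by sample id
    scheme: str                         # cfr-dichotomy | four-class | infiltration-kmeans
    cutpoints: dict[str, Cutpoint] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def write(self, path) -> None:
        out = pd.DataFrame({"label": self.labels})
        out.insert(0, "scheme", self.scheme)
        out.to_csv(path, sep="\t", index_label="sample")


# ------------------------------------------------------------------ CFR

def compute_icfr(scores, immune_cell: str, caf: str = "CAF") -> CfrResult:
    """Immune cell / CAF ratio in score space: score(cell) - score(CAF)."""
    table = scores.scores if hasattr(scores, "scores") else scores
    for name in (immune_cell, caf):
        if name not in table.columns:
            raise KeyError(f"signature column {name!r} not present in score table")
        if table[name].isna().all():
            raise ValueError(f"signature column {name!r} is all-missing")
    components = pd.DataFrame({
        "cd8_score": table[immune_cell],
        "caf_score": table[caf],
    })
    return CfrResult(cfr=table[immune_cell] - table[caf], form="score-difference",
                     components=components)


def compute_ihc_cfr(areas: pd.DataFrame) -> CfrResult:
    """CFR from stained areas: (CD8 area / total) / (CAF area / total).

    ``areas`` needs columns ``cd8_area``, ``caf_area``, ``total_area``
    and a sample identifier as index or a ``sample`` column.  Multiple
    rows per sample (regions) are summed before the ratio is formed —
    sum-then-ratio, not an average of per-region ratios.  A sample whose
    summed CAF area is zero is unevaluable (CFR is missing, never
    infinite).
    """
    a = areas.copy()
    if "sample" in a.columns:
        a = a.set_index("sample")
    needed = {"cd8_area", "caf_area", "total_area"}
    if not needed.issubset(a.columns):
        raise ValueError(f"area table needs columns {sorted(needed)}")
    if (a["total_area"] <= 0).any():
        raise ValueError("total_area must be > 0 for every region")
    if ((a["cd8_area"] < 0) | (a["cd8_area"] > a["total_area"])).any():
        raise ValueError("cd8_area must lie in [0, total_area]")
    if ((a["caf_area"] < 0) | (a["caf_area"] > a["total_area"])).any():
        raise ValueError("caf_area must lie in [0, total_area]")

    summed = a.groupby(level=0, sort=False)[["cd8_area", "caf_area", "total_area"]].sum()
    cd8_frac = summed["cd8_area"] / summed["total_area"]
    caf_frac = summed["caf_area"] / summed["total_area"]
    with np.errstate(divide="ignore", invalid="ignore"):
        cfr = cd8_frac / caf_frac
    unevaluable = summed["caf_area"] == 0
    if unevaluable.any():
        logger.warning("%d sample(s) with zero CAF area flagged unevaluable",
                       int(unevaluable.sum()))
        cfr[unevaluable] = np.nan
    comp = pd.DataFrame({"cd8_score": cd8_frac, "caf_score": caf_frac})
    return CfrResult(cfr=cfr, form="area-ratio", components=comp)


# ------------------------------------------------- log-rank scan machinery

def _logrank_z(times: np.ndarray, events: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (O - E) / sqrt(V).

    ``times`` must be sorted ascending; ``in_group`` marks membership of
    group 1 in that order.  Variance is the usual hypergeometric form at
    each distinct event time.
    """
    ome, var = _logrank_ome_var(times, events, in_group)
    return ome / np.sqrt(var) if var > 0 else 0.0


def _logrank_ome_var(times, events, in_group):
    n = times.size
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        return 0.0, 0.0
    lo = np.searchsorted(times, ev_times, side="left")
    n_at_risk = n - lo
    # events per distinct event time, overall and within group 1
    bins = np.searchsorted(ev_times, times)
    is_ev = events == 1
    d = np.bincount(bins[is_ev], minlength=ev_times.size)
    d1 = np.bincount(bins[is_ev & in_group], minlength=ev_times.size)
    cum_g = np.concatenate([[0], np.cumsum(in_group)])
    n1_at_risk = in_group.sum() - cum_g[lo]
    frac = n1_at_risk / n_at_risk
    ome = float(np.sum(d1 - d * frac))
    denom = np.maximum(n_at_risk - 1, 1)
    var = float(np.sum(d * frac * (1 - frac) * (n_at_risk - d) / denom))
    return ome, var


def _scan_statistics(marker, times, events, candidates):
    """|z| of the log-rank split at each candidate cut (marker <= c)."""
    order = np.argsort(times, kind="stable")
    t_s, e_s, m_s = times[order], events[order], marker[order]
    zs = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        zs[i] = _logrank_z(t_s, e_s, m_s <= c)
    return zs


def _maxsel_p_approx(b: float, eps_low: float, eps_high: float) -> float:
    """Improved Bonferroni bound for the maximally selected statistic.

    Approximates P(sup |standardized Brownian bridge| >= b) over the
    quantile band (eps_low, eps_high); anticonservative at small n, which
    is why a permutation alternative exists.
    """
    if b <= 1.0:  # bound is vacuous below 1; report 1
        return 1.0
    phi = norm.pdf(b)
    span = np.log((eps_high * (1 - eps_low)) / ((1 - eps_high) * eps_low))
    p = phi * (b - 1.0 / b) * span + 4.0 * phi / b
    return float(min(max(p, 0.0), 1.0))


def optimal_cutpoint(
    marker,
    time,
    event,
    quantile_range: tuple[float, float] = (0.1, 0.9),
    n_permutations: int = 0,
    seed: int | None = None,
) -> Cutpoint:
    """Survival-optimal dichotomization by maximally selected rank statistics.

    Candidates are the observed marker values whose split keeps both
    groups inside ``quantile_range`` (default: each group at least 10% of
    the cohort).  Ties in |statistic| are broken toward the candidate
    nearest the marker median.  With ``n_permutations`` > 0 a seeded
    permutation p-value of the maximal statistic is also computed.
    """
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = marker.size
    if not (time.size == n and event.size == n):
        raise ValueError("marker, time and event must have equal length")
    if event.sum() < 2:
        raise ValueError("need at least 2 events to select a cutpoint")
    if np.unique(marker).size < 2:
        raise ValueError("no admissible cutpoint: marker is constant")

    q_low, q_high = quantile_range
    sorted_m = np.sort(marker)
    n_min = int(np.ceil(q_low * n))
    n_max = n - int(np.ceil((1 - q_high) * n))
    # cut at c puts rank(c) samples in the low group; admissible cuts keep
    # n_low in [n_min, n_max)
    uniq = np.unique(marker)
    n_low = np.searchsorted(sorted_m, uniq, side="right")
    candidates = uniq[(n_low >= max(n_min, 1)) & (n_low <= min(n_max, n - 1)) & (n_low < n)]
    if candidates.size == 0:
        raise ValueError("no admissible cutpoint inside the quantile range")

    zs = np.abs(_scan_statistics(marker, time, event, candidates))
    best = np.flatnonzero(zs == zs.max())
    if best.size > 1:
        med = np.median(marker)
        best = best[np.argmin(np.abs(candidates[best] - med))]
    else:
        best = best[0]
    value = float(candidates[best])
    stat = float(zs[best])
    n_lo = int(np.sum(marker <= value))
    p_approx = _maxsel_p_approx(stat, q_low, q_high)

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(marker)
            z_perm = np.abs(_scan_statistics(perm, time, event, candidates))
            if z_perm.max() >= stat:
                exceed += 1
        p_perm = (1 + exceed) / (n_permutations + 1)

    return Cutpoint(
        value=value,
        statistic=stat,
        p_approx=p_approx,
        candidate_range=(q_low, q_high),
        group_sizes=(n_lo, n - n_lo),
        p_permutation=p_perm,
    )


# ------------------------------------------------------------ labelling

def dichotomize(cfr: CfrResult, cut: Cutpoint) -> StratifiedCohort:
    """Label each sample high (cfr > cut) or low (cfr <= cut)."""
    labels = pd.Series(
        np.where(cfr.cfr > cut.value, "high", "low"), index=cfr.cfr.index, name="label"
    )
    labels[cfr.cfr.isna()] = np.nan
    counts = labels.value_counts()
    if len(counts.index.intersection(["high", "low"])) < 2:
        logger.warning("degenerate split: all evaluable samples fall on one side of the cut")
    return StratifiedCohort(labels=labels, scheme="cfr-dichotomy", cutpoints={"cfr": cut})


def four_class(cd8_scores, caf_scores, cd8_cut: Cutpoint, caf_cut: Cutpoint) -> StratifiedCohort:
    """Cross-classify by independent CD8 and CAF cutpoints.

    Labels are CD8hi/lo x CAFhi/lo; "hi" means strictly above the
    marker's own cutpoint (same boundary convention as dichotomize).
    """
    cd8 = pd.Series(cd8_scores)
    caf = pd.Series(caf_scores, index=cd8.index)
    cd8_hi = cd8 > cd8_cut.value
    caf_hi = caf > caf_cut.value
    labels = pd.Series(
        np.where(cd8_hi, np.where(caf_hi, "CD8hiCAFhi", "CD8hiCAFlo"),
                 np.where(caf_hi, "CD8loCAFhi", "CD8loCAFlo")),
        index=cd8.index, name="label",
    )
    return StratifiedCohort(labels=labels, scheme="four-class",
                            cutpoints={"cd8": cd8_cut, "caf": caf_cut})


def infiltration_clusters(scores, k: int = 3, seed: int = 0, n_init: int = 50) -> StratifiedCohort:
    """K-means immune-infiltration clusters, relabeled by mean immune level.

    Clusters the samples on the immune-cell score matrix and renames the
    clusters high / medium / low (k = 3; otherwise c1..ck) by descending
    cluster mean of the per-sample mean score.  Deterministic for a fixed
    seed; k-means++ with ``n_init`` restarts.
    """
    from sklearn.cluster import KMeans

    table = scores.scores if hasattr(scores, "scores") else pd.DataFrame(scores)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of samples ({table.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assign = km.fit_predict(table.to_numpy())
    overall = table.mean(axis=1).to_numpy()
    cluster_means = [overall[assign == c].mean() for c in range(k)]
    order = np.argsort(cluster_means)[::-1]  # descending immune level
    if k == 3:
        names = ["high", "medium", "low"]
    elif k == 1:
        names = ["all"]
    else:
        names = [f"c{i + 1}" for i in range(k)]
    rename = {int(c): names[rank] for rank, c in enumerate(order)}
    labels = pd.Series([rename[int(c)] for c in assign], index=table.index, name="label")
    return StratifiedCohort(labels=labels, scheme="infiltration-kmeans")
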