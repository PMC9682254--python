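"""Single-sample gene set enrichment (ssGSEA) and the composite immune score.

For one sample, genes are walked from highest to lowest expression and an
enrichment score (ES) accumulates the difference between two running
fractions: the weighted fraction of signature genes seen so far (weights
are the genes' ascending expression midranks raised to ``alpha``) and the
unweighted fraction of non-signature genes seen so far,

    ES(S, j) = sum_i [ P_in^w(i) - P_out(i) ].

ES is therefore a rank statistic: it is invariant to any strictly
increasing transform of a sample's expression vector and to row order of
the input matrix.  ``alpha = 0.25`` is the conventional weighting
exponent.  With ``normalize`` on, every ES in the table is divided by the
global range (max ES - min ES over all samples and signatures), the usual
cross-sample normalization; a per-signature range mode is available.

Ties in expression receive midranks, and the walk order within a tie
block is by gene symbol, so scores are deterministic and independent of
input row order even with ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cfratio.signatures import GeneSignature, SignatureRegistry

logger = logging.getLogger(__name__)


def rank_with_ties(values) -> np.ndarray:
    """Descending ranks with midranks for ties (1 = largest value)."""
    return rankdata(-np.asarray(values, dtype=float), method="average")


@dataclass
class ScoreTable:
    """samples x signatures enrichment scores plus scoring parameters.

    ``coverage`` maps signature name -> (genes matched in the matrix,
    genes in the signature); signatures with fewer than two matched genes
    are present as all-NaN columns.
    """

    scores: pd.DataFrame
    alpha: float
    normalized: bool
    norm_mode: str = "global"
    coverage: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)

    def __getitem__(self, signature: str) -> pd.Series:
        return self.scores[signature]

    def write(self, path, sidecar_path=None) -> None:
        """Tab-separated scores; optional JSON sidecar of params/coverage."""
        self.scores.to_csv(path, sep="\t", index_label="sample")
        if sidecar_path is not None:
            import json

            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "alpha": self.alpha,
                        "normalized": self.normalized,
                        "norm_mode": self.norm_mode,
                        "coverage": {k: list(v) for k, v in self.coverage.items()},
                    },
                    fh,
                    indent=2,
                )


def _sample_es(expr: np.ndarray, members: np.ndarray, alpha: float) -> np.ndarray:
    """ES for every signature (rows of ``members``) in one sample.

    ``expr`` must already be ordered so that a stable descending sort
    breaks expression ties deterministically (callers sort genes by
    symbol first).  NaN expression values are excluded from the ranking.
    """
    ok = ~np.isnan(expr)
    expr = expr[ok]
    members = members[:, ok]
    g = expr.size
    order = np.argsort(-expr, kind="stable")
    weights = rankdata(expr, method="average") ** alpha
    w_perm = weights[order]
    m_perm = members[:, order]

    in_w = np.cumsum(m_perm * w_perm, axis=1)
    total_in_w = in_w[:, -1][:, None]
    n_in = members.sum(axis=1)
    n_out = (g - n_in)[:, None]
    out_frac = np.cumsum(~m_perm, axis=1) / np.where(n_out == 0, 1, n_out)
    es = (in_w / np.where(total_in_w == 0, 1, total_in_w) - out_frac).sum(axis=1)
    es[n_in < 2] = np.nan
    return es


def ssgsea_score(
    m: pd.DataFrame,
    reg: SignatureRegistry,
    alpha: float = 0.25,
    normalize: bool = True,
    norm_mode: str = "global",
) -> ScoreTable:
    """Score every signature in ``reg`` for every sample of ``m``.

    Signature genes absent from the matrix are dropped (count logged); a
    signature with fewer than two matched genes yields an all-NaN column
    and an error-level log entry; a signature covering every gene of the
    matrix is an error because the non-signature running fraction is
    undefined.  A gene with a missing value in some sample is excluded
    from that sample's ranking only.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if norm_mode not in ("global", "per-signature"):
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    if m.index.duplicated().any():
        raise ValueError("duplicate gene ids; collapse_duplicate_genes first")

    m = m.sort_index(kind="stable")  # symbol order breaks expression ties
    gene_ids = m.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)

    names = reg.names
    members = np.zeros((len(names), n_genes), dtype=bool)
    coverage: dict[str, tuple[int, int]] = {}
    for si, name in enumerate(names):
        sig = reg[name]
        matched = [gene_pos[g] for g in sig.genes if g in gene_pos]
        coverage[name] = (len(matched), len(sig))
        dropped = len(sig) - len(matched)
        if dropped:
            logger.warning("signature %r: %d/%d genes absent from matrix, dropped",
                           name, dropped, len(sig))
        if len(matched) < 2:
            logger.error("signature %r: fewer than 2 genes matched; scores set to missing", name)
        if len(matched) == n_genes:
            raise ValueError(f"signature {name!r} covers every gene in the matrix")
        members[si, matched] = True

    vals = m.to_numpy(dtype=float)
    if np.isnan(vals).any():
        logger.warning("%d missing expression values excluded from per-sample rankings",
                       int(np.isnan(vals).sum()))
    scores = np.empty((m.shape[1], len(names)))
    for j in range(m.shape[1]):
        scores[j] = _sample_es(vals[:, j], members, alpha)

    table = pd.DataFrame(scores, index=list(m.columns), columns=names)
    normalized = False
    if normalize:
        if norm_mode == "global":
            rng = np.nanmax(scores) - np.nanmin(scores)
            rngs = rng
        else:
            rngs = table.max() - table.min()
            rng = np.min(np.asarray(rngs)) if len(names) else 0.0
        if not np.all(np.asarray(rng) > 0):
            logger.warning("degenerate ES range; normalization skipped")
        else:
            table = table / rngs
            normalized = True
    return ScoreTable(scores=table, alpha=alpha, normalized=normalized,
                      norm_mode=norm_mode, coverage=coverage)


def immune_score(
    m: pd.DataFrame,
    immune_meta_signature: GeneSignature,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.Series:
    """Composite immune-infiltration score of a broad immune gene set.

    The score is the ssGSEA ES of the supplied meta-signature (by default
    callers pass the union of the immune-cell signatures, built with
    ``SignatureRegistry.union_signature``; the published immune gene list
    of the ESTIMATE method may be substituted).
    """
    reg = SignatureRegistry()
    reg.add(immune_meta_signature)
    table = ssgsea_score(m, reg, alpha=alpha, normalize=normalize)
    return table[immune_meta_signature.name]
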