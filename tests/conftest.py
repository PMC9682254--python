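import numpy as np
import pandas as pd
import pytest

from cfratio.signatures import GeneSignature, SignatureRegistry


def naive_ssgsea_es(expr: dict[str, float], sig_genes: set[str], alpha: float) -> float:
    """Independent step-by-step ssGSEA oracle.

    Materializes both running fractions explicitly: genes are walked from
    highest to lowest expression (ties broken by gene symbol), each
    signature gene contributes its ascending midrank raised to ``alpha``
    to the weighted in-set ECDF, each non-signature gene contributes one
    count to the out-of-set ECDF, and the ES is the sum of the running
    differences.
    """
    genes = sorted(expr, key=lambda g: (-expr[g], g))
    values = list(expr.values())

    def asc_midrank(v: float) -> float:
        below = sum(1 for x in values if x < v)
        tied = sum(1 for x in values if x == v)
        return below + (tied + 1) / 2

    total_in = sum(asc_midrank(expr[g]) ** alpha for g in genes if g in sig_genes)
    total_out = sum(1 for g in genes if g not in sig_genes)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for g in genes:
        if g in sig_genes:
            cum_in += asc_midrank(expr[g]) ** alpha
        else:
            cum_out += 1
        es += cum_in / total_in - cum_out / total_out
    return es


def random_matrix_and_registry(rng: np.random.Generator, max_genes: int = 20,
                               max_sigs: int = 5, allow_ties: bool = False):
    """A small random expression matrix plus random signatures over its genes."""
    g = int(rng.integers(5, max_genes + 1))
    s = int(rng.integers(1, max_sigs + 1))
    n = int(rng.integers(1, 4))
    genes = [f"g{i:02d}" for i in range(g)]
    vals = rng.uniform(0, 100, size=(g, n))
    if allow_ties:
        vals = np.round(vals, 0)
    m = pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(n)])
    reg = SignatureRegistry()
    for k in range(s):
        size = int(rng.integers(2, g))  # never all genes
        members = list(rng.choice(genes, size=size, replace=False))
        reg.add(GeneSignature(f"sig{k}", members))
    return m, reg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """6 genes x 2 samples; sample A strictly decreasing down the rows."""
    return pd.DataFrame(
        {
            "A": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            "B": [1.0, 4.0, 2.0, 6.0, 3.0, 5.0],
        },
        index=[f"g{i}" for i in range(6)],
    )
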