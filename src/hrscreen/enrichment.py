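"""Category over-representation among screen hits.

Fold enrichment is (k/n) / (K/N): the fraction of hits annotated to a
category over the fraction of the background universe so annotated. The
significance of over-representation is the exact upper-tail hypergeometric
probability P(X >= k) for drawing n genes from a universe of N containing K
category members. Benjamini–Hochberg adjustment across categories is applied
by default (with an off switch), since fixed-cut-off screens typically test
many categories at once.

The background universe is an explicit required input — enrichment against
"all screened genes" and "the genome" are different questions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ScreenError


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # hits in category
    n: int  # hits
    K: int  # universe genes in category
    N: int  # universe size
    fold: float
    p_hyper: float


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ScreenError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N); undefined when the category or hit list is empty."""
    if n == 0 or K == 0:
        raise ScreenError(f"fold enrichment undefined for n={n}, K={K}")
    return (k / n) / (K / N)


def enrich_category(
    hits: Iterable[str],
    annotation: Mapping[str, set[str] | frozenset[str]],
    category: str,
    universe: Iterable[str],
) -> EnrichmentResult:
    """Enrichment of one category among ``hits`` against ``universe``."""
    universe = set(universe)
    hits = set(hits)
    if not hits <= universe:
        raise ScreenError(f"hits outside the universe: {sorted(hits - universe)[:5]}")
    in_cat = {g for g in universe if category in annotation.get(g, ())}
    k = len(hits & in_cat)
    n, K, N = len(hits), len(in_cat), len(universe)
    return EnrichmentResult(
        category=category, k=k, n=n, K=K, N=N,
        fold=fold_enrichment(k, n, K, N),
        p_hyper=hypergeometric_p(k, n, K, N),
    )


def enrichment_table(
    hits: Iterable[str],
    annotation: Mapping[str, set[str] | frozenset[str]],
    universe: Iterable[str],
    categories: Sequence[str] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Enrichment of every (or the given) categories, BH-adjusted by default."""
    universe = set(universe)
    hits = set(hits)
    if categories is None:
        categories = sorted({c for g in universe for c in annotation.get(g, ())})
    results = [enrich_category(hits, annotation, c, universe) for c in categories]
    df = pd.DataFrame([vars(r) for r in results])
    if adjust and len(df):
        df["p_adjusted"] = benjamini_hochberg(df["p_hyper"].tolist())
    return df.sort_values("p_hyper").reset_index(drop=True)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH-adjusted p-values (monotone, idempotent on already-adjusted input)."""
    if len(pvalues) == 0:
        return []
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(p) for p in adjusted]
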