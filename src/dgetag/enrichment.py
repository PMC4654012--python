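"""Hypergeometric over-representation of DE gene sets in annotation terms.

Annotations are consumed as given term -> gene-set maps (GO-style or pathway
style); no ontology propagation is performed.  For a background of N genes of
which K carry a term, and n DE genes of which k carry it, the enrichment
p-value is the upper hypergeometric tail P(X >= k).  Q-values are
Benjamini–Hochberg across the testable terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Set, Tuple

import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_fdr


@dataclass
class TermMap:
    """term_id -> (term_name, gene set)."""

    terms: Dict[str, Tuple[str, Set[str]]]

    def __len__(self) -> int:
        return len(self.terms)

    @classmethod
    def from_pairs(cls, rows: Iterable[Tuple[str, str, str]]) -> "TermMap":
        """Build from (term_id, term_name, gene_id) rows, one row per pair."""
        terms: Dict[str, Tuple[str, Set[str]]] = {}
        for term_id, term_name, gene_id in rows:
            if term_id not in terms:
                terms[term_id] = (term_name, set())
            terms[term_id][1].add(gene_id)
        return cls(terms)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    de_genes: Set[str],
    background: Set[str],
    terms: TermMap,
    p_max: float = 0.05,
    q_max: float | None = 0.05,
) -> pd.DataFrame:
    """One record per testable term, sorted by p-value.

    Terms are intersected with the background first; terms left empty are
    dropped before multiple testing.  A term is flagged significant when
    p <= p_max and (if ``q_max`` is given) q <= q_max.
    """
    stray = de_genes - background
    if stray:
        raise ValueError(f"DE genes outside the background: {sorted(stray)[:10]}")

    N = len(background)
    n = len(de_genes)
    rows = []
    for term_id, (name, genes) in terms.terms.items():
        in_bg = genes & background
        if not in_bg:
            continue
        K = len(in_bg)
        k = len(in_bg & de_genes)
        rows.append((term_id, name, k, K, n, N, hypergeom_pvalue(k, K, n, N)))

    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"])
        df["significant"] = (df["p_value"] <= p_max) & (
            True if q_max is None else df["q_value"] <= q_max
        )
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        df["q_value"] = []
        df["significant"] = []
    return df
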