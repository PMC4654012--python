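"""Audic–Claverie two-library test for tag counts, FDR control, DE calling.

A gene contributing x tags among N1 in library 1 is modeled as Poisson; the
posterior-predictive distribution of its count y among N2 tags in library 2
is then

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

a negative-binomial form that integrates the Poisson mean out under a flat
prior.  The two-sided p-value doubles the smaller of the lower-tail sum
S = sum_{i<=y} p(i|x) and its complement 1-S, capped at 1.  This convention
is exactly symmetric under exchanging the two libraries, because
sum_{i<=y} p(i|x; N1,N2) + sum_{i<=x} p(i|y; N2,N1) = 1 (a regularized
incomplete-beta identity), and it yields p = 1 whenever x = y and N1 = N2.

Differential expression is called at FDR <= 0.001 together with
|log2 ratio| >= 1 of the two TPM values.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionTable

#: smallest reportable p-value; results live in (0, 1]
_TINY = 5e-324


def _log_pmf(i: np.ndarray, x: int, N1: float, N2: float) -> np.ndarray:
    r = N2 / N1
    return (
        i * math.log(r)
        + gammaln(x + i + 1.0)
        - gammaln(x + 1.0)
        - gammaln(i + 1.0)
        - (x + i + 1.0) * math.log1p(r)
    )


def ac_pmf(i: int, x: int, N1: float, N2: float) -> float:
    """Predictive probability p(i|x) of observing i tags in library 2."""
    if i < 0 or x < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    return float(np.exp(_log_pmf(np.asarray([i], dtype=float), x, N1, N2))[0])


def _lower_tail(x: int, y: int, N1: float, N2: float) -> float:
    logs = _log_pmf(np.arange(y + 1, dtype=float), x, N1, N2)
    return float(np.exp(logsumexp(logs)))


def _upper_tail_strict(x: int, y: int, N1: float, N2: float) -> float:
    """sum_{i>y} p(i|x) by direct block summation (used when 1-S underflows)."""
    total = 0.0
    i0 = y + 1
    block = 1024
    while True:
        i = np.arange(i0, i0 + block, dtype=float)
        terms = np.exp(_log_pmf(i, x, N1, N2))
        total += float(terms.sum())
        # past the mode the terms decay geometrically; stop once negligible
        if terms[-1] < 1e-18 * max(total, 1e-300) and i0 > x * N2 / N1:
            return total
        i0 += block


def ac_pvalue(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided equality p-value for counts x (library 1) vs y (library 2).

    p = 2 * min(S, 1 - S) with S = sum_{i=0}^{y} p(i|x), capped into (0, 1].
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    S = _lower_tail(x, y, N1, N2)
    if S <= 0.5:
        p = 2.0 * S
    else:
        # computing 1-S by subtraction loses digits; sum the tail directly
        p = 2.0 * min(_upper_tail_strict(x, y, N1, N2), 0.5)
    return float(min(max(p, _TINY), 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


UP = "up"
DOWN = "down"
NOT_DE = "not_de"


def call_de(
    expr1: ExpressionTable,
    expr2: ExpressionTable,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    pseudo_tpm: float = 0.001,
) -> pd.DataFrame:
    """Per-gene two-library test with the joint FDR / log2-ratio calling rule.

    Genes absent from both libraries (x = y = 0) are excluded from testing
    and called not_de; the multiple-testing family is the tested set.  TPM
    values are floored at ``pseudo_tpm`` before the log2 ratio so that genes
    detected in only one library get large finite ratios.  Positive ratios
    mean higher expression in ``expr2``.
    """
    g1, g2 = list(expr1.data.index), list(expr2.data.index)
    if g1 != g2:
        raise ValueError("expression tables cover different gene universes")

    x = expr1.counts.to_numpy()
    y = expr2.counts.to_numpy()
    N1, N2 = expr1.library_size, expr2.library_size
    tpm1 = expr1.tpm.to_numpy()
    tpm2 = expr2.tpm.to_numpy()
    log2_ratio = np.log2(np.maximum(tpm2, pseudo_tpm) / np.maximum(tpm1, pseudo_tpm))

    tested = (x + y) >= 1
    pvals = np.ones(len(x))
    for i in np.flatnonzero(tested):
        pvals[i] = ac_pvalue(int(x[i]), int(y[i]), N1, N2)

    fdr = np.ones(len(x))
    if tested.any():
        fdr[tested] = bh_fdr(pvals[tested])

    call = np.full(len(x), NOT_DE, dtype=object)
    sig = tested & (fdr <= fdr_max) & (np.abs(log2_ratio) >= min_abs_log2)
    call[sig & (log2_ratio > 0)] = UP
    call[sig & (log2_ratio < 0)] = DOWN

    return pd.DataFrame(
        {
            "count1": x,
            "count2": y,
            "tpm1": tpm1,
            "tpm2": tpm2,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
            "fdr": fdr,
            "tested": tested,
            "call": call,
        },
        index=expr1.data.index,
    )
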