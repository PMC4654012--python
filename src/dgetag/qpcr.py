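"""Relative qPCR quantification (2^-ddCt) and concordance with DGE ratios.

Each gene x condition is summarized by its mean threshold cycle (Ct) over
technical replicates; dCt normalizes to a housekeeping reference gene within
the same condition, ddCt to the calibrator condition, and the fold change is
2^-ddCt (amplification efficiency fixed at 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = ["gene", "condition", "replicate", "ct"]


def ddct(table: pd.DataFrame, reference_gene: str, calibrator: str) -> pd.DataFrame:
    """Per gene x condition fold changes by the 2^-ddCt method.

    ``table`` has columns gene, condition, replicate, ct.  The reference gene
    must be measured in every condition; the calibrator condition has fold 1
    for every gene by construction.
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    mean_ct = table.groupby(["gene", "condition"])["ct"].mean()
    conditions = sorted(table["condition"].unique())
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} absent from table")
    for cond in conditions:
        if (reference_gene, cond) not in mean_ct.index:
            raise ValueError(f"reference gene {reference_gene!r} missing in condition {cond!r}")

    rows = []
    genes = [g for g in table["gene"].unique() if g != reference_gene]
    for gene in genes:
        dct = {}
        for cond in conditions:
            if (gene, cond) in mean_ct.index:
                dct[cond] = mean_ct[(gene, cond)] - mean_ct[(reference_gene, cond)]
        if calibrator not in dct:
            continue
        for cond, d in dct.items():
            dd = d - dct[calibrator]
            rows.append((gene, cond, d, dd, 2.0 ** (-dd)))
    return pd.DataFrame(
        rows, columns=["gene", "condition", "delta_ct", "delta_delta_ct", "fold"]
    )


def concordance(folds: pd.DataFrame, de: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Direction agreement between qPCR folds and DGE log2 ratios, per gene.

    ``folds`` is a ddct() result; ``de`` a call_de() result indexed by gene.
    A gene is concordant when sign(log2 fold) equals sign(log2_ratio).
    """
    sub = folds[folds["condition"] == condition]
    shared = [g for g in sub["gene"] if g in de.index]
    if not shared:
        raise ValueError("no shared genes between qPCR panel and DGE results")
    rows = []
    for gene in shared:
        fold = float(sub.loc[sub["gene"] == gene, "fold"].iloc[0])
        qdir = np.sign(np.log2(fold))
        ddir = np.sign(de.loc[gene, "log2_ratio"])
        rows.append((gene, fold, float(de.loc[gene, "log2_ratio"]), qdir == ddir))
    out = pd.DataFrame(rows, columns=["gene", "qpcr_fold", "dge_log2_ratio", "concordant"])
    out.attrs["fraction_concordant"] = float(out["concordant"].mean())
    return out
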