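"""Per-gene expression tables (unambiguous tag counts, TPM) and saturation curves."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .index import ANTISENSE, SENSE, VirtualTagIndex
from .mapping import UNIQUE_GENE, MappingTable, TagAssignment, map_tags, unambiguous_assignments
from .qc import TagLibrary


@dataclass
class ExpressionTable:
    """Unambiguous sense tag counts and TPM for one library.

    TPM(g) = 1e6 * count(g) / library_size, where ``library_size`` is the
    library's total clean tag count (the normalization denominator).
    Antisense counts are reported alongside but never enter TPM or any
    downstream differential test.
    """

    library_name: str
    data: pd.DataFrame  # index: gene_id; columns: count, tpm, antisense_count
    library_size: int

    @property
    def counts(self) -> pd.Series:
        return self.data["count"]

    @property
    def tpm(self) -> pd.Series:
        return self.data["tpm"]


def quantify(
    assignments: Sequence[TagAssignment],
    clean: TagLibrary,
    index: VirtualTagIndex,
    denominator: str = "clean_total",
) -> ExpressionTable:
    """Sum unambiguous tag copies per gene and normalize to TPM.

    ``denominator`` selects the TPM normalizer: "clean_total" (all clean tags
    of the library, the default) or "unambiguous" (unambiguously mapped
    copies only).
    """
    sense: Dict[str, int] = {}
    anti: Dict[str, int] = {}
    for a in assignments:
        if a.multiplicity != UNIQUE_GENE:
            raise ValueError(f"ambiguous assignment for tag {a.tag!r}")
        g = a.gene_ids[0]
        bucket = sense if a.strand == SENSE else anti
        bucket[g] = bucket.get(g, 0) + a.copy_number

    genes = index.gene_ids
    counts = np.array([sense.get(g, 0) for g in genes], dtype=np.int64)
    anti_counts = np.array([anti.get(g, 0) for g in genes], dtype=np.int64)
    if denominator == "clean_total":
        n = clean.total_tags
    elif denominator == "unambiguous":
        n = int(counts.sum() + anti_counts.sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    tpm = np.zeros(len(genes)) if n == 0 else 1e6 * counts / n
    df = pd.DataFrame(
        {"count": counts, "tpm": tpm, "antisense_count": anti_counts},
        index=pd.Index(genes, name="gene_id"),
    )
    return ExpressionTable(clean.name, df, n)


@dataclass
class SaturationCurve:
    library_name: str
    data: pd.DataFrame  # columns: subsample_size, genes_detected
    seed: int


def saturation_curve(
    clean: TagLibrary,
    index: VirtualTagIndex,
    grid: Sequence[int],
    seed: int,
) -> SaturationCurve:
    """Detected-gene count as a function of sequencing depth.

    Tags are copy-expanded, shuffled once under ``seed``, and prefixes of the
    shuffled sequence are taken at each grid size, so subsamples are nested
    and the curve is monotone non-decreasing by construction.  A gene counts
    as detected when at least one of its tags maps unambiguously (either
    strand).
    """
    grid = sorted(int(s) for s in grid)
    total = clean.total_tags
    if grid and grid[-1] > total:
        raise ValueError(f"grid size {grid[-1]} exceeds library total {total}")

    # resolve each distinct tag once; a tag contributes its gene iff unambiguous
    tags = list(clean.counts)
    table = map_tags(clean, index)
    tag_gene = {
        a.tag: a.gene_ids[0] for a in table.assignments if a.multiplicity == UNIQUE_GENE
    }
    tag_idx = np.repeat(
        np.arange(len(tags)), np.fromiter((clean.counts[t] for t in tags), dtype=np.int64)
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(tag_idx)

    detected: set = set()
    rows: List[tuple] = []
    pos = 0
    for s in grid:
        for i in tag_idx[pos:s]:
            g = tag_gene.get(tags[i])
            if g is not None:
                detected.add(g)
        pos = s
        rows.append((s, len(detected)))
    return SaturationCurve(
        clean.name, pd.DataFrame(rows, columns=["subsample_size", "genes_detected"]), seed
    )
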