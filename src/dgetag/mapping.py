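"""Strand-aware tag-to-gene mapping with 1-mismatch tolerance.

Every clean tag is resolved against the virtual index: exact hash lookup
first, and only if that fails, a lookup of all 63 single-substitution
neighbors.  A perfect hit therefore strictly outranks a 1-mismatch hit, and
the two tiers are disjoint categories, as in classic DGE mapping reports.
Tags whose winning-tier origins span several genes are "ambiguous" and are
kept for accounting but excluded from expression counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Set, Tuple

import pandas as pd

from .index import ANTISENSE, SENSE, TAG_LEN, VirtualTagIndex, pct
from .qc import TagLibrary

PERFECT = "perfect"
ONE_MISMATCH = "one_mismatch"
UNMAPPED = "unmapped"

UNIQUE_GENE = "unique_gene"
MULTI_GENE = "multi_gene"
NONE = "none"

_BASES = "ACGT"


def hamming_neighbors(tag: str) -> Iterator[str]:
    """All 3·len(tag) single-substitution neighbors (the tag itself excluded).

    Substitutions are generated at every position, including the CATG anchor:
    a sequencing error can hit any base of the observed tag.
    """
    for i, b in enumerate(tag):
        for alt in _BASES:
            if alt != b:
                yield tag[:i] + alt + tag[i + 1 :]


@dataclass
class TagAssignment:
    tag: str
    copy_number: int
    match_tier: str
    strand: str
    multiplicity: str
    gene_ids: List[str]

    @property
    def is_mapped(self) -> bool:
        return self.match_tier != UNMAPPED


@dataclass
class MappingTable:
    library_name: str
    assignments: List[TagAssignment]
    n_genes: int
    n_both_strand: int = 0  # winning-tier origins on both strands (labeled sense)

    def mapped(self) -> List[TagAssignment]:
        return [a for a in self.assignments if a.is_mapped]


def map_tags(
    clean: TagLibrary, index: VirtualTagIndex, max_mismatch: int = 1
) -> MappingTable:
    """Assign every clean tag to its best-tier reference hits.

    Strand tie-break: when a tag's winning-tier origins include both strands
    the assignment is labeled sense and tallied in ``n_both_strand``.
    """
    if max_mismatch > 1:
        raise ValueError("only 0 or 1 mismatches are supported")

    assignments: List[TagAssignment] = []
    n_both = 0
    for tag, copies in clean.counts.items():
        origins = index.lookup(tag)
        tier = PERFECT
        if not origins and max_mismatch >= 1:
            origins = []
            for nb in hamming_neighbors(tag):
                origins.extend(index.lookup(nb))
            tier = ONE_MISMATCH if origins else UNMAPPED
        elif not origins:
            tier = UNMAPPED

        if not origins:
            assignments.append(
                TagAssignment(tag, copies, UNMAPPED, NONE, NONE, [])
            )
            continue

        genes = sorted({o.gene_id for o in origins})
        strands = {o.strand for o in origins}
        if strands == {SENSE, ANTISENSE}:
            n_both += 1
        strand = SENSE if SENSE in strands else ANTISENSE
        mult = UNIQUE_GENE if len(genes) == 1 else MULTI_GENE
        assignments.append(TagAssignment(tag, copies, tier, strand, mult, genes))

    return MappingTable(clean.name, assignments, index.n_genes, n_both)


def unambiguous_assignments(table: MappingTable) -> List[TagAssignment]:
    """The assignments counted toward gene expression: single-gene hits only."""
    return [a for a in table.assignments if a.multiplicity == UNIQUE_GENE]


# (tier, strand, multiplicity) rows in display order
_CATEGORIES = [
    (PERFECT, SENSE, UNIQUE_GENE),
    (PERFECT, SENSE, MULTI_GENE),
    (ONE_MISMATCH, SENSE, UNIQUE_GENE),
    (ONE_MISMATCH, SENSE, MULTI_GENE),
    (PERFECT, ANTISENSE, UNIQUE_GENE),
    (PERFECT, ANTISENSE, MULTI_GENE),
    (ONE_MISMATCH, ANTISENSE, UNIQUE_GENE),
    (ONE_MISMATCH, ANTISENSE, MULTI_GENE),
]


def mapping_summary(table: MappingTable, n_genes: int | None = None) -> pd.DataFrame:
    """Genes reached per tier × strand × multiplicity category, plus aggregates.

    Each row reports the number of distinct genes receiving at least one tag
    in that category and its percentage of the reference gene count.
    """
    if n_genes is None:
        n_genes = table.n_genes

    cat_genes: Dict[Tuple[str, str, str], Set[str]] = {c: set() for c in _CATEGORIES}
    strand_all: Dict[str, Set[str]] = {SENSE: set(), ANTISENSE: set()}
    strand_unamb: Dict[str, Set[str]] = {SENSE: set(), ANTISENSE: set()}
    all_genes: Set[str] = set()
    unamb_genes: Set[str] = set()

    for a in table.mapped():
        key = (a.match_tier, a.strand, a.multiplicity)
        cat_genes[key].update(a.gene_ids)
        strand_all[a.strand].update(a.gene_ids)
        all_genes.update(a.gene_ids)
        if a.multiplicity == UNIQUE_GENE:
            strand_unamb[a.strand].update(a.gene_ids)
            unamb_genes.update(a.gene_ids)

    rows = []
    labels = {
        (PERFECT, SENSE): "Perfect match (sense)",
        (ONE_MISMATCH, SENSE): "1 bp mismatch (sense)",
        (PERFECT, ANTISENSE): "Perfect match (antisense)",
        (ONE_MISMATCH, ANTISENSE): "1 bp mismatch (antisense)",
    }
    for tier, strand, mult in _CATEGORIES:
        what = "1 tag -> 1 gene" if mult == UNIQUE_GENE else "1 tag -> n gene"
        rows.append(
            (f"{labels[(tier, strand)]}: {what}", len(cat_genes[(tier, strand, mult)]))
        )
    rows += [
        ("All tag mapping to sense gene", len(strand_all[SENSE])),
        ("Unambiguous tag mapping to sense gene", len(strand_unamb[SENSE])),
        ("All tag mapping to antisense gene", len(strand_all[ANTISENSE])),
        ("Unambiguous tag mapping to antisense gene", len(strand_unamb[ANTISENSE])),
        ("All tag mapping to gene (sense and antisense)", len(all_genes)),
        ("Unambiguous tag mapping to gene (sense and antisense)", len(unamb_genes)),
    ]
    df = pd.DataFrame(rows, columns=["category", "n_genes"])
    df["pct_of_reference"] = [pct(n, n_genes) for n in df["n_genes"]]
    return df
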