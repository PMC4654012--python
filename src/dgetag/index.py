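"""Virtual reference-tag index.

Restriction-tag DGE profiling anchors every sequenced tag at an NlaIII
recognition site (``CATG``) followed by 17 bases, i.e. a 21-mer.  Before any
observed library can be interpreted, the reference transcriptome is turned
into a *virtual tag library*: every possible CATG+17 tag of every transcript,
on both the sense strand and its reverse complement, keyed by tag sequence so
that observed tags resolve to their gene(s) of origin by hash lookup.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

TAG_LEN = 21
ANCHOR = "CATG"

SENSE = "sense"
ANTISENSE = "antisense"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A reference transcript: unique id plus an uppercase A/C/G/T/N sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"transcript {self.id!r}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class TagOrigin:
    """One genomic origin of a reference tag.

    ``offset`` is the 0-based position of the first base of CATG on the
    indexed strand (for antisense origins, coordinates refer to the reverse
    complement of the transcript).
    """

    gene_id: str
    strand: str
    offset: int


def iter_catg_tags(seq: str) -> Iterator[Tuple[int, str]]:
    """Yield ``(offset, tag)`` for every CATG site with >= 17 downstream bases.

    Tags containing N are skipped: they cannot be matched in a 4-letter
    1-mismatch scheme.
    """
    start = 0
    while True:
        i = seq.find(ANCHOR, start)
        if i < 0:
            return
        if i + TAG_LEN <= len(seq):
            tag = seq[i : i + TAG_LEN]
            if "N" not in tag:
                yield i, tag
        start = i + 1


@dataclass
class VirtualTagIndex:
    """All reference tags of a transcript set, keyed by tag sequence."""

    entries: Dict[str, List[TagOrigin]] = field(default_factory=dict)
    gene_ids: List[str] = field(default_factory=list)
    n_genes: int = 0
    n_genes_with_site: int = 0
    n_tags_total: int = 0
    n_tags_unambiguous: int = 0

    def lookup(self, tag: str) -> List[TagOrigin]:
        return self.entries.get(tag, [])


def build_virtual_index(transcripts: Iterable[Transcript]) -> VirtualTagIndex:
    """Extract every CATG+17 reference tag from both strands of each transcript.

    Summary counts (tags total / unambiguous, genes with a site) are defined
    over sense-strand tags only; a tag is unambiguous when its sense origins
    all lie in a single gene.  A tag recurring at several offsets of one gene
    is one distinct tag and remains unambiguous: ambiguity is across genes.
    """
    entries: Dict[str, List[TagOrigin]] = defaultdict(list)
    gene_ids: List[str] = []
    seen = set()
    n_with_site = 0

    for tx in transcripts:
        if tx.id in seen:
            raise ValueError(f"duplicate transcript id {tx.id!r}")
        seen.add(tx.id)
        gene_ids.append(tx.id)

        has_site = False
        for off, tag in iter_catg_tags(tx.seq):
            entries[tag].append(TagOrigin(tx.id, SENSE, off))
            has_site = True
        for off, tag in iter_catg_tags(revcomp(tx.seq)):
            entries[tag].append(TagOrigin(tx.id, ANTISENSE, off))
        if has_site:
            n_with_site += 1

    n_total = 0
    n_unamb = 0
    for origins in entries.values():
        sense_genes = {o.gene_id for o in origins if o.strand == SENSE}
        if sense_genes:
            n_total += 1
            if len(sense_genes) == 1:
                n_unamb += 1

    return VirtualTagIndex(
        entries=dict(entries),
        gene_ids=gene_ids,
        n_genes=len(gene_ids),
        n_genes_with_site=n_with_site,
        n_tags_total=n_total,
        n_tags_unambiguous=n_unamb,
    )


def pct(num: float, den: float) -> float:
    """Percentage rounded half-away-from-zero to two decimals; NaN on a zero denominator."""
    if den == 0:
        return float("nan")
    x = 100.0 * num / den
    return float(int(abs(x) * 100 + 0.5) / 100.0 * (1 if x >= 0 else -1))


def index_summary(index: VirtualTagIndex) -> dict:
    """Headline statistics of a virtual index (sense-strand tags only)."""
    return {
        "n_genes": index.n_genes,
        "n_genes_with_site": index.n_genes_with_site,
        "pct_with_site": pct(index.n_genes_with_site, index.n_genes),
        "n_tags_total": index.n_tags_total,
        "n_tags_unambiguous": index.n_tags_unambiguous,
        "pct_unambiguous": pct(index.n_tags_unambiguous, index.n_tags_total),
    }
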