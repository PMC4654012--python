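"""Tag library QC: read-to-tag extraction, filtering, copy-number statistics.

A raw tag library is a multiset of 21-mer sequences.  Cleaning removes, in
order: tags containing N, adaptor/empty entries, low-complexity tags, and
tags seen only once (likely sequencing errors).  Every removal is recorded in
a ledger so that raw totals reconcile exactly with clean totals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

from .index import ANCHOR, TAG_LEN, pct

RAW = "raw"
CLEAN = "clean"

COPY_THRESHOLDS = (1, 5, 10, 20, 50, 100)


@dataclass
class TagLibrary:
    """A named multiset of 21-mer tags with copy numbers.

    ``adaptor_reads_*`` tally reads that never yielded a tag (adaptor-only /
    empty reads identified at extraction time); they are part of the raw read
    total but carry no tag sequence.
    """

    name: str
    counts: Dict[str, int] = field(default_factory=dict)
    stage: str = RAW
    adaptor_reads_distinct: int = 0
    adaptor_reads_total: int = 0

    @property
    def distinct_tags(self) -> int:
        return len(self.counts)

    @property
    def total_tags(self) -> int:
        return sum(self.counts.values())


@dataclass
class QCStats:
    """Table-style removal ledger for one library's cleaning pass.

    Each pair is (distinct, total).  ``copy_buckets[t]`` counts clean tags
    with copy number strictly greater than t.
    """

    name: str
    raw_distinct: int
    raw_total: int
    n_with_N: Tuple[int, int]
    n_adaptor: Tuple[int, int]
    n_low_complexity: Tuple[int, int]
    n_singleton: Tuple[int, int]
    clean_distinct: int
    clean_total: int
    copy_buckets: Dict[int, Tuple[int, int]]
    pct_distinct_over_total: float
    pct_high_copy_distinct: float

    def removed_total(self) -> int:
        return (
            self.n_with_N[1]
            + self.n_adaptor[1]
            + self.n_low_complexity[1]
            + self.n_singleton[1]
        )


def extract_tags(reads: Iterable[str], adaptor: str = "", name: str = "library") -> TagLibrary:
    """Reduce raw reads to their CATG+17 tags.

    The tag is the 21-mer starting at the first CATG at or after the adaptor
    prefix.  Reads with no such site, or too short to supply 17 bases after
    it, are tallied as adaptor/empty reads.
    """
    counts: Counter = Counter()
    adaptor_reads: Counter = Counter()
    start = len(adaptor)
    for read in reads:
        read = read.strip().upper()
        i = read.find(ANCHOR, start)
        if i < 0 or i + TAG_LEN > len(read):
            adaptor_reads[read] += 1
        else:
            counts[read[i : i + TAG_LEN]] += 1
    return TagLibrary(
        name=name,
        counts=dict(counts),
        stage=RAW,
        adaptor_reads_distinct=len(adaptor_reads),
        adaptor_reads_total=sum(adaptor_reads.values()),
    )


def is_low_complexity(tag: str, max_mono_fraction: float = 0.9) -> bool:
    """True when one nucleotide occupies >= ``max_mono_fraction`` of the tag."""
    if not tag:
        return False
    top = max(tag.count(b) for b in "ACGT")
    return top >= max_mono_fraction * len(tag)


def copy_number_distribution(clean: TagLibrary) -> Dict[int, Tuple[int, int]]:
    """(distinct, total) counts of tags with copy number > t for each threshold t."""
    buckets = {}
    for t in COPY_THRESHOLDS:
        d = sum(1 for c in clean.counts.values() if c > t)
        tot = sum(c for c in clean.counts.values() if c > t)
        buckets[t] = (d, tot)
    return buckets


def clean_library(
    raw: TagLibrary,
    min_copy: int = 2,
    low_complexity_fraction: Optional[float] = 0.9,
    require_catg_prefix: bool = True,
) -> Tuple[TagLibrary, QCStats]:
    """Apply the tag filters and return the clean library plus its QC ledger.

    Filter order: N-containing, adaptor/empty, low-complexity, then copy
    number < ``min_copy``.  Each removed tag is charged to the first rule it
    trips, so ledger totals partition the removed mass exactly.

    ``require_catg_prefix`` classifies a tag that does not begin with CATG as
    adaptor/empty; this is how adaptor content is recognized in pre-tabulated
    tag tables, where no read context exists.  Set ``low_complexity_fraction``
    to None to disable that rule.
    """
    kept: Dict[str, int] = {}
    n_N = [0, 0]
    n_adpt = [raw.adaptor_reads_distinct, raw.adaptor_reads_total]
    n_low = [0, 0]
    n_single = [0, 0]

    for tag, c in raw.counts.items():
        if "N" in tag:
            n_N[0] += 1
            n_N[1] += c
        elif require_catg_prefix and not tag.startswith(ANCHOR):
            n_adpt[0] += 1
            n_adpt[1] += c
        elif low_complexity_fraction is not None and is_low_complexity(
            tag, low_complexity_fraction
        ):
            n_low[0] += 1
            n_low[1] += c
        elif c < min_copy:
            n_single[0] += 1
            n_single[1] += c
        else:
            kept[tag] = c

    # removed reads are not carried forward, so cleaning is idempotent
    clean = replace(
        raw, counts=kept, stage=CLEAN, adaptor_reads_distinct=0, adaptor_reads_total=0
    )
    buckets = copy_number_distribution(clean)
    stats = QCStats(
        name=raw.name,
        raw_distinct=raw.distinct_tags + raw.adaptor_reads_distinct,
        raw_total=raw.total_tags + raw.adaptor_reads_total,
        n_with_N=tuple(n_N),
        n_adaptor=tuple(n_adpt),
        n_low_complexity=tuple(n_low),
        n_singleton=tuple(n_single),
        clean_distinct=clean.distinct_tags,
        clean_total=clean.total_tags,
        copy_buckets=buckets,
        pct_distinct_over_total=pct(clean.distinct_tags, clean.total_tags),
        pct_high_copy_distinct=pct(buckets[100][0], clean.distinct_tags),
    )
    return clean, stats
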