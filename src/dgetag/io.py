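"""File I/O: FASTA references, tag-count TSVs, term maps, Ct tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import TermMap
from .index import Transcript, VirtualTagIndex
from .qc import TagLibrary


def read_fasta(path: str | Path) -> List[Transcript]:
    """Multi-record FASTA; wrapped lines allowed, lowercase uppercased."""
    return [Transcript(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = [SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts]
    SeqIO.write(records, str(path), "fasta")


def read_tag_tsv(path: str | Path, name: str | None = None, stage: str = "raw") -> TagLibrary:
    """Tag-count TSV with columns ``tag`` and ``count``."""
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    if not {"tag", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'tag' and 'count'")
    return TagLibrary(
        name=name or Path(path).stem,
        counts=dict(zip(df["tag"], df["count"])),
        stage=stage,
    )


def write_tag_tsv(lib: TagLibrary, path: str | Path) -> None:
    pd.DataFrame(
        sorted(lib.counts.items()), columns=["tag", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_reads(path: str | Path) -> List[str]:
    """Plain read list (one sequence per line) or FASTQ (qualities ignored)."""
    path = Path(path)
    text = path.read_text().splitlines()
    if text and text[0].startswith("@"):
        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
    return [line.strip() for line in text if line.strip()]


def write_index_tsv(index: VirtualTagIndex, path: str | Path) -> None:
    rows = [
        (tag, o.gene_id, o.strand, o.offset)
        for tag, origins in sorted(index.entries.items())
        for o in origins
    ]
    pd.DataFrame(rows, columns=["tag", "gene_id", "strand", "offset"]).to_csv(
        path, sep="\t", index=False
    )


def read_term_map(path: str | Path) -> TermMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TermMap.from_pairs(df[["term_id", "term_name", "gene_id"]].itertuples(index=False))


def read_gene_list(path: str | Path) -> List[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_ct_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "condition": str})
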