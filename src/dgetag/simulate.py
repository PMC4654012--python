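"""Synthetic DGE study generator with a truth manifest.

Emulates a three-condition restriction-tag sequencing experiment: a random
reference transcriptome in which a configurable fraction of genes carries a
CATG site, per-condition tag libraries with spiked differential expression,
and matching annotation / qPCR fixtures.  Library chemistry is modeled after
the bead-bound 3' fragment protocol: each transcript molecule contributes
the tag of its 3'-most CATG site (or, with the incomplete-digestion
probability, a uniformly chosen upstream site).  Per-base substitution
errors, N-containing reads and adaptor-only reads corrupt the emitted tags
at configurable rates.  Every draw is recorded so downstream ledgers can be
reconciled exactly against the truth.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .index import ANCHOR, TAG_LEN, Transcript, iter_catg_tags, revcomp
from .qc import RAW, TagLibrary

_BASES = np.array(list("ACGT"))

#: 5' adaptor used in simulated reads; contains no CATG by construction
DEFAULT_ADAPTOR = "GTTCAGAGTTCTACAGTCCGAC"


@dataclass
class SimConfig:
    """Knobs of the synthetic study; the seed is mandatory.

    Defaults describe a desk-scale study: 2,000 genes, 62 % of them carrying
    a CATG site, three libraries (one control, two stress conditions) of
    5e5 tags each, 10 % of site-bearing genes spiked differentially expressed
    at 2-8x with condition-specific up/down splits.
    """

    seed: int
    n_genes: int = 2000
    length_log_mean: float = 6.6  # lognormal of transcript length, ~730 nt median
    length_log_sd: float = 0.45
    min_length: int = 100
    max_length: int = 8000
    catg_fraction: float = 0.62
    gc: float = 0.5
    conditions: Tuple[str, ...] = ("NC", "HS", "CS")
    control: str = "NC"
    depth: int = 500_000
    expression_log_sd: float = 1.0
    de_fraction: float = 0.10
    fold_range: Tuple[float, float] = (2.0, 8.0)
    up_fraction: Dict[str, float] = field(
        default_factory=lambda: {"HS": 0.59, "CS": 0.32}
    )
    error_rate: float = 0.001
    adaptor_rate: float = 0.005
    n_rate: float = 0.005
    incomplete_digestion: float = 0.05
    antisense_rate: float = 0.05
    adaptor_seq: str = DEFAULT_ADAPTOR
    ct_noise_sd: float = 0.15
    ct_replicates: int = 3

    def __post_init__(self):
        for name in (
            "catg_fraction",
            "de_fraction",
            "error_rate",
            "adaptor_rate",
            "n_rate",
            "incomplete_digestion",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.control not in self.conditions:
            raise ValueError("control condition must be among conditions")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# stable stream offsets so each stage draws from an independent substream
_STREAM_TRANSCRIPTOME = 0
_STREAM_TRUTH = 1
_STREAM_FIXTURES = 2
_STREAM_LIBRARY = 10  # + condition index


@dataclass
class TruthManifest:
    """Per-gene generative truth: Poisson rates, DE flags/folds, emitted counts."""

    data: pd.DataFrame  # indexed by gene_id
    conditions: Tuple[str, ...]
    control: str
    catg_genes: List[str]
    contaminants: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def de_genes(self, condition: str) -> Set[str]:
        return set(self.data.index[self.data[f"de_{condition}"]])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _strip_catg(seq: str, rng: np.random.Generator) -> str:
    """Mutate one base of every CATG occurrence until none remain."""
    s = list(seq)
    while True:
        i = "".join(s).find(ANCHOR)
        if i < 0:
            return "".join(s)
        # any base other than A at the second position destroys the site
        s[i + 1] = str(rng.choice(list("CGT")))


def _has_tag_site(seq: str) -> bool:
    return next(iter_catg_tags(seq), None) is not None


def make_transcriptome(config: SimConfig) -> List[Transcript]:
    """Random reference transcripts with an exact CATG-bearing fraction.

    The realized fraction of genes with at least one taggable site equals
    round(catg_fraction * n_genes) / n_genes: site-free genes are scrubbed of
    CATG occurrences, and a site is injected into any designated site-bearing
    gene that failed to acquire one by chance.
    """
    if config.catg_fraction > 0 and config.max_length < TAG_LEN:
        raise ValueError("cannot place a CATG+17 site in sequences shorter than 21")
    rng = config.rng(_STREAM_TRANSCRIPTOME)
    n_with = int(round(config.catg_fraction * config.n_genes))
    with_site = np.zeros(config.n_genes, dtype=bool)
    with_site[rng.choice(config.n_genes, size=n_with, replace=False)] = True

    out: List[Transcript] = []
    for i in range(config.n_genes):
        length = int(
            np.clip(
                rng.lognormal(config.length_log_mean, config.length_log_sd),
                max(config.min_length, TAG_LEN + 4),
                config.max_length,
            )
        )
        seq = _random_seq(rng, length, config.gc)
        if with_site[i]:
            if not _has_tag_site(seq):
                pos = length - TAG_LEN
                seq = seq[:pos] + ANCHOR + seq[pos + 4 :]
        else:
            seq = _strip_catg(seq, rng)
        out.append(Transcript(f"gene_{i:05d}", seq))
    return out


def catg_gene_ids(transcripts: Sequence[Transcript]) -> List[str]:
    return [t.id for t in transcripts if _has_tag_site(t.seq)]


def make_de_truth(
    config: SimConfig,
    catg_genes: Optional[Sequence[str]] = None,
    de_gene_sets: Optional[Dict[str, Sequence[str]]] = None,
) -> TruthManifest:
    """Assign per-condition Poisson rates with spiked fold changes.

    Exactly floor(de_fraction * m) of the m site-bearing genes are flagged DE
    per stress condition, with folds log-uniform in ``fold_range`` and the
    direction split given by ``up_fraction``.  ``de_gene_sets`` pins the
    spiked genes per condition (for constructed designs); remaining genes
    share one rate vector across conditions.
    """
    if config.de_fraction > 1:
        raise ValueError("de_fraction must be <= 1")
    rng = config.rng(_STREAM_TRUTH)
    genes = [f"gene_{i:05d}" for i in range(config.n_genes)]
    if catg_genes is None:
        catg_genes = genes
    eligible = [g for g in genes if g in set(catg_genes)]

    lam = rng.lognormal(0.0, config.expression_log_sd, size=config.n_genes)
    df = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    df[f"lam_{config.control}"] = lam

    for cond in config.conditions:
        if cond == config.control:
            continue
        if de_gene_sets is not None and cond in de_gene_sets:
            chosen = list(de_gene_sets[cond])
        else:
            n_de = int(math.floor(config.de_fraction * len(eligible)))
            chosen = list(rng.choice(eligible, size=n_de, replace=False))
        lo, hi = config.fold_range
        folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(chosen)))
        up = rng.random(len(chosen)) < config.up_fraction.get(cond, 0.5)
        fold_col = pd.Series(1.0, index=df.index)
        de_col = pd.Series(False, index=df.index)
        for g, f, u in zip(chosen, folds, up):
            fold_col[g] = f if u else 1.0 / f
            de_col[g] = True
        df[f"fold_{cond}"] = fold_col
        df[f"de_{cond}"] = de_col
        df[f"lam_{cond}"] = df[f"lam_{config.control}"] * fold_col
    df[f"fold_{config.control}"] = 1.0
    df[f"de_{config.control}"] = False

    return TruthManifest(df, config.conditions, config.control, list(eligible))


def _site_tags(seq: str) -> List[str]:
    return [tag for _, tag in iter_catg_tags(seq)]


def _conditional_error_count_probs(e: float, length: int = TAG_LEN) -> np.ndarray:
    """P(m errors | >= 1 error) for m = 1..length under per-base rate e."""
    m = np.arange(1, length + 1)
    pm = (
        np.array([math.comb(length, int(k)) for k in m])
        * e**m
        * (1 - e) ** (length - m)
    )
    return pm / pm.sum()


def _mutate(tag: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    s = list(tag)
    for p in positions:
        s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
    return "".join(s)


def simulate_library(
    transcriptome: Sequence[Transcript],
    truth: TruthManifest,
    condition: str,
    config: SimConfig,
    with_reads: bool = False,
) -> Tuple[TagLibrary, Optional[List[str]]]:
    """Draw one condition's raw tag library (and optionally its 49-bp reads).

    Per-gene sense emissions are Poisson(lambda_g * depth / sum(lambda) over
    site-bearing genes); each emission is the gene's 3'-most tag unless
    incomplete digestion redirects it to a uniformly chosen upstream site.
    Antisense emissions occur at ``antisense_rate`` of the sense rate from
    the 3'-most site of the reverse-complement strand.  Emitted counts are
    recorded in the manifest before corruption.
    """
    if condition not in truth.conditions:
        raise ValueError(f"condition {condition!r} absent from truth manifest")
    ci = list(config.conditions).index(condition)
    rng = config.rng(_STREAM_LIBRARY + ci)

    lam = truth.data[f"lam_{condition}"]
    catg = set(truth.catg_genes)
    site_tags: Dict[str, List[str]] = {}
    anti_tag: Dict[str, Optional[str]] = {}
    for t in transcriptome:
        if t.id in catg:
            site_tags[t.id] = _site_tags(t.seq)
            anti = _site_tags(revcomp(t.seq))
            anti_tag[t.id] = anti[-1] if anti else None

    lam_total = float(sum(lam[g] for g in site_tags))
    scale = config.depth / lam_total if lam_total > 0 else 0.0

    emitted: Counter = Counter()
    emitted_sense: Dict[str, int] = {}
    emitted_anti: Dict[str, int] = {}
    for g, tags in site_tags.items():
        n = int(rng.poisson(lam[g] * scale))
        emitted_sense[g] = n
        if n:
            three_prime = tags[-1]
            n_inc = (
                int(rng.binomial(n, config.incomplete_digestion))
                if len(tags) > 1
                else 0
            )
            emitted[three_prime] += n - n_inc
            if n_inc:
                picks = rng.integers(0, len(tags) - 1, size=n_inc)
                for j in picks:
                    emitted[tags[j]] += 1
        if anti_tag[g] is not None:
            na = int(rng.poisson(config.antisense_rate * lam[g] * scale))
            emitted_anti[g] = na
            if na:
                emitted[anti_tag[g]] += na
        else:
            emitted_anti[g] = 0

    truth.data[f"emitted_{condition}"] = pd.Series(emitted_sense).reindex(
        truth.data.index, fill_value=0
    )
    truth.data[f"emitted_anti_{condition}"] = pd.Series(emitted_anti).reindex(
        truth.data.index, fill_value=0
    )

    # per-base substitution errors
    corrupted: Counter = Counter()
    if config.error_rate > 0:
        p_any = 1.0 - (1.0 - config.error_rate) ** TAG_LEN
        mprobs = _conditional_error_count_probs(config.error_rate)
        for tag, c in emitted.items():
            n_err = int(rng.binomial(c, p_any))
            if c - n_err:
                corrupted[tag] += c - n_err
            for _ in range(n_err):
                m = int(rng.choice(np.arange(1, TAG_LEN + 1), p=mprobs))
                pos = rng.choice(TAG_LEN, size=m, replace=False)
                corrupted[_mutate(tag, pos, rng)] += 1
    else:
        corrupted = emitted.copy()

    # N-containing reads: a base inside the tag body is called as N
    final: Counter = Counter()
    if config.n_rate > 0:
        for tag, c in corrupted.items():
            n_N = int(rng.binomial(c, config.n_rate))
            if c - n_N:
                final[tag] += c - n_N
            for _ in range(n_N):
                p = int(rng.integers(4, TAG_LEN))
                final[tag[:p] + "N" + tag[p + 1 :]] += 1
    else:
        final = corrupted

    # adaptor-only reads carry no tag
    n_adaptor = int(rng.poisson(config.adaptor_rate * config.depth))
    fillers = [
        _strip_catg(_random_seq(rng, 49 - len(config.adaptor_seq), config.gc), rng)
        for _ in range(n_adaptor)
    ]
    truth.contaminants[condition] = {
        "adaptor_reads": n_adaptor,
        "emitted_sense": sum(emitted_sense.values()),
        "emitted_antisense": sum(emitted_anti.values()),
    }

    lib = TagLibrary(
        name=condition,
        counts=dict(final),
        stage=RAW,
        adaptor_reads_distinct=len(set(fillers)),
        adaptor_reads_total=n_adaptor,
    )

    reads: Optional[List[str]] = None
    if with_reads:
        reads = []
        fill_len = 49 - len(config.adaptor_seq) - TAG_LEN
        for tag, c in final.items():
            for _ in range(c):
                reads.append(
                    config.adaptor_seq + tag + _random_seq(rng, max(fill_len, 0), config.gc)
                )
        for f in fillers:
            reads.append(config.adaptor_seq + f)
        rng.shuffle(reads)
    return lib, reads


def make_fixtures(
    truth: TruthManifest,
    config: SimConfig,
    n_background_terms: int = 30,
    planted_term_size: int = 50,
    planted_de_overlap: int = 20,
    panel_up: int = 8,
    panel_down: int = 4,
    planted_condition: Optional[str] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic annotation term map and qPCR Ct table matched to the truth.

    The term map plants one term enriched for true DE genes among random
    background terms.  The Ct panel holds ``panel_up`` up- and ``panel_down``
    down-regulated genes whose Ct values encode the true folds (reference
    gene Ct fixed, calibrator = control condition) plus Gaussian noise.
    """
    rng = config.rng(_STREAM_FIXTURES)
    background = list(truth.catg_genes)
    stress = [c for c in truth.conditions if c != truth.control]
    de_union: Set[str] = set()
    for c in stress:
        de_union |= truth.de_genes(c)
    # plant within one condition's DE set so that condition's comparison sees it
    target = planted_condition or (stress[0] if stress else truth.control)
    de_in_bg = sorted(truth.de_genes(target) & set(background))

    # planted enriched term
    k = min(planted_de_overlap, len(de_in_bg))
    non_de = sorted(set(background) - de_union)
    planted = list(rng.choice(de_in_bg, size=k, replace=False)) + list(
        rng.choice(non_de, size=min(planted_term_size - k, len(non_de)), replace=False)
    )
    rows = [("TERM_PLANTED", "planted DE-enriched term", g) for g in planted]
    for t in range(n_background_terms):
        size = int(rng.integers(10, 81))
        for g in rng.choice(background, size=min(size, len(background)), replace=False):
            rows.append((f"TERM_{t:03d}", f"background term {t}", g))
    term_map = pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])

    # qPCR panel: up-regulated genes from the first stress condition,
    # down-regulated from the last (mirroring an asymmetric stress design)
    up_pool = sorted(
        g for c in stress for g in truth.de_genes(c) if truth.data.loc[g, f"fold_{c}"] > 1
    )
    down_pool = sorted(
        g for c in stress for g in truth.de_genes(c) if truth.data.loc[g, f"fold_{c}"] < 1
    )
    panel = list(
        rng.choice(sorted(set(up_pool)), size=min(panel_up, len(set(up_pool))), replace=False)
    ) + list(
        rng.choice(sorted(set(down_pool) - set(up_pool)),
                   size=min(panel_down, len(set(down_pool) - set(up_pool))), replace=False)
    )

    ref_gene = "reference"
    ct_rows = []
    for cond in truth.conditions:
        for rep in range(1, config.ct_replicates + 1):
            ct_rows.append((ref_gene, cond, rep, 15.0))
        for g in panel:
            base = 20.0
            fold = float(truth.data.loc[g, f"fold_{cond}"]) if cond != truth.control else 1.0
            ct = base - math.log2(fold)
            for rep in range(1, config.ct_replicates + 1):
                noise = float(rng.normal(0.0, config.ct_noise_sd)) if config.ct_noise_sd else 0.0
                ct_rows.append((g, cond, rep, ct + noise))
    ct_table = pd.DataFrame(ct_rows, columns=["gene", "condition", "replicate", "ct"])
    return term_map, ct_table
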