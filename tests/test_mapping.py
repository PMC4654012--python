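"""Tag mapping: tier priority, strandedness, Table-style gene accounting."""

import numpy as np
import pytest

from dgetag import TagLibrary, build_virtual_index, map_tags, mapping_summary, pct
from dgetag.index import TAG_LEN
from dgetag.mapping import (
    MULTI_GENE,
    ONE_MISMATCH,
    PERFECT,
    UNIQUE_GENE,
    UNMAPPED,
    hamming_neighbors,
    unambiguous_assignments,
)

from conftest import random_transcripts


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def brute_force_map(tag, index, max_mismatch=1):
    """Quadratic oracle: compare the tag against every reference tag."""
    best_d, hits = None, []
    for ref, origins in index.entries.items():
        d = hamming(tag, ref)
        if d > max_mismatch:
            continue
        if best_d is None or d < best_d:
            best_d, hits = d, list(origins)
        elif d == best_d:
            hits.extend(origins)
    if best_d is None:
        return UNMAPPED, set(), set()
    tier = PERFECT if best_d == 0 else ONE_MISMATCH
    return tier, {o.gene_id for o in hits}, {o.strand for o in hits}


def _mutate(tag, pos, rng):
    alt = rng.choice([b for b in "ACGT" if b != tag[pos]])
    return tag[:pos] + alt + tag[pos + 1 :]


def test_perfect_private_tag(toy_index):
    tag = "CATG" + "A" * 16 + "C"
    lib = TagLibrary("x", {tag: 4}, stage="clean")
    (a,) = map_tags(lib, toy_index).assignments
    assert (a.match_tier, a.strand, a.multiplicity, a.gene_ids) == (
        PERFECT,
        "sense",
        UNIQUE_GENE,
        ["gA"],
    )


def test_antisense_perfect_match(small_sim):
    _, transcripts, _ = small_sim
    idx = build_virtual_index(transcripts)
    anti = next(
        t
        for t, os in idx.entries.items()
        if {o.strand for o in os} == {"antisense"} and len({o.gene_id for o in os}) == 1
    )
    lib = TagLibrary("x", {anti: 2}, stage="clean")
    (a,) = map_tags(lib, idx).assignments
    assert (a.match_tier, a.strand, a.multiplicity) == (PERFECT, "antisense", UNIQUE_GENE)


def test_one_mismatch_unique(toy_index):
    tag = _mutate("CATG" + "A" * 16 + "C", 10, np.random.default_rng(0))
    lib = TagLibrary("x", {tag: 1}, stage="clean")
    (a,) = map_tags(lib, toy_index).assignments
    assert a.match_tier == ONE_MISMATCH
    assert a.gene_ids == ["gA"]


def test_neighbors_cover_all_positions():
    tag = "CATG" + "A" * 17
    nbs = set(hamming_neighbors(tag))
    assert len(nbs) == 3 * TAG_LEN
    assert all(hamming(tag, nb) == 1 for nb in nbs)
    assert any(not nb.startswith("CATG") for nb in nbs)  # anchor may mutate


def test_max_mismatch_above_one_rejected(toy_index):
    lib = TagLibrary("x", {"CATG" + "A" * 17: 1}, stage="clean")
    with pytest.raises(ValueError):
        map_tags(lib, toy_index, max_mismatch=2)


def test_brute_force_equivalence():
    """Hash+neighbor mapping equals the all-pairs Hamming oracle."""
    rng = np.random.default_rng(23)
    txs = random_transcripts(rng, 60, length=(50, 200))
    idx = build_virtual_index(txs)
    ref_tags = list(idx.entries)
    assert len(ref_tags) <= 500

    bases = np.array(list("ACGT"))
    observed = {}
    for _ in range(120):
        u = rng.random()
        if u < 0.4:
            tag = ref_tags[int(rng.integers(len(ref_tags)))]
        elif u < 0.8:
            tag = _mutate(ref_tags[int(rng.integers(len(ref_tags)))], int(rng.integers(TAG_LEN)), rng)
        else:
            tag = "".join(bases[rng.integers(0, 4, size=TAG_LEN)])
        observed[tag] = observed.get(tag, 0) + 1

    lib = TagLibrary("x", observed, stage="clean")
    table = map_tags(lib, idx)
    for a in table.assignments:
        tier, genes, _ = brute_force_map(a.tag, idx)
        assert a.match_tier == tier
        assert set(a.gene_ids) == genes
        if a.match_tier != UNMAPPED:
            assert a.multiplicity == (UNIQUE_GENE if len(genes) == 1 else MULTI_GENE)


def test_tier_priority(toy_index):
    """A tag with a perfect hit is never classified one_mismatch."""
    for tag in toy_index.entries:
        lib = TagLibrary("x", {tag: 1}, stage="clean")
        (a,) = map_tags(lib, toy_index).assignments
        assert a.match_tier == PERFECT


def test_unambiguous_filter():
    txs = random_transcripts(np.random.default_rng(2), 30, length=(60, 150))
    idx = build_virtual_index(txs)
    lib = TagLibrary("x", {t: 1 for t in list(idx.entries)[:50]}, stage="clean")
    table = map_tags(lib, idx)
    got = unambiguous_assignments(table)
    expect = [a for a in table.assignments if len(set(a.gene_ids)) == 1 and a.is_mapped]
    assert got == expect
    assert all(a.multiplicity == UNIQUE_GENE for a in got)


def test_summary_toy_full_coverage(toy_index):
    tags = {t: 1 for t, os in toy_index.entries.items() if os[0].strand == "sense"}
    table = map_tags(TagLibrary("x", tags, stage="clean"), toy_index)
    df = mapping_summary(table).set_index("category")
    for row in [
        "All tag mapping to sense gene",
        "Unambiguous tag mapping to sense gene",
        "All tag mapping to gene (sense and antisense)",
    ]:
        assert df.loc[row, "n_genes"] == 3
        assert df.loc[row, "pct_of_reference"] == 100.0


def test_summary_union_and_ordering(small_sim):
    cfg, transcripts, _ = small_sim
    idx = build_virtual_index(transcripts)
    rng = np.random.default_rng(9)
    tags = {t: int(rng.integers(1, 5)) for t in list(idx.entries)[::3]}
    table = map_tags(TagLibrary("x", tags, stage="clean"), idx)
    df = mapping_summary(table).set_index("category")
    all_any = df.loc["All tag mapping to gene (sense and antisense)", "n_genes"]
    # aggregate equals the union of per-category gene sets: no double counting
    union = set()
    for a in table.mapped():
        union.update(a.gene_ids)
    assert all_any == len(union)
    assert df.loc["All tag mapping to sense gene", "n_genes"] <= all_any
    assert df.loc["All tag mapping to antisense gene", "n_genes"] <= all_any
    assert (
        df.loc["Unambiguous tag mapping to sense gene", "n_genes"]
        <= df.loc["All tag mapping to sense gene", "n_genes"]
    )


@pytest.mark.parametrize(
    "num,den,expect",
    [
        (10156, 38381, 26.46),  # genes reached by any tag
        (8629, 38381, 22.48),  # perfect-sense-unique genes
        (10304, 38381, 26.85),
    ],
)
def test_gene_percentage_arithmetic(num, den, expect):
    assert pct(num, den) == pytest.approx(expect, abs=1e-9)
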