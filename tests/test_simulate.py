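"""Synthetic study generator: determinism, site fractions, emission model, corruption."""

import numpy as np
import pytest
from scipy.stats import poisson

from dgetag import SimConfig, build_virtual_index, clean_library, make_de_truth, make_transcriptome
from dgetag.index import TAG_LEN, iter_catg_tags
from dgetag.simulate import catg_gene_ids, make_fixtures, simulate_library


def test_transcriptome_target_fraction():
    cfg = SimConfig(seed=3, n_genes=500, catg_fraction=0.62)
    txs = make_transcriptome(cfg)
    frac = len(catg_gene_ids(txs)) / len(txs)
    assert 0.59 <= frac <= 0.65


def test_transcriptome_deterministic_under_seed():
    cfg = SimConfig(seed=42, n_genes=50)
    a = make_transcriptome(cfg)
    b = make_transcriptome(cfg)
    assert [(t.id, t.seq) for t in a] == [(t.id, t.seq) for t in b]


def test_zero_fraction_means_no_catg():
    cfg = SimConfig(seed=1, n_genes=40, catg_fraction=0.0)
    for t in make_transcriptome(cfg):
        assert "CATG" not in t.seq


def test_infeasible_target_rejected():
    with pytest.raises(ValueError):
        make_transcriptome(SimConfig(seed=1, n_genes=5, catg_fraction=1.0, max_length=15))


def test_de_truth_construction():
    cfg = SimConfig(seed=5, n_genes=400, de_fraction=0.1, fold_range=(2, 8))
    txs = make_transcriptome(cfg)
    eligible = catg_gene_ids(txs)
    truth = make_de_truth(cfg, eligible)
    for cond in ("HS", "CS"):
        de = truth.de_genes(cond)
        assert len(de) == int(0.1 * len(eligible))
        folds = truth.data.loc[sorted(de), f"fold_{cond}"]
        assert ((folds >= 2) | (folds <= 0.5)).all()
        # non-DE genes share the control rate vector
        same = ~truth.data[f"de_{cond}"]
        assert np.allclose(
            truth.data.loc[same, f"lam_{cond}"], truth.data.loc[same, "lam_NC"]
        )


def test_zero_de_fraction_shares_rates():
    cfg = SimConfig(seed=5, n_genes=100, de_fraction=0.0)
    truth = make_de_truth(cfg)
    for cond in ("HS", "CS"):
        assert np.allclose(truth.data[f"lam_{cond}"], truth.data["lam_NC"])


def test_single_gene_poisson_emission():
    """One site-bearing gene, no corruption: one distinct tag, Poisson-bounded count."""
    cfg = SimConfig(
        seed=9,
        n_genes=1,
        catg_fraction=1.0,
        depth=50,
        de_fraction=0.0,
        error_rate=0.0,
        adaptor_rate=0.0,
        n_rate=0.0,
        incomplete_digestion=0.0,
        antisense_rate=0.0,
    )
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    lib, _ = simulate_library(txs, truth, "NC", cfg)
    assert len(lib.counts) <= 1
    total = sum(lib.counts.values())
    lo, hi = poisson.ppf([0.0005, 0.9995], 50)
    assert lo <= total <= hi


def test_three_prime_most_site_without_incomplete_digestion():
    cfg = SimConfig(
        seed=11, n_genes=60, depth=5000, error_rate=0.0, n_rate=0.0,
        adaptor_rate=0.0, incomplete_digestion=0.0, antisense_rate=0.0,
    )
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    lib, _ = simulate_library(txs, truth, "NC", cfg)
    three_prime = set()
    for t in txs:
        tags = [tag for _, tag in iter_catg_tags(t.seq)]
        if tags:
            three_prime.add(tags[-1])
    assert set(lib.counts) <= three_prime


def test_error_rate_fraction_within_binomial_bounds():
    cfg = SimConfig(
        seed=13, n_genes=30, depth=20_000, error_rate=0.01, n_rate=0.0,
        adaptor_rate=0.0, incomplete_digestion=0.0, antisense_rate=0.0,
    )
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    lib, _ = simulate_library(txs, truth, "NC", cfg)
    exact = set()
    for t in txs:
        exact.update(tag for _, tag in iter_catg_tags(t.seq))
    n_err = sum(c for tag, c in lib.counts.items() if tag not in exact)
    total = sum(lib.counts.values())
    p = 1 - 0.99**TAG_LEN
    sd = np.sqrt(p * (1 - p) * total)
    assert abs(n_err - p * total) <= 5 * sd


def test_manifest_conservation():
    """Emitted + contaminant reads account for the raw library exactly."""
    cfg = SimConfig(seed=21, n_genes=100, depth=30_000)
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    lib, _ = simulate_library(txs, truth, "NC", cfg)
    ledger = truth.contaminants["NC"]
    assert lib.total_tags == ledger["emitted_sense"] + ledger["emitted_antisense"]
    assert lib.adaptor_reads_total == ledger["adaptor_reads"]
    assert truth.data["emitted_NC"].sum() == ledger["emitted_sense"]


def test_clean_equals_emitted_minus_singletons_when_uncorrupted():
    cfg = SimConfig(
        seed=31, n_genes=80, depth=20_000, error_rate=0.0, n_rate=0.0,
        adaptor_rate=0.0, antisense_rate=0.0,
    )
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    lib, _ = simulate_library(txs, truth, "NC", cfg)
    clean, _ = clean_library(lib)
    expect = {t: c for t, c in lib.counts.items() if c >= 2}
    assert clean.counts == expect


def test_library_determinism_and_reads():
    cfg = SimConfig(seed=17, n_genes=40, depth=2000)
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    lib1, reads1 = simulate_library(txs, truth, "HS", cfg, with_reads=True)
    lib2, reads2 = simulate_library(txs, truth, "HS", cfg, with_reads=True)
    assert lib1.counts == lib2.counts
    assert reads1 == reads2
    assert all(len(r) == 49 for r in reads1)


def test_unknown_condition_rejected():
    cfg = SimConfig(seed=1, n_genes=10)
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    with pytest.raises(ValueError):
        simulate_library(txs, truth, "XX", cfg)


def test_fixtures_shapes_and_noise_free_folds():
    cfg = SimConfig(seed=23, n_genes=300, ct_noise_sd=0.0)
    txs = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(txs))
    term_map, ct = make_fixtures(truth, cfg)
    assert "TERM_PLANTED" in set(term_map["term_id"])
    # noise-free Ct panel encodes the true folds exactly
    from dgetag import ddct

    folds = ddct(ct, "reference", "NC")
    for _, row in folds.iterrows():
        want = float(truth.data.loc[row["gene"], f"fold_{row['condition']}"])
        assert row["fold"] == pytest.approx(want, rel=1e-9)
    panel = set(folds["gene"])
    assert len(panel) == 12
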