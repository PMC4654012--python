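import numpy as np
import pytest

from dgetag import SimConfig, Transcript, build_virtual_index
from dgetag.simulate import catg_gene_ids, make_de_truth, make_transcriptome


@pytest.fixture(scope="session")
def toy_transcripts():
    """Three genes, each with one private CATG+17 tag."""
    return [
        Transcript("gA", "AAA" + "CATG" + "A" * 16 + "C" + "GG"),
        Transcript("gB", "TTT" + "CATG" + "C" * 16 + "A" + "GG"),
        Transcript("gC", "GGA" + "CATG" + "G" * 8 + "T" * 9 + "GG"),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_transcripts):
    return build_virtual_index(toy_transcripts)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(seed=7, n_genes=300, depth=60_000)
    transcripts = make_transcriptome(cfg)
    truth = make_de_truth(cfg, catg_gene_ids(transcripts))
    return cfg, transcripts, truth


def random_transcripts(rng: np.random.Generator, n: int, length=(60, 400)):
    bases = np.array(list("ACGT"))
    out = []
    for i in range(n):
        L = int(rng.integers(*length))
        out.append(Transcript(f"t{i}", "".join(bases[rng.integers(0, 4, size=L)])))
    return out
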