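import numpy as np
import pytest
from hypothesis import settings

import motifdens as md
from motifdens.pipeline import Config

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def planted_fixture():
    """150-gene periodic fixture with a GC-rich 6-mer pair planted in a
    focal region holding ~25% of the genes."""
    X = md.gen_expression(150, 12, "periodic", noise_sd=0.3, seed=1)
    plant = md.PlantSpec(md.IUPACMotif("WGCGCA"), p_inside=0.9, p_outside=0.02,
                         focal_fraction=0.25)
    records, truth = md.gen_sequences(X, 0.6, 150, [plant], seed=2)
    return X, records, truth, plant


@pytest.fixture(scope="session")
def small_config():
    return Config(q=6, k=25, seed=3, max_len=8)


@pytest.fixture(scope="session")
def forward_pair_fixture():
    """Forward-strand fixture planting the {AAGACA, TAGACA} pair in one
    focal region of a GC-rich background (so spurious hits are rare)."""
    X = md.gen_expression(80, 10, "periodic", noise_sd=0.2, seed=11)
    plant = md.PlantSpec(md.IUPACMotif("WAGACA"), p_inside=0.95, p_outside=0.0,
                         focal_fraction=0.3, strand="forward")
    records, truth = md.gen_sequences(X, 0.25, 120, [plant], seed=12)
    return X, records, truth


@pytest.fixture(scope="session")
def forward_scorer(forward_pair_fixture):
    X, records, _ = forward_pair_fixture
    gk = md.build_neighbor_graph(X, 12, "euclidean", seed=5)
    return md.DensityScorer(md.SequenceSet(records), gk,
                            "mutual_information", "forward")


def naive_scan(motif: str, seq: str) -> list[int]:
    """Regex-free double-loop occurrence oracle (forward strand)."""
    sets = {s: set(md.motifs.IUPAC_SETS[s]) for s in md.motifs.IUPAC_SETS}
    w, out = len(motif), []
    for i in range(len(seq) - w + 1):
        if all(seq[i + j] in sets[motif[j]] for j in range(w)):
            out.append(i)
    return out


def random_motif(rng: np.random.Generator, length: int) -> str:
    syms = list(md.motifs.IUPAC_SETS)
    # mostly plain bases with occasional degeneracy, like refined motifs
    return "".join(
        syms[rng.integers(4)] if rng.random() < 0.7 else syms[rng.integers(15)]
        for _ in range(length))
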