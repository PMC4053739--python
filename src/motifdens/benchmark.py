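"""Reference protocols run on synthetic data.

These routines bundle the study conditions used to validate the method on
fixtures with known ground truth: planted-motif recovery by the full
pipeline, the behavior of the shuffle FDR on null data, and the reduction
of in-degree skewness by balanced neighbor sampling.  Both the test suite
and the reproduction script call them, so the numbers they report are
always recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import skew

from .expression import ExpressionMatrix, balanced_neighbor_sample, knn_graph, symmetrize
from .motifs import IUPACMotif, IUPAC_SETS, SequenceSet, expand_motif, reverse_complement
from .pipeline import Config, run_discovery
from .scoring import DensityScorer
from .seeds import build_seed_table, qmer_presence_matrix
from .simulate import PlantSpec, gen_expression, gen_sequences

# Planted study conditions: a 7-mer pair (the two expansions of WAGACAA)
# localized in a focal region holding ~20% of the genes of a periodic
# 24-condition dataset, in 600 bp background at 60% A+T.
PLANTED_MOTIF = IUPACMotif("WAGACAA")
PLANT = PlantSpec(PLANTED_MOTIF, p_inside=0.7, p_outside=0.05,
                  focal_fraction=0.2, strand="forward")
N_GENES = 1000
N_CONDITIONS = 24
SEQ_LENGTH = 600
AT_FRACTION = 0.6


def motif_covers_word(motif: IUPACMotif, word: str, strands: str = "both") -> bool:
    """True if every base of ``word`` fits inside a window of ``motif``."""
    def fits(m: str, w: str) -> bool:
        return any(all(w[i] in IUPAC_SETS[m[off + i]] for i in range(len(w)))
                   for off in range(len(m) - len(w) + 1))
    if len(word) > len(motif):
        return False
    if fits(motif.symbols, word):
        return True
    return strands == "both" and fits(reverse_complement(motif).symbols, word)


def _fixture(seed: int, planted: bool):
    X = gen_expression(N_GENES, N_CONDITIONS, "periodic", noise_sd=0.3, seed=seed)
    plants = [PLANT] if planted else []
    records, truth = gen_sequences(X, AT_FRACTION, SEQ_LENGTH, plants,
                                   seed=seed + 1)
    return X, records, truth


def planted_recovery(seed: int = 0) -> dict:
    """Full pipeline on one planted fixture; recovery indicators.

    Returns whether any q-mer equal to a planted word passes the seed FDR,
    whether refinement produced a motif covering both planted words, and how
    many filtered motifs do so.
    """
    X, records, truth = _fixture(seed, planted=True)
    cfg = Config(seed=seed)
    res = run_discovery(X, records, cfg)
    words = sorted(expand_motif(PLANTED_MOTIF))
    planted_seed_pass = any(
        str(m) in words or str(reverse_complement(m)) in words
        for m, _, _ in res.seeds)
    covering = [r for r in res.motifs
                if all(motif_covers_word(r.motif, w, cfg.strands) for w in words)]
    return {"n_seeds": len(res.seeds),
            "planted_seed_pass": planted_seed_pass,
            "n_filtered_motifs": len(res.motifs),
            "n_covering_motifs": len(covering),
            "recovered": bool(covering),
            "top_motifs": [str(r.motif) for r in res.motifs[:5]],
            "n_planted_genes": len({p.gene_id for p in truth.plants})}


def null_seed_fraction(n_runs: int = 20, seed: int = 0) -> dict:
    """Pooled fraction of q-mers passing the seed FDR on unplanted fixtures."""
    cfg = Config(seed=seed)
    passing = total = 0
    runs_with_seed = 0
    for r in range(n_runs):
        X, records, _ = _fixture(seed + 1000 + r, planted=False)
        gk = balanced_neighbor_sample(
            symmetrize(knn_graph(X, cfg.k, cfg.metric)), cfg.k,
            seed=cfg.stage_seed("graph") + r)
        seqs = SequenceSet(records)
        scorer = DensityScorer(seqs, gk, cfg.criterion, cfg.strands)
        qp = qmer_presence_matrix(seqs, cfg.q, cfg.strands)
        table = build_seed_table(qp, scorer, cfg.n_shuffles,
                                 cfg.stage_seed("shuffle") + r)
        n_pass = int((table.fdr < cfg.seed_fdr).sum())
        passing += n_pass
        total += len(table.qmers)
        runs_with_seed += n_pass > 0
    return {"qmer_fraction": passing / total, "n_passing": passing,
            "n_total": total, "runs_with_seed": runs_with_seed,
            "n_runs": n_runs}


def hubness_reduction(n: int = 500, p: int = 100, k: int = 50,
                      n_seeds: int = 20, seed: int = 0) -> dict:
    """In-degree skewness of raw kNN vs balanced graphs on Gaussian data.

    Averaged over ``n_seeds`` independent datasets; balancing should reduce
    the skewness.
    """
    sk_knn, sk_bal = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        X = ExpressionMatrix([f"g{i}" for i in range(n)],
                             rng.normal(size=(n, p)))
        g = knn_graph(X, k)
        gb = balanced_neighbor_sample(symmetrize(g), k, seed=seed + s)
        sk_knn.append(skew(g.in_degrees().astype(float)))
        sk_bal.append(skew(gb.in_degrees().astype(float)))
    return {"skewness_knn": float(np.mean(sk_knn)),
            "skewness_balanced": float(np.mean(sk_bal)),
            "n_seeds": n_seeds, "n": n, "p": p, "k": k}
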