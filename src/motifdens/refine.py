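"""Greedy seed refinement: constrained generalization, then elongation.

A seed q-mer is turned into a richer degenerate motif by hill climbing on
its score.  Generalization replaces one non-degenerate position at a time by
a strictly more permissive IUPAC symbol; to keep the refined motif anchored
to the seed's location in the expression space, a candidate is admissible
only if the Pearson correlation between its density profile and the
*original seed's* profile is at least alpha (0.75 by default).  When no
generalization improves the score, the motif is elongated by prepending or
appending any IUPAC symbol (no alpha gate: extension can only shrink the
word set), up to a maximum length.  Every accepted move strictly increases
the score, so refinement terminates at a local maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motifs import IUPACMotif, elongations_of, generalizations_of
from .scoring import DensityScorer

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefinementStep:
    iteration: int
    motif: IUPACMotif
    score: float
    move: str  # 'seed' | 'generalize' | 'elongate'


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def generalize_step(current: IUPACMotif, current_score: float,
                    seed_profile: np.ndarray, alpha: float,
                    scorer: DensityScorer,
                    include_n: bool = True) -> tuple[IUPACMotif, float] | None:
    """Best admissible one-symbol generalization, or None if no improvement.

    Admissible: density-profile correlation with the seed profile >= alpha;
    candidates with a flat (zero-variance) profile are excluded.  Among
    admissible candidates that strictly beat ``current_score``, ties are
    broken by motif string.
    """
    best: tuple[float, str, IUPACMotif] | None = None
    for cand in generalizations_of(current, include_n=include_n):
        counts = scorer.counts_from_presence(scorer.presence(cand))
        r = _pearson(counts.astype(float), seed_profile.astype(float))
        if np.isnan(r):
            log.debug("candidate %s excluded: zero-variance density profile", cand)
            continue
        if r < alpha:
            continue
        sc = float(scorer.score_counts(counts, int(scorer.presence(cand).sum())))
        key = (-sc, str(cand))
        if sc > current_score and (best is None or key < (-best[0], best[1])):
            best = (sc, str(cand), cand)
    if best is None:
        return None
    return best[2], best[0]


def elongate_step(current: IUPACMotif, current_score: float,
                  scorer: DensityScorer,
                  max_len: int = 9) -> tuple[IUPACMotif, float] | None:
    """Best one-symbol extension at either end, or None if no improvement.

    At ``max_len`` no candidates are generated.  Appending N leaves the word
    set's matches unchanged, so N-extensions can never strictly improve and
    are never accepted.
    """
    if len(current) >= max_len:
        return None
    best: tuple[float, str, IUPACMotif] | None = None
    for cand in elongations_of(current):
        sc = scorer.score_motif(cand)
        key = (-sc, str(cand))
        if sc > current_score and (best is None or key < (-best[0], best[1])):
            best = (sc, str(cand), cand)
    if best is None:
        return None
    return best[2], best[0]


def optimize_seed(seed: IUPACMotif, scorer: DensityScorer, alpha: float = 0.75,
                  max_len: int = 9,
                  include_n: bool = True) -> tuple[IUPACMotif, float, list[RefinementStep]]:
    """Refine one seed to a local score maximum.

    Generalization runs to a fixpoint first, then elongation; the accepted
    score sequence is strictly increasing.  Each seed is optimized
    independently of all others.
    """
    seed_profile = scorer.counts_from_presence(scorer.presence(seed))
    score = scorer.score_presence(scorer.presence(seed))
    trace = [RefinementStep(0, seed, score, "seed")]
    current = seed
    it = 0
    while True:
        nxt = generalize_step(current, score, seed_profile, alpha, scorer,
                              include_n=include_n)
        if nxt is None:
            break
        it += 1
        current, score = nxt
        trace.append(RefinementStep(it, current, score, "generalize"))
    while True:
        nxt = elongate_step(current, score, scorer, max_len=max_len)
        if nxt is None:
            break
        it += 1
        current, score = nxt
        trace.append(RefinementStep(it, current, score, "elongate"))
    return current, score, trace


def trace_to_rows(trace: list[RefinementStep]) -> list[tuple]:
    return [(s.iteration, str(s.motif), s.score, s.move) for s in trace]
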