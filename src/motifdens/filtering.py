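"""Redundancy removal among refined motifs.

Two motifs are candidate-redundant when they can be aligned without internal
gaps so that at least ``min_overlap`` (default 4) aligned symbol pairs all
have a non-empty IUPAC intersection.  Because sequence-similar motifs can
still live in different parts of the expression space, redundancy
additionally requires the Pearson correlation of their density profiles to
reach gamma (0.75 by default).  Filtering is greedy: motifs are visited in
descending score order and kept iff not redundant with any motif already
kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .motifs import IUPACMotif, IUPAC_MASKS, reverse_complement

log = logging.getLogger(__name__)


def _overlap_oriented(a: str, b: str) -> int:
    """Max ungapped aligned length with all symbol pairs intersecting."""
    best = 0
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):  # offset of b relative to a
        lo = max(0, off)
        hi = min(la, off + lb)
        if hi - lo <= best:
            continue
        if all(IUPAC_MASKS[a[i]] & IUPAC_MASKS[b[i - off]] for i in range(lo, hi)):
            best = hi - lo
    return best


def overlap(a: IUPACMotif, b: IUPACMotif, strands: str = "forward") -> int:
    """Maximum mismatch-free ungapped alignment length between two motifs.

    In ``both`` mode the second motif is also tried in reverse complement.
    """
    out = _overlap_oriented(a.symbols, b.symbols)
    if strands == "both":
        out = max(out, _overlap_oriented(a.symbols, reverse_complement(b).symbols))
    elif strands != "forward":
        raise ValueError(f"bad strands {strands!r}")
    return out


def profile_correlation(pa: np.ndarray, pb: np.ndarray) -> float:
    """Pearson correlation of two density profiles; 0 if either is flat."""
    if np.std(pa) == 0 or np.std(pb) == 0:
        log.debug("flat density profile in redundancy check; correlation set to 0")
        return 0.0
    return float(np.corrcoef(pa, pb)[0, 1])


def is_redundant(a: IUPACMotif, b: IUPACMotif, profile_a: np.ndarray,
                 profile_b: np.ndarray, gamma: float = 0.75,
                 min_overlap: int = 4, strands: str = "forward") -> bool:
    return (overlap(a, b, strands) >= min_overlap
            and profile_correlation(profile_a, profile_b) >= gamma)


@dataclass(frozen=True)
class ScoredMotif:
    motif: IUPACMotif
    score: float


def filter_motifs(optimized: list[ScoredMotif], profiles: dict[str, np.ndarray],
                  gamma: float = 0.75, min_overlap: int = 4,
                  strands: str = "forward") -> list[ScoredMotif]:
    """Greedy best-first retention of pairwise non-redundant motifs.

    ``profiles`` maps motif strings to density profiles.  Score ties are
    broken by motif string, so the output does not depend on input order.
    """
    ranked = sorted(optimized, key=lambda sm: (-sm.score, str(sm.motif)))
    kept: list[ScoredMotif] = []
    for sm in ranked:
        if any(is_redundant(sm.motif, other.motif, profiles[str(sm.motif)],
                            profiles[str(other.motif)], gamma, min_overlap, strands)
               for other in kept):
            continue
        kept.append(sm)
    return kept
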