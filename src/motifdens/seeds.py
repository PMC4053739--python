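"""Exhaustive q-mer seeding with an empirical shuffle FDR.

Every non-degenerate q-mer (q = 7 by default) is scored once against the
expression data.  Significance is assessed without any analytic null: the
mapping between sequences and expression profiles is shuffled (ten rounds by
default, one shared gene permutation per round), all q-mers are rescored,
and the FDR at an observed score s is

    FDR(s) = E[ #null q-mers with score >= s ] / #observed q-mers >= s,

capped at 1.  q-mers below the FDR threshold become seeds for refinement.

Presence of all q-mers is computed in one pass over the sequences (integer
window codes); shuffling permutes gene rows of that presence matrix and
never rescans sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import IUPACMotif, SequenceSet
from .scoring import DensityScorer

_BASES = "ACGT"


def _rc_code_table(q: int) -> np.ndarray:
    """code -> code of the reverse complement word, for all 4**q codes."""
    codes = np.arange(4**q, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(q):
        rc = rc * 4 + (3 - tmp % 4)
        tmp //= 4
    return rc


def _decode(code: int, q: int) -> str:
    out = []
    for _ in range(q):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def canonical_qmer_codes(q: int, strands: str) -> np.ndarray:
    """Sorted codes of the q-mer universe (reverse-complement pairs collapsed
    to their lexicographically smaller member in ``both`` mode)."""
    if strands == "forward":
        return np.arange(4**q, dtype=np.int64)
    if strands == "both":
        rc = _rc_code_table(q)
        canon = np.minimum(np.arange(4**q, dtype=np.int64), rc)
        return np.unique(canon)
    raise ValueError(f"bad strands {strands!r}")


def enumerate_qmers(q: int, strands: str = "forward") -> list[IUPACMotif]:
    """All non-degenerate q-mers (canonical representatives in both mode)."""
    if not 1 <= q <= 15:
        raise ValueError("require 1 <= q <= 15")
    return [IUPACMotif(_decode(int(c), q)) for c in canonical_qmer_codes(q, strands)]


@dataclass
class QmerPresence:
    """Binary presence of every q-mer in every gene sequence."""

    gene_ids: list[str]
    qmers: list[IUPACMotif]
    P: np.ndarray  # bool, (n_genes, n_qmers)
    q: int
    strands: str

    @property
    def n_m(self) -> np.ndarray:
        return self.P.sum(axis=0).astype(np.int64)


def qmer_presence_matrix(seqs: SequenceSet, q: int,
                         strands: str = "both") -> QmerPresence:
    """One suffix-scan over each sequence marking all contained q-mers.

    Windows containing a masked base are skipped.  In ``both`` mode a window
    marks the canonical member of its reverse-complement pair.
    """
    cols = canonical_qmer_codes(q, strands)
    col_of = np.full(4**q, -1, dtype=np.int64)
    col_of[cols] = np.arange(len(cols))
    if strands == "both":
        rc = _rc_code_table(q)
        canon = np.minimum(np.arange(4**q, dtype=np.int64), rc)
    else:
        canon = np.arange(4**q, dtype=np.int64)

    code_tbl = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code_tbl[ord(b)] = i
        code_tbl[ord(b.lower())] = i

    P = np.zeros((seqs.n, len(cols)), dtype=bool)
    for g, rec in enumerate(seqs.records):
        c = code_tbl[np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)]
        L = len(c)
        if L < q:
            continue
        w = np.zeros(L - q + 1, dtype=np.int64)
        valid = np.ones(L - q + 1, dtype=bool)
        for j in range(q):
            cj = c[j : L - q + 1 + j]
            valid &= cj >= 0
            w = w * 4 + np.maximum(cj, 0)
        hits = np.unique(canon[w[valid]])
        P[g, col_of[hits]] = True
    return QmerPresence(list(seqs.gene_ids), enumerate_qmers(q, strands), P, q, strands)


# ---------------------------------------------------------------------------
# Scoring, shuffle null, FDR
# ---------------------------------------------------------------------------

def score_qmers(qp: QmerPresence, scorer: DensityScorer) -> np.ndarray:
    """Observed continuous score of every q-mer (vectorized)."""
    return np.asarray(scorer.score_presence_matrix(qp.P, qp.n_m), dtype=float)


def null_scores(qp: QmerPresence, scorer: DensityScorer, n_shuffles: int = 10,
                seed: int = 0) -> np.ndarray:
    """(n_shuffles, Q) scores after shuffling sequence-to-profile mapping.

    Each round applies one shared random gene permutation to the presence
    rows (the neighbor graph stays fixed) and rescores every q-mer.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n_m = qp.n_m
    out = np.empty((n_shuffles, qp.P.shape[1]))
    for s in range(n_shuffles):
        perm = rng.permutation(qp.P.shape[0])
        out[s] = scorer.score_presence_matrix(qp.P[perm], n_m)
    return out


def fdr_curve(observed: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """Empirical FDR at each observed score, capped at 1.

    FDR(s) = (mean over shuffle rounds of #null >= s) / #observed >= s.
    No monotonicity smoothing is applied.
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if nulls.ndim != 2 or nulls.shape[1] != observed.shape[0]:
        raise ValueError("nulls must be (n_shuffles, n_qmers)")
    n_sh = nulls.shape[0]
    null_sorted = np.sort(nulls.ravel())
    obs_sorted = np.sort(observed)
    exp_count = (null_sorted.size - np.searchsorted(null_sorted, observed, "left")) / n_sh
    obs_count = obs_sorted.size - np.searchsorted(obs_sorted, observed, "left")
    return np.minimum(exp_count / obs_count, 1.0)


@dataclass
class SeedTable:
    """Observed and null q-mer scores with the per-q-mer FDR."""

    qmers: list[IUPACMotif]
    observed: np.ndarray
    nulls: np.ndarray
    fdr: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fdr is None:
            self.fdr = fdr_curve(self.observed, self.nulls)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"qmer": [str(m) for m in self.qmers],
                           "score": self.observed, "fdr": self.fdr})
        if self.n_m is not None:
            df["n_m"] = self.n_m
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def select_seeds(table: SeedTable, fdr_threshold: float = 1e-3
                 ) -> list[tuple[IUPACMotif, float, float]]:
    """q-mers with FDR < threshold, ranked by score descending.

    Score ties are broken by the q-mer string, so selection is deterministic.
    """
    picked = [(m, float(s), float(f))
              for m, s, f in zip(table.qmers, table.observed, table.fdr)
              if f < fdr_threshold]
    picked.sort(key=lambda t: (-t[1], str(t[0])))
    return picked


def build_seed_table(qp: QmerPresence, scorer: DensityScorer,
                     n_shuffles: int = 10, seed: int = 0) -> SeedTable:
    obs = score_qmers(qp, scorer)
    nulls = null_scores(qp, scorer, n_shuffles, seed)
    return SeedTable(qp.qmers, obs, nulls, n_m=qp.n_m)
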