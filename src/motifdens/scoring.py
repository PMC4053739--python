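"""Motif density profiles and the four enrichment criteria.

Two families of criteria relate a motif's binary presence M to expression:

* the *local* (hypergeometric) criterion scores the single best gene set —
  a cluster in the discrete version, a gene's k-neighborhood in the
  continuous one — by the upper tail P(X >= observed positives);
* the *global* (mutual information) criterion sums dependence contributions
  over the whole partition (discrete) or averages per-gene KL terms over the
  expression space (continuous), with P(M=1 | X_g) estimated by the motif
  density n_mkg / k around each gene.

Continuous scores are intentionally *scores*, not P values: significance is
assessed downstream by an empirical shuffle FDR, never analytically.

The density z-score standardizes an observed neighborhood count against its
hypergeometric mean and variance; it ranks genes by how unexpectedly dense
the motif is around them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr
from scipy.stats import hypergeom

from .expression import NeighborGraph, Partition
from .motifs import IUPACMotif, PresenceMatrix, SequenceSet

log = logging.getLogger(__name__)

HYPERGEOMETRIC = "hypergeometric"
MUTUAL_INFORMATION = "mutual_information"
CRITERIA = (HYPERGEOMETRIC, MUTUAL_INFORMATION)


# ---------------------------------------------------------------------------
# Hypergeometric tail
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(x: int, n: int, n_m: int, draw: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(n, n_m, draw)."""
    if not (0 <= n_m <= n and 0 <= draw <= n):
        raise ValueError("require 0 <= n_m <= n and 0 <= draw <= n")
    if x <= 0:
        return 1.0
    if x > min(draw, n_m):
        return 0.0
    return float(hypergeom.sf(x - 1, n, n_m, draw))


def neglog_hypergeom_upper_tail(x, n, n_m, draw) -> np.ndarray:
    """-log P(X >= x), evaluated in log space (safe under tail underflow)."""
    x = np.asarray(x)
    with np.errstate(divide="ignore"):
        val = -hypergeom.logsf(x - 1, n, n_m, draw)
    return np.where(x <= 0, 0.0, val)


# ---------------------------------------------------------------------------
# Density profiles and z-scores
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-gene neighborhood counts of one motif (n_mkg) and densities."""

    gene_ids: list[str]
    counts: np.ndarray  # int, 0..k
    k: int
    motif: IUPACMotif | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.k:
            raise ValueError("counts must lie in [0, k]")

    @property
    def densities(self) -> np.ndarray:
        return self.counts / self.k


def density_profile(pm: PresenceMatrix, gk: NeighborGraph) -> DensityProfile:
    """counts[g] = number of g's neighbors whose sequence contains the motif."""
    if pm.gene_ids != gk.gene_ids:
        raise ValueError("presence matrix and graph cover different gene universes")
    counts = np.array([int(pm.values[nb].sum()) for nb in gk.neighbors])
    return DensityProfile(list(pm.gene_ids), counts, gk.k, pm.motif)


def density_zscore(n_mk, k: int, n_m: int, n: int):
    """Standardized deviation of a neighborhood count from expectation.

    Under a random motif distribution the count among k sampled genes is
    hypergeometric; z = (n_mk - k n_m / n) / sd.  Undefined when the motif
    is absent from, or present in, every gene.
    """
    if not 0 < k < n:
        raise ValueError("require 0 < k < n")
    if n_m <= 0 or n_m >= n:
        raise ValueError("z-score undefined for n_m in {0, n}")
    mean = k * n_m / n
    var = k * n_m * (n - k) * (n - n_m) / (n**2 * (n - 1))
    return (np.asarray(n_mk) - mean) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Discrete (cluster) criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreValue:
    value: float
    criterion: str
    mode: str  # 'discrete' | 'continuous'


def score_discrete(pm: PresenceMatrix, part: Partition, criterion: str,
                   log_base: float | None = None) -> ScoreValue:
    """Cluster-based enrichment of one motif.

    hypergeometric: max over clusters c of -log P(X >= n_mc) with draw = n_c
    (natural log by default).  mutual_information: plug-in I(M; C) in bits by
    default.
    """
    n = pm.n
    sizes = part.sizes()
    if (sizes == 0).any():
        raise ValueError("empty cluster in partition")
    n_mc = np.array([int(pm.values[part.labels == c].sum())
                     for c in range(part.k_clusters)])
    n_m = pm.n_m
    if criterion == HYPERGEOMETRIC:
        vals = neglog_hypergeom_upper_tail(n_mc, n, n_m, sizes)
        base = np.e if log_base is None else log_base
        return ScoreValue(float(vals.max() / np.log(base)), criterion, "discrete")
    if criterion == MUTUAL_INFORMATION:
        base = 2.0 if log_base is None else log_base
        p_mc = np.stack([n_mc / n, (sizes - n_mc) / n])        # (2, C)
        p_m = np.array([n_m / n, 1 - n_m / n])[:, None]
        p_c = (sizes / n)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = p_mc * np.log(p_mc / (p_m * p_c))
        mi = float(np.nansum(np.where(p_mc > 0, t, 0.0)) / np.log(base))
        return ScoreValue(max(mi, 0.0), criterion, "discrete")
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# Continuous (neighborhood) criteria
# ---------------------------------------------------------------------------

def mi_continuous_from_counts(counts: np.ndarray, k: int, n_m, n: int,
                              log_base: float = 2.0) -> np.ndarray:
    """Neighborhood mutual-information estimate, vectorized over motifs.

    ``counts`` is (n_genes,) or (n_genes, n_motifs) of n_mkg values; ``n_m``
    scalar or per-motif.  Each gene contributes the KL divergence between the
    local Bernoulli(n_mkg/k) and the global Bernoulli(n_m/n); the estimate is
    the gene average, hence always >= 0, and 0 iff every density equals the
    global frequency.  Degenerate motifs (present everywhere or nowhere)
    score 0 by continuity.
    """
    C = np.asarray(counts, dtype=np.float64)
    one_d = C.ndim == 1
    C = np.atleast_2d(C.T).T  # (n_genes, Q)
    pm = np.atleast_1d(np.asarray(n_m, dtype=np.float64)) / n
    d = np.clip(C / k, 0.0, 1.0)
    out = np.zeros(C.shape[1])
    ok = (pm > 0) & (pm < 1)
    if (~ok).any():
        log.info("MI set to 0 for %d motif(s) with degenerate presence", int((~ok).sum()))
    if ok.any():
        dd, pp = d[:, ok], pm[ok]
        # per-gene Bernoulli KL via rel_entr (handles 0 log 0 = 0 exactly)
        kl = rel_entr(dd, pp[None, :]) + rel_entr(1.0 - dd, (1.0 - pp)[None, :])
        out[ok] = kl.mean(axis=0) / np.log(log_base)
    out = np.maximum(out, 0.0)
    return out[0] if one_d and out.size == 1 else out


def hyper_continuous_from_counts(counts: np.ndarray, k: int, n_m, n: int,
                                 log_base: float | None = None) -> np.ndarray:
    """max over genes of -log P(X >= n_mkg), draw = k, vectorized over motifs.

    The tail is non-increasing in the count, so the max over genes is reached
    at the largest neighborhood count of each motif.
    """
    C = np.asarray(counts)
    one_d = C.ndim == 1
    C = np.atleast_2d(C.T).T
    xmax = C.max(axis=0)
    base = np.e if log_base is None else log_base
    out = neglog_hypergeom_upper_tail(xmax, n, np.atleast_1d(n_m), k) / np.log(base)
    out = np.asarray(out, dtype=float)
    return float(out[0]) if one_d and out.size == 1 else out


def score_continuous(dp: DensityProfile, n_m: int, n: int, criterion: str,
                     log_base: float | None = None) -> ScoreValue:
    """Clustering-free score of one motif from its density profile."""
    if criterion == HYPERGEOMETRIC:
        v = hyper_continuous_from_counts(dp.counts, dp.k, n_m, n, log_base)
        return ScoreValue(float(v), criterion, "continuous")
    if criterion == MUTUAL_INFORMATION:
        v = mi_continuous_from_counts(dp.counts, dp.k, n_m, n,
                                      2.0 if log_base is None else log_base)
        return ScoreValue(float(v), criterion, "continuous")
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# Scoring context used by seed search and refinement
# ---------------------------------------------------------------------------

class DensityScorer:
    """Binds sequences, a balanced neighbor graph and a criterion.

    Refinement and the pipeline score many candidate motifs against the same
    fixed graph; this object caches the dense adjacency so each candidate
    costs one scan plus one matrix-vector product.
    """

    def __init__(self, seqs: SequenceSet, graph: NeighborGraph,
                 criterion: str = MUTUAL_INFORMATION, strands: str = "both",
                 log_base: float | None = None):
        if seqs.gene_ids != graph.gene_ids:
            raise ValueError("sequence set and graph cover different gene universes")
        if criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {criterion!r}")
        self.seqs = seqs
        self.graph = graph
        self.criterion = criterion
        self.strands = strands
        self.log_base = log_base
        self.n = graph.n
        self.k = graph.k
        self._A = graph.to_dense(np.float32)

    def presence(self, motif: IUPACMotif) -> np.ndarray:
        return self.seqs.presence(motif, self.strands)

    def counts_from_presence(self, presence: np.ndarray) -> np.ndarray:
        return (self._A @ presence.astype(np.float32)).round().astype(np.int64)

    def counts_matrix(self, P: np.ndarray) -> np.ndarray:
        """Neighborhood counts for a whole presence matrix (n x Q)."""
        return (self._A @ P.astype(np.float32)).round().astype(np.int64)

    def score_presence_matrix(self, P: np.ndarray, n_m: np.ndarray) -> np.ndarray:
        """Batch scores for a presence matrix, avoiding integer round-trips."""
        C = self._A @ P.astype(np.float32)
        if self.criterion == MUTUAL_INFORMATION:
            return mi_continuous_from_counts(
                C, self.k, n_m, self.n,
                2.0 if self.log_base is None else self.log_base)
        return hyper_continuous_from_counts(C.round().astype(np.int64),
                                            self.k, n_m, self.n, self.log_base)

    def profile(self, motif: IUPACMotif) -> DensityProfile:
        return DensityProfile(list(self.graph.gene_ids),
                              self.counts_from_presence(self.presence(motif)),
                              self.k, motif)

    def score_counts(self, counts: np.ndarray, n_m) -> np.ndarray:
        if self.criterion == MUTUAL_INFORMATION:
            return mi_continuous_from_counts(counts, self.k, n_m, self.n,
                                             2.0 if self.log_base is None else self.log_base)
        return hyper_continuous_from_counts(counts, self.k, n_m, self.n, self.log_base)

    def score_presence(self, presence: np.ndarray) -> float:
        return float(self.score_counts(self.counts_from_presence(presence),
                                       int(presence.sum())))

    def score_motif(self, motif: IUPACMotif) -> float:
        return self.score_presence(self.presence(motif))
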