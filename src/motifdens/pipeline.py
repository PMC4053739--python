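"""End-to-end discovery runs: configuration, orchestration, manifests.

A run executes, in order: load expression + sequences -> pairwise distances
-> kNN graph -> symmetrization -> balanced neighbor sampling -> q-mer
presence -> scoring -> shuffle null -> FDR -> seed selection -> greedy
refinement of each seed -> redundancy filtering -> per-motif reports.  A
single master seed derives the per-stage seeds by fixed offsets, and the
manifest records every parameter, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .expression import (ExpressionMatrix, balanced_neighbor_sample, kmeans_partition,
                         knn_graph, pairwise_distance, symmetrize)
from .filtering import ScoredMotif, filter_motifs
from .motifs import IUPACMotif, PresenceMatrix, SequenceRecord, SequenceSet, read_fasta
from .refine import optimize_seed, trace_to_rows
from .reports import write_motif_report
from .scoring import CRITERIA, DensityProfile, DensityScorer
from .seeds import SeedTable, build_seed_table, qmer_presence_matrix, select_seeds

log = logging.getLogger(__name__)

# The neighborhood MI estimate uses the density n_mkg/k for P(M=1 | X_g);
# an /n denominator sometimes seen in print contradicts the density
# definition.  Recorded in every manifest for auditability.
_DENOMINATOR_NOTE = ("P(M=1|X_g) computed as n_mkg/k (neighborhood density); "
                     "log bases: natural for -log tail scores, 2 for MI")


class ConfigError(ValueError):
    """Invalid or unknown configuration value (CLI exit code 2)."""


class DataError(ValueError):
    """Unusable input data (CLI exit code 3)."""


@dataclass(frozen=True)
class Config:
    q: int = 7
    k: int = 200
    n_shuffles: int = 10
    seed_fdr: float = 0.001
    alpha: float = 0.75
    gamma: float = 0.75
    max_len: int = 9
    min_overlap: int = 4
    criterion: str = "mutual_information"
    metric: str = "euclidean"
    strands: str = "both"
    heatmap_bins: int = 25
    histogram_bin_width: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (1 <= self.q <= 15, "q", "1..15"),
            (self.k >= 1, "k", ">= 1"),
            (self.n_shuffles >= 1, "n_shuffles", ">= 1"),
            (0 <= self.seed_fdr <= 1, "seed_fdr", "[0, 1]"),
            (0 <= self.alpha <= 1, "alpha", "[0, 1]"),
            (0 <= self.gamma <= 1, "gamma", "[0, 1]"),
            (self.q <= self.max_len <= 15, "max_len", "q..15"),
            (self.min_overlap >= 1, "min_overlap", ">= 1"),
            (self.criterion in CRITERIA, "criterion", str(CRITERIA)),
            (self.metric in ("euclidean", "pearson"), "metric",
             "euclidean|pearson"),
            (self.strands in ("forward", "both"), "strands", "forward|both"),
            (self.heatmap_bins >= 2, "heatmap_bins", ">= 2"),
            (self.histogram_bin_width >= 1, "histogram_bin_width", ">= 1"),
            (0 <= self.seed < 2**31, "seed", "[0, 2^31)"),
        ]
        for ok, name, legal in checks:
            if not ok:
                raise ConfigError(f"parameter {name!r} out of range; legal: {legal}")

    def stage_seed(self, stage: str) -> int:
        offsets = {"graph": 1, "shuffle": 2, "fixture": 3, "kmeans": 4, "match": 5}
        return (self.seed * 1000003 + offsets[stage]) % (2**31)


def load_config(path=None, **overrides) -> Config:
    """Defaults, overridden by a YAML/JSON mapping file and keyword args.

    Unknown keys are rejected with the offending name.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    try:
        return Config(**data)
    except TypeError as e:
        raise ConfigError(str(e)) from e


@dataclass
class MotifResult:
    motif: IUPACMotif
    score: float
    seed: IUPACMotif
    seed_score: float
    seed_fdr: float
    n_m: int
    trace: list


@dataclass
class RunResult:
    config: Config
    gene_ids: list[str]
    seed_table: SeedTable
    seeds: list[tuple[IUPACMotif, float, float]]
    motifs: list[MotifResult]
    outdir: Path | None = None


def _align_inputs(X: ExpressionMatrix, records: list[SequenceRecord]
                  ) -> tuple[ExpressionMatrix, list[SequenceRecord]]:
    by_id = {r.gene_id: r for r in records}
    common = [g for g in X.gene_ids if g in by_id]
    dropped = (X.n - len(common)) + (len(records) - len(common))
    if dropped:
        log.info("dropped %d gene(s) lacking expression or sequence data", dropped)
    if not common:
        raise DataError("no gene IDs shared between expression matrix and FASTA")
    return X.subset(common), [by_id[g] for g in common]


def run_discovery(expression, fasta, config: Config | None = None,
                  outdir=None) -> RunResult:
    """Full discovery run; writes reports when ``outdir`` is given.

    ``expression`` is a path or ExpressionMatrix; ``fasta`` a path or list of
    SequenceRecord.
    """
    cfg = config or Config()
    X = expression if isinstance(expression, ExpressionMatrix) else \
        ExpressionMatrix.from_tsv(expression)
    records = fasta if isinstance(fasta, list) else read_fasta(fasta)
    X, records = _align_inputs(X, records)
    if X.n < cfg.k + 1:
        raise DataError(f"need at least k+1 = {cfg.k + 1} usable genes, got {X.n}")

    D = pairwise_distance(X, cfg.metric)
    gk = balanced_neighbor_sample(symmetrize(knn_graph(X, cfg.k, cfg.metric, D)),
                                  cfg.k, seed=cfg.stage_seed("graph"))
    seqs = SequenceSet(records)
    scorer = DensityScorer(seqs, gk, cfg.criterion, cfg.strands)
    qp = qmer_presence_matrix(seqs, cfg.q, cfg.strands)
    table = build_seed_table(qp, scorer, cfg.n_shuffles, cfg.stage_seed("shuffle"))
    seeds = select_seeds(table, cfg.seed_fdr)

    optimized: list[MotifResult] = []
    for seed_motif, seed_score, seed_fdr in seeds:
        motif, score, trace = optimize_seed(seed_motif, scorer, cfg.alpha,
                                            cfg.max_len)
        n_m = int(scorer.presence(motif).sum())
        optimized.append(MotifResult(motif, score, seed_motif, seed_score,
                                     seed_fdr, n_m, trace))

    profiles = {str(r.motif):
                scorer.counts_from_presence(scorer.presence(r.motif)).astype(float)
                for r in optimized}
    kept = filter_motifs([ScoredMotif(r.motif, r.score) for r in optimized],
                         profiles, cfg.gamma, cfg.min_overlap, cfg.strands)
    # among identical refined motifs keep the first (highest seed score)
    final: list[MotifResult] = []
    seen: set[str] = set()
    for sm in kept:
        for r in optimized:
            if str(r.motif) == str(sm.motif) and str(r.motif) not in seen:
                seen.add(str(r.motif))
                final.append(r)
                break
    result = RunResult(cfg, list(X.gene_ids), table, seeds, final)
    if outdir is not None:
        _write_run(result, X, seqs, scorer, Path(outdir))
        result.outdir = Path(outdir)
    return result


def _write_run(res: RunResult, X: ExpressionMatrix, seqs: SequenceSet,
               scorer: DensityScorer, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = res.config
    res.seed_table.to_tsv(outdir / "seeds.tsv")
    pd.DataFrame(
        [(str(r.motif), r.score, str(r.seed), r.seed_score, r.seed_fdr, r.n_m)
         for r in res.motifs],
        columns=["motif", "score", "seed", "seed_score", "seed_fdr", "n_m"]
    ).to_csv(outdir / "motifs.tsv", sep="\t", index=False, float_format="%.6g")
    if res.motifs:
        from .dbmatch import iupac_to_pwm, write_meme
        write_meme([iupac_to_pwm(r.motif) for r in res.motifs],
                   outdir / "motifs.meme")
    for r in res.motifs:
        pm = PresenceMatrix(list(seqs.gene_ids), scorer.presence(r.motif), r.motif)
        dp = DensityProfile(list(seqs.gene_ids),
                            scorer.counts_from_presence(pm.values),
                            scorer.k, r.motif)
        occs = seqs.scan(r.motif, cfg.strands)
        summary = {"motif": str(r.motif), "score": r.score,
                   "seed": str(r.seed), "seed_fdr": r.seed_fdr, "n_m": r.n_m,
                   "criterion": cfg.criterion, "k": cfg.k, "q": cfg.q}
        write_motif_report(outdir, str(r.motif), occs, seqs.records, pm, X, dp,
                           summary, cfg.heatmap_bins, cfg.histogram_bin_width)
        pd.DataFrame(trace_to_rows(r.trace),
                     columns=["iteration", "motif", "score", "move"]
                     ).to_csv(outdir / str(r.motif) / "trace.tsv", sep="\t",
                              index=False, float_format="%.6g")
    manifest = {"version": __version__, "parameters": asdict(cfg),
                "n_genes": len(res.gene_ids), "n_seeds": len(res.seeds),
                "n_motifs": len(res.motifs),
                "stage_seeds": {s: cfg.stage_seed(s)
                                for s in ("graph", "shuffle")},
                "notes": _DENOMINATOR_NOTE}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Cluster-based baseline (discrete criteria over k-means partitions)
# ---------------------------------------------------------------------------

def baseline_seed_table(X: ExpressionMatrix, records: list[SequenceRecord],
                        k_clusters: int, cfg: Config | None = None,
                        restarts: int = 100) -> SeedTable:
    """Seed table under the discrete (cluster) criterion for one k-means run.

    Uses the same q-mer presence matrix and shuffle-null protocol as the
    continuous pipeline, but scores each q-mer against a best-of-``restarts``
    k-means partition instead of gene neighborhoods.
    """
    from .scoring import (HYPERGEOMETRIC, MUTUAL_INFORMATION,
                          neglog_hypergeom_upper_tail)

    cfg = cfg or Config()
    X, records = _align_inputs(X, records)
    part = kmeans_partition(X, k_clusters, restarts, cfg.stage_seed("kmeans"))
    seqs = SequenceSet(records)
    qp = qmer_presence_matrix(seqs, cfg.q, cfg.strands)
    B = part.indicator(np.float32)
    sizes = part.sizes().astype(np.int64)
    n = X.n
    n_m = qp.n_m

    def score(P: np.ndarray) -> np.ndarray:
        n_mc = (B @ P.astype(np.float32)).round().astype(np.int64)  # (C, Q)
        if cfg.criterion == HYPERGEOMETRIC:
            vals = neglog_hypergeom_upper_tail(n_mc, n, n_m[None, :], sizes[:, None])
            return vals.max(axis=0)
        p1 = n_mc / n
        p0 = (sizes[:, None] - n_mc) / n
        pm1, pm0 = n_m / n, 1 - n_m / n
        pc = sizes[:, None] / n
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(p1 > 0, p1 * np.log(p1 / (pm1[None, :] * pc)), 0.0)
            t0 = np.where(p0 > 0, p0 * np.log(p0 / (pm0[None, :] * pc)), 0.0)
        return np.maximum((t1 + t0).sum(axis=0) / np.log(2.0), 0.0)

    obs = score(qp.P)
    rng = np.random.default_rng(cfg.stage_seed("shuffle"))
    nulls = np.empty((cfg.n_shuffles, qp.P.shape[1]))
    for s in range(cfg.n_shuffles):
        nulls[s] = score(qp.P[rng.permutation(n)])
    return SeedTable(qp.qmers, obs, nulls, n_m=n_m)
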