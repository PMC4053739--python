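"""Per-motif reporting: positional histograms, strand bias, expression-space
heatmap, ranked gene lists, and the exact sign test.

The sign test is the workhorse comparison statistic: an exact two-sided
binomial test at success probability 1/2, with the two-sided P value formed
by doubling the smaller exact tail (capped at 1).  It serves both the
per-motif strand-bias check and paired method comparisons.

Gene ranking uses the density z-score: a motif occurrence is more likely
functional in a gene whose expression-space neighborhood is unexpectedly
rich in the motif.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .expression import ExpressionMatrix
from .motifs import Occurrence, PresenceMatrix, SequenceRecord, occurrences_to_rows
from .scoring import DensityProfile, density_zscore


def sign_test(wins: int, losses: int) -> float:
    """Exact two-sided sign test P value (ties excluded beforehand)."""
    if wins < 0 or losses < 0 or wins + losses < 1:
        raise ValueError("need wins + losses >= 1, both non-negative")
    n = wins + losses
    tail_up = float(binom.sf(wins - 1, n, 0.5))   # P(X >= wins)
    tail_down = float(binom.cdf(wins, n, 0.5))    # P(X <= wins)
    return min(1.0, 2.0 * min(tail_up, tail_down))


def strand_bias(occurrences: list[Occurrence]) -> tuple[float, str]:
    """Sign test on forward vs reverse occurrence counts, plus majority strand."""
    fwd = sum(1 for o in occurrences if o.strand == "+")
    rev = sum(1 for o in occurrences if o.strand == "-")
    if fwd + rev == 0:
        raise ValueError("strand bias undefined with zero occurrences")
    direction = "+" if fwd >= rev else "-"
    return sign_test(fwd, rev), direction


def occurrence_distance(occ: Occurrence, rec: SequenceRecord) -> int:
    """Distance of an occurrence from the codon-proximal sequence end.

    Upstream regions are anchored at the start codon, i.e. the 3' end of the
    stored sequence; downstream regions at the stop codon, the 5' end.  An
    occurrence flush against the codon has distance 0.
    """
    if rec.region_kind == "upstream":
        return len(rec.seq) - occ.end
    return occ.start


def position_histogram(occurrences: list[Occurrence],
                       records: list[SequenceRecord],
                       anchor: str = "start_codon", bin_width: int = 50,
                       count_genes: bool = False) -> pd.DataFrame:
    """Binned distances of occurrences from the anchoring codon.

    ``anchor`` must agree with the region kind of the records (start_codon
    for upstream regions, stop_codon for downstream).  ``count_genes``
    counts each gene at most once per bin instead of every occurrence.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if anchor not in ("start_codon", "stop_codon"):
        raise ValueError(f"bad anchor {anchor!r}")
    by_id = {r.gene_id: r for r in records}
    pairs = [(occurrence_distance(o, by_id[o.gene_id]), o.gene_id)
             for o in occurrences]
    max_d = max((d for d, _ in pairs), default=0)
    edges = np.arange(0, max_d + bin_width + 1, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    seen: set[tuple[int, str]] = set()
    for d, gid in pairs:
        b = min(d // bin_width, len(counts) - 1)
        if count_genes:
            if (b, gid) in seen:
                continue
            seen.add((b, gid))
        counts[b] += 1
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts})


def expression_heatmap(pm: PresenceMatrix, X: ExpressionMatrix,
                       n_bins: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Motif density z-scores over an (expression level x condition) grid.

    Per condition, genes fall into ``n_bins`` equal-width bins of that
    condition's expression range; each occupied cell gets the density
    z-score of its positive-gene count against the hypergeometric
    expectation for a sample of the cell's size.  Returns (Z, sizes) of
    shape (n_conditions, n_bins); cells that are empty, full-universe, or
    undefined are NaN in Z.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if pm.gene_ids != X.gene_ids:
        raise ValueError("presence and expression cover different gene universes")
    n, n_m = pm.n, pm.n_m
    Z = np.full((X.p, n_bins), np.nan)
    sizes = np.zeros((X.p, n_bins), dtype=np.int64)
    for c in range(X.p):
        col = X.values[:, c]
        lo, hi = col.min(), col.max()
        if hi == lo:
            idx = np.zeros(n, dtype=np.int64)  # constant condition: one bin
        else:
            idx = np.minimum(((col - lo) / (hi - lo) * n_bins).astype(np.int64),
                             n_bins - 1)
        for b in range(n_bins):
            cell = idx == b
            sz = int(cell.sum())
            sizes[c, b] = sz
            if sz == 0 or sz >= n or n_m in (0, n):
                continue
            Z[c, b] = float(density_zscore(int(pm.values[cell].sum()), sz, n_m, n))
    return Z, sizes


def ranked_gene_list(dp: DensityProfile, n_m: int, n: int,
                     pm: PresenceMatrix) -> pd.DataFrame:
    """Genes possessing the motif, sorted by density z-score descending.

    Positive z means the gene sits where the motif's neighborhood density
    exceeds its genome-wide expectation, flagging likely functional
    occurrences.
    """
    if dp.gene_ids != pm.gene_ids:
        raise ValueError("profile and presence cover different gene universes")
    z = density_zscore(dp.counts, dp.k, n_m, n)
    df = pd.DataFrame({"gene_id": dp.gene_ids, "count": dp.counts,
                       "density": dp.densities, "zscore": z})
    df = df[np.asarray(pm.values)]
    return (df.sort_values(["zscore", "gene_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True))


# ---------------------------------------------------------------------------
# Report directory
# ---------------------------------------------------------------------------

def write_motif_report(outdir, motif_name: str, occurrences: list[Occurrence],
                       records: list[SequenceRecord], pm: PresenceMatrix,
                       X: ExpressionMatrix, dp: DensityProfile,
                       summary: dict, n_bins: int = 25,
                       bin_width: int = 50) -> Path:
    """Write the standard per-motif report files; returns the directory."""
    d = Path(outdir) / motif_name
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(occurrences_to_rows(occurrences),
                 columns=["gene_id", "start", "end", "strand", "word", "context"]
                 ).to_csv(d / "occurrences.tsv", sep="\t", index=False)
    anchor = ("start_codon" if records and records[0].region_kind == "upstream"
              else "stop_codon")
    position_histogram(occurrences, records, anchor, bin_width
                       ).to_csv(d / "histogram.tsv", sep="\t", index=False)
    Z, sizes = expression_heatmap(pm, X, n_bins)
    pd.DataFrame(Z, index=X.condition_names,
                 columns=[f"bin{i}" for i in range(Z.shape[1])]
                 ).to_csv(d / "heatmap.tsv", sep="\t", float_format="%.6g",
                          index_label="condition")
    ranked_gene_list(dp, pm.n_m, pm.n, pm).to_csv(
        d / "genes.tsv", sep="\t", index=False, float_format="%.6g")
    summary = dict(summary)
    if occurrences:
        p, direction = strand_bias(occurrences)
        summary["strand_bias_p"] = p
        summary["strand_bias_direction"] = direction
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return d
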