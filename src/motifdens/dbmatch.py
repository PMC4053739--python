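"""Evaluation of predicted motifs against a database of known motifs.

Predicted IUPAC motifs are converted to position weight matrices (each
symbol becomes the uniform distribution over its nucleotide set) and
compared to database PWMs with an ungapped alignment score: the sum, over
aligned positions, of the Pearson correlation between the two 4-vector
columns.  Significance is empirical: the columns of the whole database pool
are shuffled (target lengths preserved), the best alignment score against
each shuffled database forms the null, and P = (1 + #null >= observed) /
(1 + n_shuffles).  A query's best match is its lowest-P target; matches are
counted after Benjamini-Hochberg selection at a global FDR (15% by default),
and when several queries share the same best target only the lowest-P query
counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import IUPAC_SETS, IUPACMotif

_BASES = "ACGT"


@dataclass
class PWM:
    """Position weight matrix: rows = positions, columns = (A, C, G, T)."""

    name: str
    matrix: np.ndarray  # (L, 4), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (L, 4)")
        if (self.matrix < 0).any() or not np.allclose(self.matrix.sum(axis=1), 1.0):
            raise ValueError("PWM columns must be non-negative and sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1].copy())


def iupac_to_pwm(m: IUPACMotif, name: str | None = None) -> PWM:
    """Uniform-distribution PWM of a consensus (A -> [1,0,0,0], W -> [.5,.5,0,0])."""
    rows = []
    for sym in m.symbols:
        row = np.zeros(4)
        for b in IUPAC_SETS[sym]:
            row[_BASES.index(b)] = 1.0
        rows.append(row / row.sum())
    return PWM(name or m.symbols, np.array(rows))


def _column_corr(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson r of two 4-vectors; 0 when either column has zero variance."""
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(((u - u.mean()) @ (v - v.mean())) / (4 * su * sv))


def align_score(q: PWM, t: PWM, min_cols: int = 4,
                strands: str = "both") -> tuple[float, int, str]:
    """Best ungapped alignment of t (both orientations) against q.

    Returns (score, offset of t relative to q, orientation).  Offsets with
    fewer than ``min_cols`` aligned columns are skipped; if no offset is
    admissible the score is -inf.
    """
    orientations = [("+", t)]
    if strands == "both":
        orientations.append(("-", t.reverse_complement()))
    best = (-np.inf, 0, "+")
    lq = len(q)
    for orient, tt in orientations:
        lt = len(tt)
        for off in range(-(lt - 1), lq):
            lo, hi = max(0, off), min(lq, off + lt)
            if hi - lo < min_cols:
                continue
            sc = sum(_column_corr(q.matrix[i], tt.matrix[i - off])
                     for i in range(lo, hi))
            if sc > best[0]:
                best = (sc, off, orient)
    return best


def _shuffled_db(db: list[PWM], rng: np.random.Generator) -> list[PWM]:
    """Permute all columns across the database pool, preserving lengths."""
    pool = np.concatenate([p.matrix for p in db], axis=0)
    pool = pool[rng.permutation(pool.shape[0])]
    out, i = [], 0
    for p in db:
        out.append(PWM(p.name, pool[i : i + len(p)].copy()))
        i += len(p)
    return out


def match_pvalue(q: PWM, db: list[PWM], n_shuffles: int = 1000, seed: int = 0,
                 min_cols: int = 4, strands: str = "both",
                 within_motif: bool = False) -> np.ndarray:
    """Per-target empirical P values for the alignment of q against db.

    The null statistic is the best alignment score of q against an entirely
    column-shuffled database (pool shuffling by default; ``within_motif``
    restricts each permutation to its own motif's columns).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    observed = np.array([align_score(q, t, min_cols, strands)[0] for t in db])
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        if within_motif:
            shuf = [PWM(p.name, p.matrix[rng.permutation(len(p))].copy()) for p in db]
        else:
            shuf = _shuffled_db(db, rng)
        null[s] = max(align_score(q, t, min_cols, strands)[0] for t in shuf)
    null_sorted = np.sort(null)
    ge = n_shuffles - np.searchsorted(null_sorted, observed, side="left")
    return (1 + ge) / (1 + n_shuffles)


def benjamini_hochberg(pvals: np.ndarray, fdr: float) -> np.ndarray:
    """Step-up rejection mask at level ``fdr``."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    reject = np.zeros(m, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(p, kind="stable")
    passing = np.nonzero(p[order] <= (np.arange(1, m + 1) / m) * fdr)[0]
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def benchmark_matches(queries: list[PWM], db: list[PWM], fdr: float = 0.15,
                      n_shuffles: int = 1000, seed: int = 0, min_cols: int = 4,
                      strands: str = "both") -> tuple[int, pd.DataFrame]:
    """Count database matches of a prediction set at a global FDR.

    Each query's best match is the minimum-P target; BH step-up runs over
    the best-match P values of all queries; among significant queries that
    share a best target only the lowest-P one is counted (ties broken by
    query order).  Returns (count, per-query table).
    """
    rows = []
    for i, q in enumerate(queries):
        pv = match_pvalue(q, db, n_shuffles=n_shuffles, seed=seed + i,
                          min_cols=min_cols, strands=strands)
        j = int(np.argmin(pv))
        sc, off, orient = align_score(q, db[j], min_cols, strands)
        rows.append((q.name, db[j].name, sc, float(pv[j]), off, orient))
    df = pd.DataFrame(rows, columns=["query", "target", "score", "p_value",
                                     "offset", "orientation"])
    if df.empty:
        df["bh_significant"] = df["counted"] = pd.Series(dtype=bool)
        return 0, df
    df["bh_significant"] = benjamini_hochberg(df["p_value"].to_numpy(), fdr)
    counted = np.zeros(len(df), dtype=bool)
    sig = df[df["bh_significant"]].sort_values(["p_value", "query"], kind="stable")
    seen: set[str] = set()
    for idx, row in sig.iterrows():
        if row["target"] not in seen:
            seen.add(row["target"])
            counted[df.index.get_loc(idx)] = True
    df["counted"] = counted
    return int(counted.sum()), df


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"
                 "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for p in pwms:
            fh.write(f"MOTIF {p.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(p)} "
                     f"nsites= 20 E= 0\n")
            for row in p.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, rows
        if name is not None and rows:
            mat = np.array(rows)
            pwms.append(PWM(name, mat / mat.sum(axis=1, keepdims=True)))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split()[1]
            elif name is not None and line and line[0] in "0123456789.":
                rows.append([float(v) for v in line.split()[:4]])
    flush()
    return pwms
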