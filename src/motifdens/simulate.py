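"""Synthetic expression + sequence fixtures with planted, expression-localized
motifs.

The generator emulates the two data regimes the method targets: smooth
low-dimensional expression structure (periodic trajectories, as produced by
time-course experiments over a full cycle, or Gaussian blobs) and regulatory
regions of configurable nucleotide composition, up to the ~80-90% A+T of
AT-rich intergenic genomes.  A planted motif is localized in expression
space: genes whose profile lies within a focal region (distance to a focal
profile below a radius) receive one occurrence with probability
``p_inside``, all others with probability ``p_outside``.  Every planted
occurrence is recorded so that each pipeline stage can be checked against
ground truth; background sequence may still contain chance occurrences, and
the truth object distinguishes the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .expression import ExpressionMatrix
from .motifs import IUPACMotif, SequenceRecord, expand_motif, write_fasta
from Bio.Seq import Seq

_BASES = np.array(list("ACGT"))


def gen_expression(n: int, p: int, structure: str = "periodic",
                   noise_sd: float = 0.3, seed: int = 0,
                   n_blobs: int = 5) -> ExpressionMatrix:
    """Synthetic expression matrix with smooth low-dimensional structure.

    periodic: gene g follows sin(2*pi*t/p + phase_g) over p timepoints, the
    phase uniform on the circle, plus Gaussian noise — the whole dataset
    lives near a 2D circle.  blobs: an n_blobs-component Gaussian mixture.
    """
    if n < 10 or p < 2:
        raise ValueError("require n >= 10 and p >= 2")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    if structure == "periodic":
        phase = rng.uniform(0, 2 * np.pi, size=n)
        t = 2 * np.pi * np.arange(p) / p
        values = np.sin(t[None, :] + phase[:, None])
    elif structure == "blobs":
        centers = rng.normal(scale=3.0, size=(n_blobs, p))
        labels = rng.integers(n_blobs, size=n)
        values = centers[labels]
    else:
        raise ValueError(f"unknown structure {structure!r}")
    values = values + rng.normal(scale=noise_sd, size=(n, p))
    return ExpressionMatrix(gene_ids, values)


@dataclass(frozen=True)
class PlantSpec:
    """One motif to plant, localized around a focal expression profile.

    ``focal_fraction`` sets the region radius as the distance quantile that
    captures that fraction of genes around ``focal_profile`` (the profile of
    gene 0 when omitted).
    """

    motif: IUPACMotif
    p_inside: float = 0.7
    p_outside: float = 0.05
    focal_fraction: float = 0.2
    focal_profile: tuple[float, ...] | None = None
    strand: str = "forward"  # 'forward' or 'both'

    def __post_init__(self) -> None:
        for name in ("p_inside", "p_outside", "focal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.strand not in ("forward", "both"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class Plant:
    gene_id: str
    motif: str
    word: str
    start: int
    strand: str


@dataclass
class SyntheticTruth:
    """Ground truth of one generated fixture."""

    plants: list[Plant]
    inside_genes: dict[str, list[str]]  # motif string -> gene IDs in focal region
    params: dict

    def plants_for(self, motif: IUPACMotif | str) -> list[Plant]:
        key = str(motif)
        return [pl for pl in self.plants if pl.motif == key]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"plants": [vars(p) for p in self.plants],
                       "inside_genes": self.inside_genes,
                       "params": self.params}, fh, indent=2)


def gen_sequences(X: ExpressionMatrix, bg_at_fraction: float = 0.6,
                  length: int = 600, plants: list[PlantSpec] = (),
                  seed: int = 0, region_kind: str = "upstream"
                  ) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Background sequences with expression-localized planted occurrences.

    Background bases are i.i.d. with P(A) = P(T) = bg_at_fraction / 2.  Each
    gene receives at most one plant per motif; plant positions within a gene
    are sampled uniformly among windows that do not overlap a previous
    plant, so every recorded plant stays findable in the emitted sequence.
    """
    if not 0.0 <= bg_at_fraction <= 1.0:
        raise ValueError("bg_at_fraction must be in [0, 1]")
    for spec in plants:
        if len(spec.motif) > length:
            raise ValueError(f"motif {spec.motif} longer than sequence length")
    rng = np.random.default_rng(seed)
    n = X.n
    probs = np.array([bg_at_fraction / 2, (1 - bg_at_fraction) / 2,
                      (1 - bg_at_fraction) / 2, bg_at_fraction / 2])
    seqs = rng.choice(4, size=(n, length), p=probs)

    truth_plants: list[Plant] = []
    inside_map: dict[str, list[str]] = {}
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for spec in plants:
        focal = (np.asarray(spec.focal_profile, dtype=float)
                 if spec.focal_profile is not None else X.values[0])
        dist = np.linalg.norm(X.values - focal[None, :], axis=1)
        radius = np.quantile(dist, spec.focal_fraction)
        inside = dist <= radius
        inside_map[str(spec.motif)] = [g for g, i in zip(X.gene_ids, inside) if i]
        words = sorted(expand_motif(spec.motif))
        w = len(spec.motif)
        for g in range(n):
            p_plant = spec.p_inside if inside[g] else spec.p_outside
            if rng.random() >= p_plant:
                continue
            word = words[rng.integers(len(words))]
            strand = "+"
            if spec.strand == "both" and rng.random() < 0.5:
                strand = "-"
            placed = word if strand == "+" else str(Seq(word).reverse_complement())
            pos = _free_position(rng, length, w, occupied[g])
            if pos is None:
                continue
            occupied[g].append((pos, pos + w))
            seqs[g, pos : pos + w] = [("ACGT").index(b) for b in placed]
            truth_plants.append(Plant(X.gene_ids[g], str(spec.motif), word,
                                      pos, strand))

    records = [SequenceRecord(gid, "".join(_BASES[row]), region_kind)
               for gid, row in zip(X.gene_ids, seqs)]
    params = {"bg_at_fraction": bg_at_fraction, "length": length, "seed": seed,
              "region_kind": region_kind,
              "plants": [{"motif": str(s.motif), "p_inside": s.p_inside,
                          "p_outside": s.p_outside,
                          "focal_fraction": s.focal_fraction,
                          "strand": s.strand} for s in plants]}
    return records, SyntheticTruth(truth_plants, inside_map, params)


def _free_position(rng: np.random.Generator, length: int, w: int,
                   occupied: list[tuple[int, int]], tries: int = 100) -> int | None:
    for _ in range(tries):
        pos = int(rng.integers(0, length - w + 1))
        if all(pos + w <= a or pos >= b for a, b in occupied):
            return pos
    return None


def write_fixture(outdir, X: ExpressionMatrix, records: list[SequenceRecord],
                  truth: SyntheticTruth) -> None:
    """Emit expression TSV + FASTA + truth JSON so the CLI runs unchanged."""
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    X.to_tsv(d / "expression.tsv")
    write_fasta(records, d / "sequences.fasta")
    truth.to_json(d / "truth.json")
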