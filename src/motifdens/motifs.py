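"""IUPAC consensus motifs and occurrence scanning.

A motif is a short string over the 15-letter IUPAC DNA alphabet and denotes
the finite set of exact words obtained by expanding every degenerate symbol
(e.g. ``WAGACA`` denotes ``{AAGACA, TAGACA}``).  A sequence *contains* a
motif if at least one of its substrings belongs to that set; containment is
binary regardless of the number of occurrences.

Matching is implemented on 4-bit base masks (A=1, C=2, G=4, T=8): a sequence
base matches a motif symbol iff its bit is set in the symbol's mask.  Masked
bases (``N`` in an *input sequence*) carry mask 0 and never match anything.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASKS: dict[str, int] = {
    sym: sum(_BASE_BITS[b] for b in bases) for sym, bases in IUPAC_SETS.items()
}
_MASK_TO_SYM: dict[int, str] = {m: s for s, m in IUPAC_MASKS.items()}
_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
IUPAC_COMPLEMENT: dict[str, str] = {
    sym: _MASK_TO_SYM[sum(_BASE_BITS[_BASE_COMPLEMENT[b]] for b in bases)]
    for sym, bases in IUPAC_SETS.items()
}


class InvalidMotifError(ValueError):
    """Raised when a motif string contains a non-IUPAC symbol or is empty."""


@dataclass(frozen=True, order=True)
class IUPACMotif:
    """A degenerate DNA consensus string.

    Ordering is plain lexicographic on the symbol string, which is the
    deterministic tie-break used throughout the pipeline.
    """

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise InvalidMotifError("motif must have length >= 1")
        bad = set(self.symbols) - set(IUPAC_SETS)
        if bad:
            raise InvalidMotifError(f"invalid IUPAC symbol(s): {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    @property
    def cardinality(self) -> int:
        """Size of the denoted word set (product of symbol cardinalities)."""
        out = 1
        for s in self.symbols:
            out *= len(IUPAC_SETS[s])
        return out

    def masks(self) -> np.ndarray:
        """Per-position 4-bit base masks, dtype uint8."""
        return np.array([IUPAC_MASKS[s] for s in self.symbols], dtype=np.uint8)

    def is_degenerate_at(self, i: int) -> bool:
        return len(IUPAC_SETS[self.symbols[i]]) > 1


def expand_motif(motif: IUPACMotif) -> set[str]:
    """All exact words denoted by *motif* (Cartesian product of symbol sets)."""
    return {"".join(w) for w in itertools.product(*(IUPAC_SETS[s] for s in motif.symbols))}


def reverse_complement(motif: IUPACMotif) -> IUPACMotif:
    """Symbol-wise IUPAC complement in reversed order; an involution."""
    return IUPACMotif("".join(IUPAC_COMPLEMENT[s] for s in reversed(motif.symbols)))


def is_self_reverse_complement(motif: IUPACMotif) -> bool:
    return motif.symbols == reverse_complement(motif).symbols


def canonical(motif: IUPACMotif) -> IUPACMotif:
    """Lexicographically smaller of a motif and its reverse complement."""
    rc = reverse_complement(motif)
    return motif if motif.symbols <= rc.symbols else rc


def generalizations_of(motif: IUPACMotif, include_n: bool = True) -> set[IUPACMotif]:
    """One-symbol generalizations of every non-degenerate position.

    For each position holding a single nucleotide, emit one candidate per
    IUPAC symbol that is a strict superset of that nucleotide (7 per base,
    ``N`` included unless ``include_n`` is false).  Degenerate positions are
    left untouched, so a fully degenerate motif has no generalizations.
    """
    out: set[IUPACMotif] = set()
    for i, sym in enumerate(motif.symbols):
        base_mask = IUPAC_MASKS[sym]
        if len(IUPAC_SETS[sym]) != 1:
            continue
        for cand, mask in IUPAC_MASKS.items():
            if mask == base_mask or (mask & base_mask) != base_mask:
                continue
            if cand == "N" and not include_n:
                continue
            out.add(IUPACMotif(motif.symbols[:i] + cand + motif.symbols[i + 1 :]))
    return out


def elongations_of(motif: IUPACMotif) -> set[IUPACMotif]:
    """Candidates with any IUPAC symbol prepended or appended (30 per motif)."""
    out: set[IUPACMotif] = set()
    for sym in IUPAC_SETS:
        out.add(IUPACMotif(sym + motif.symbols))
        out.add(IUPACMotif(motif.symbols + sym))
    return out


# ---------------------------------------------------------------------------
# Sequences and scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One regulatory region attached to a gene.

    ``region_kind`` says which gene-proximal end of the stored sequence abuts
    the coding region: ``upstream`` regions end at the start codon (3' end of
    the stored string), ``downstream`` regions begin at the stop codon.
    """

    gene_id: str
    seq: str
    region_kind: str = "upstream"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        if self.region_kind not in ("upstream", "downstream"):
            raise ValueError(f"bad region_kind {self.region_kind!r}")


@dataclass(frozen=True)
class Occurrence:
    """A single motif match: 0-based half-open window on the stored strand."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    word: str    # matched word as read on the matching strand
    context: str  # stored-strand sequence +/- 10 bp, truncated at the ends


def _seq_masks(seq: str) -> np.ndarray:
    tbl = np.zeros(256, dtype=np.uint8)
    for b, m in _BASE_BITS.items():
        tbl[ord(b)] = m
        tbl[ord(b.lower())] = m
    return tbl[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class SequenceSet:
    """A collection of gene sequences packed for fast IUPAC scanning.

    All sequences are concatenated into one mask array with a zero separator
    between genes; a window containing a separator (or a masked base) can
    never match, so matches never straddle gene boundaries.
    """

    def __init__(self, records: Sequence[SequenceRecord]):
        ids = [r.gene_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene IDs in sequence set")
        self.records = list(records)
        self.gene_ids = ids
        self.n = len(records)
        lens = np.array([len(r.seq) for r in records], dtype=np.int64)
        self.lengths = lens
        self.starts = np.concatenate([[0], np.cumsum(lens + 1)[:-1]])
        buf = np.zeros(int(lens.sum()) + self.n, dtype=np.uint8)
        for s, rec in zip(self.starts, records):
            buf[s : s + len(rec.seq)] = _seq_masks(rec.seq)
        self._buf = buf

    def _match_starts(self, masks: np.ndarray) -> np.ndarray:
        """Global start positions where the mask vector matches."""
        w = len(masks)
        L = len(self._buf)
        if L < w:
            return np.empty(0, dtype=np.int64)
        ok = (self._buf[: L - w + 1] & masks[0]) != 0
        for j in range(1, w):
            ok &= (self._buf[j : L - w + 1 + j] & masks[j]) != 0
        return np.nonzero(ok)[0]

    def _strand_masks(self, motif: IUPACMotif, strands: str) -> list[tuple[str, np.ndarray]]:
        if strands not in ("forward", "both"):
            raise ValueError(f"bad strands {strands!r}")
        out = [("+", motif.masks())]
        if strands == "both" and not is_self_reverse_complement(motif):
            out.append(("-", reverse_complement(motif).masks()))
        return out

    def presence(self, motif: IUPACMotif, strands: str = "both") -> np.ndarray:
        """Boolean per-gene indicator: does the gene contain the motif?"""
        hit = np.zeros(self.n, dtype=bool)
        for _, masks in self._strand_masks(motif, strands):
            pos = self._match_starts(masks)
            if pos.size:
                genes = np.searchsorted(self.starts, pos, side="right") - 1
                hit[np.unique(genes)] = True
        return hit

    def scan(self, motif: IUPACMotif, strands: str = "both",
             context_bp: int = 10) -> list[Occurrence]:
        """All occurrences with +/- ``context_bp`` of stored-strand context.

        A self-reverse-complementary motif in ``both`` mode is scanned once
        per window (never double counted).
        """
        w = len(motif)
        occs: list[Occurrence] = []
        for strand, masks in self._strand_masks(motif, strands):
            for pos in self._match_starts(masks):
                g = int(np.searchsorted(self.starts, pos, side="right") - 1)
                off = int(pos - self.starts[g])
                rec = self.records[g]
                word = rec.seq[off : off + w].upper()
                if strand == "-":
                    word = str(Seq(word).reverse_complement())
                lo = max(0, off - context_bp)
                hi = min(len(rec.seq), off + w + context_bp)
                occs.append(Occurrence(rec.gene_id, off, off + w, strand,
                                       word, rec.seq[lo:hi].upper()))
        occs.sort(key=lambda o: (o.gene_id, o.start, o.strand))
        return occs


def scan_occurrences(motif: IUPACMotif, rec: SequenceRecord,
                     strands: str = "forward", context_bp: int = 10) -> list[Occurrence]:
    """Occurrences of *motif* in a single record (empty if seq shorter)."""
    if len(rec.seq) < len(motif):
        return []
    return SequenceSet([rec]).scan(motif, strands=strands, context_bp=context_bp)


@dataclass
class PresenceMatrix:
    """Binary per-gene containment of one motif (random variable M)."""

    gene_ids: list[str]
    values: np.ndarray  # bool, shape (n,)
    motif: IUPACMotif | None = None

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def n_m(self) -> int:
        return int(self.values.sum())


def presence_matrix(motif: IUPACMotif, records: Sequence[SequenceRecord],
                    strands: str = "both") -> PresenceMatrix:
    ss = records if isinstance(records, SequenceSet) else SequenceSet(records)
    return PresenceMatrix(list(ss.gene_ids), ss.presence(motif, strands), motif)


# ---------------------------------------------------------------------------
# FASTA and TSV plumbing
# ---------------------------------------------------------------------------

def read_fasta(path, region_kind: str = "upstream") -> list[SequenceRecord]:
    return [SequenceRecord(r.id, str(r.seq).upper(), region_kind)
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write((_BioSeqRecord(Seq(r.seq), id=r.gene_id, description="")
                 for r in records), str(path), "fasta")


def occurrences_to_rows(occs: Iterable[Occurrence]) -> Iterator[tuple]:
    """BED-like rows (gene_id, start, end, strand, word, context)."""
    for o in occs:
        yield (o.gene_id, o.start, o.end, o.strand, o.word, o.context)
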