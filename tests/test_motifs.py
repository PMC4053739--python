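"""IUPAC motif representation, expansion, generalization and scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import motifdens as md
from motifdens.motifs import IUPAC_SETS, InvalidMotifError, SequenceSet

from conftest import naive_scan, random_motif

MOTIF_STR = st.text(alphabet=sorted(IUPAC_SETS), min_size=1, max_size=9)


class TestExpansion:
    def test_worked_example(self):
        assert md.expand_motif(md.IUPACMotif("WAGACA")) == {"AAGACA", "TAGACA"}

    @pytest.mark.parametrize("motif,size", [("N", 4), ("WN", 8), ("ACGT", 1)])
    def test_cardinality_examples(self, motif, size):
        assert len(md.expand_motif(md.IUPACMotif(motif))) == size

    @given(MOTIF_STR)
    @settings(max_examples=100, deadline=None)
    def test_expansion_size_is_product_of_cardinalities(self, s):
        m = md.IUPACMotif(s)
        assert len(md.expand_motif(m)) == m.cardinality

    def test_invalid_symbol_rejected(self):
        with pytest.raises(InvalidMotifError):
            md.IUPACMotif("ACGU")
        with pytest.raises(InvalidMotifError):
            md.IUPACMotif("")


class TestReverseComplement:
    @pytest.mark.parametrize("m,rc", [("ACGT", "ACGT"), ("WAGACA", "TGTCTW"),
                                      ("N", "N"), ("RY", "RY")])
    def test_examples(self, m, rc):
        assert str(md.reverse_complement(md.IUPACMotif(m))) == rc

    @given(MOTIF_STR)
    @settings(max_examples=100, deadline=None)
    def test_involution(self, s):
        m = md.IUPACMotif(s)
        assert md.reverse_complement(md.reverse_complement(m)) == m

    @given(MOTIF_STR)
    @settings(max_examples=50, deadline=None)
    def test_word_sets_are_reverse_complements(self, s):
        from Bio.Seq import Seq
        m = md.IUPACMotif(s)
        rc_words = {str(Seq(w).reverse_complement()) for w in md.expand_motif(m)}
        assert rc_words == md.expand_motif(md.reverse_complement(m))


class TestGeneralization:
    def test_worked_examples_present(self):
        cands = {str(c) for c in md.generalizations_of(md.IUPACMotif("WAGACA"))}
        assert {"WWGACA", "WHGACA", "WARACA"} <= cands

    def test_candidate_count(self):
        # 5 non-degenerate positions x 7 strict supersets each
        assert len(md.generalizations_of(md.IUPACMotif("WAGACA"))) == 35

    def test_fully_degenerate_has_none(self):
        assert md.generalizations_of(md.IUPACMotif("NNNN")) == set()

    def test_exclude_n_flag(self):
        cands = md.generalizations_of(md.IUPACMotif("A"), include_n=False)
        assert len(cands) == 6 and md.IUPACMotif("N") not in cands

    @given(MOTIF_STR)
    @settings(max_examples=50, deadline=None)
    def test_candidates_are_strict_supersets(self, s):
        m = md.IUPACMotif(s)
        words = md.expand_motif(m)
        for cand in md.generalizations_of(m):
            assert words < md.expand_motif(cand)


class TestScanning:
    def test_worked_example(self):
        rec = md.SequenceRecord("g", "TTAGACAT")
        occs = md.scan_occurrences(md.IUPACMotif("WAGACA"), rec, "forward")
        assert [(o.start, o.end, o.strand, o.word)
                for o in occs] == [(1, 7, "+", "TAGACA")]

    def test_sequence_shorter_than_motif(self):
        rec = md.SequenceRecord("g", "ACG")
        assert md.scan_occurrences(md.IUPACMotif("ACGTT"), rec) == []

    def test_overlapping_matches_allowed(self):
        rec = md.SequenceRecord("g", "AAA")
        occs = md.scan_occurrences(md.IUPACMotif("AA"), rec, "forward")
        assert sorted(o.start for o in occs) == [0, 1]

    def test_masked_bases_never_match(self):
        rec = md.SequenceRecord("g", "ANA")
        assert md.scan_occurrences(md.IUPACMotif("ANA"), rec, "forward") == []
        assert md.scan_occurrences(md.IUPACMotif("NNN"), rec, "forward") == []

    def test_reverse_strand_occurrence(self):
        # TGTCTA on the stored strand is WAGACA read on the reverse strand
        rec = md.SequenceRecord("g", "CCTGTCTACC")
        occs = md.scan_occurrences(md.IUPACMotif("WAGACA"), rec, "both")
        assert [(o.start, o.strand, o.word) for o in occs] == [(2, "-", "TAGACA")]

    def test_self_rc_motif_counted_once_per_window(self):
        rec = md.SequenceRecord("g", "GACGTC")
        occs = md.scan_occurrences(md.IUPACMotif("ACGT"), rec, "both")
        assert len(occs) == 1

    def test_context_truncated_at_ends(self):
        rec = md.SequenceRecord("g", "AAGACATTTTTTTTTTTTTT")
        (o,) = md.scan_occurrences(md.IUPACMotif("AAGACA"), rec, "forward")
        assert o.context == rec.seq[0:16]

    def test_agreement_with_naive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            motif = random_motif(rng, int(rng.integers(2, 8)))
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(5, 60)),
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            rec = md.SequenceRecord("g", seq)
            got = sorted(o.start for o in
                         md.scan_occurrences(md.IUPACMotif(motif), rec, "forward"))
            assert got == naive_scan(motif, seq)


class TestPresence:
    def test_counts_positive_genes(self):
        recs = [md.SequenceRecord("g1", "TTAGACAT"), md.SequenceRecord("g2", "CCCCCC")]
        pm = md.presence_matrix(md.IUPACMotif("WAGACA"), recs, "forward")
        assert pm.n_m == 1 and list(pm.values) == [True, False]

    def test_absent_everywhere(self):
        recs = [md.SequenceRecord("g1", "CCCC"), md.SequenceRecord("g2", "GGGG")]
        assert md.presence_matrix(md.IUPACMotif("AAA"), recs).n_m == 0

    def test_both_strands_dominate_forward(self):
        rng = np.random.default_rng(7)
        recs = [md.SequenceRecord(f"g{i}", "".join(rng.choice(list("ACGT"), 40)))
                for i in range(30)]
        m = md.IUPACMotif("AGAC")
        fwd = md.presence_matrix(m, recs, "forward").values
        both = md.presence_matrix(m, recs, "both").values
        assert (both >= fwd).all()

    def test_presence_equals_union_of_expansion(self):
        rng = np.random.default_rng(3)
        recs = [md.SequenceRecord(f"g{i}", "".join(rng.choice(list("ACGT"), 50)))
                for i in range(40)]
        ss = SequenceSet(recs)
        m = md.IUPACMotif("RAGAW")
        by_words = np.zeros(40, dtype=bool)
        for w in md.expand_motif(m):
            by_words |= ss.presence(md.IUPACMotif(w), "forward")
        assert (ss.presence(m, "forward") == by_words).all()

    def test_duplicate_ids_rejected(self):
        recs = [md.SequenceRecord("g", "ACGT"), md.SequenceRecord("g", "ACGT")]
        with pytest.raises(ValueError):
            SequenceSet(recs)


def test_fasta_roundtrip(tmp_path):
    recs = [md.SequenceRecord("gene1", "ACGTACGT"), md.SequenceRecord("gene2", "TTTTAA")]
    md.write_fasta(recs, tmp_path / "x.fasta")
    back = md.read_fasta(tmp_path / "x.fasta")
    assert [(r.gene_id, r.seq) for r in back] == [(r.gene_id, r.seq) for r in recs]
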