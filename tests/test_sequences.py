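"""Sequence container, FASTA I/O, edit application and allele diffing."""

import numpy as np
import pytest

from capripep import (
    ProteinSequence,
    VariantEdit,
    apply_edits,
    diff_alleles,
    read_fasta,
    write_fasta,
)
from capripep.errors import (
    EditConflictError,
    EditRangeError,
    FastaParseError,
    NotComparableError,
    SequenceValidationError,
    UsageError,
)
from capripep.sequences import STANDARD_AA, load_edit_list


class TestFastaIO:
    def test_single_record_parsed(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nPLGPV\n")
        (rec,) = read_fasta(p)
        assert rec.id == "x"
        assert rec.residues == "PLGPV"
        assert rec.n_residues == 5

    def test_lowercase_and_whitespace_normalized(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">y\nplg pv\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "PLGPV"

    def test_terminal_stop_symbol_stripped(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">z\nMKLV*\n")
        (rec,) = read_fasta(p)
        assert rec.residues == "MKLV"

    def test_invalid_residue_reported_with_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">bad\nAKJLM\n")
        with pytest.raises(SequenceValidationError, match="'J' at position 3"):
            read_fasta(p)

    def test_text_before_header_is_a_parse_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("PLGPV\n>x\nAA\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FastaParseError):
            read_fasta(p)

    def test_write_read_round_trip_preserves_metadata(self, tmp_path):
        seqs = [
            ProteinSequence(id="NP_1", residues="MKLVWY", gene="CSN2", allele="A"),
            ProteinSequence(id="plain", residues="ACDE"),
        ]
        p = tmp_path / "out.fasta"
        write_fasta(seqs, p)
        back = read_fasta(p)
        assert [(s.id, s.residues, s.gene, s.allele) for s in back] == [
            (s.id, s.residues, s.gene, s.allele) for s in seqs
        ]


class TestProteinSequence:
    def test_ambiguity_codes_rejected_by_default(self):
        for bad in "BZX":
            with pytest.raises(SequenceValidationError):
                ProteinSequence(id="s", residues=f"AA{bad}")

    def test_custom_alphabet_accepts_extra_codes(self):
        seq = ProteinSequence(id="s", residues="AAX",
                              alphabet=STANDARD_AA | {"X"})
        assert seq.n_residues == 3

    def test_trim_removes_leading_residues(self):
        seq = ProteinSequence(id="s", residues="MKLVWY")
        assert seq.trimmed(2).residues == "LVWY"


class TestApplyEdits:
    def test_empty_edit_list_is_identity(self):
        ref = ProteinSequence(id="r", residues="ACDEF", gene="G", allele="A")
        out = apply_edits(ref, [], new_allele="B")
        assert out.residues == ref.residues
        assert out.allele == "B"
        assert ref.residues == "ACDEF"  # input untouched

    def test_double_substitution_releases_new_motif(self):
        # T->A at two consecutive positions turns an interior TTM into AAM,
        # the allele-E style change that creates a new candidate peptide.
        ref = ProteinSequence(id="r", residues="GPLTTMQK", gene="CSN1S1", allele="A")
        edits = [
            VariantEdit("substitution", 4, ref_residue="T", alt_residue="A"),
            VariantEdit("substitution", 5, ref_residue="T", alt_residue="A"),
        ]
        var = apply_edits(ref, edits, new_allele="E")
        assert var.residues == "GPLAAMQK"
        assert "AAM" in var.residues and "TTM" not in var.residues

    def test_single_deletion_shifts_downstream(self):
        ref = ProteinSequence(id="r", residues="ACDEF")
        var = apply_edits(ref, [VariantEdit("deletion", 3, ref_residue="D")])
        assert var.residues == "ACEF"
        assert var.n_residues == 4

    def test_insertion_after_position(self):
        ref = ProteinSequence(id="r", residues="ACDEF")
        var = apply_edits(ref, [VariantEdit("insertion", 2, alt_residue="WW")])
        assert var.residues == "ACWWDEF"

    def test_insertion_at_zero_prepends(self):
        ref = ProteinSequence(id="r", residues="ACD")
        var = apply_edits(ref, [VariantEdit("insertion", 0, alt_residue="M")])
        assert var.residues == "MACD"

    def test_ref_mismatch_is_conflict(self):
        ref = ProteinSequence(id="r", residues="ACDEF")
        with pytest.raises(EditConflictError, match="expected 'T', found 'C'"):
            apply_edits(ref, [VariantEdit("substitution", 2, "T", "A")])

    def test_out_of_range_position(self):
        ref = ProteinSequence(id="r", residues="ACD")
        with pytest.raises(EditRangeError):
            apply_edits(ref, [VariantEdit("deletion", 9, ref_residue="A")])

    def test_descending_application_keeps_reference_frame(self):
        # Deletion before a substitution must not shift its coordinates.
        ref = ProteinSequence(id="r", residues="ACDEF")
        edits = [
            VariantEdit("deletion", 2, ref_residue="C"),
            VariantEdit("substitution", 5, ref_residue="F", alt_residue="Y"),
        ]
        assert apply_edits(ref, edits).residues == "ADEY"


class TestDiffAlleles:
    def test_identical_sequences_give_empty_diff(self):
        a = ProteinSequence(id="a", residues="ACDEF", gene="G")
        assert diff_alleles(a, a) == []

    def test_single_substitution_found(self):
        # The alpha-S2 F-style A->P change inside an AGAF context.
        a = ProteinSequence(id="a", residues="KQAGAFPY", gene="CSN1S2", allele="A")
        b = ProteinSequence(id="f", residues="KQAGPFPY", gene="CSN1S2", allele="F")
        (edit,) = diff_alleles(a, b)
        assert edit == VariantEdit("substitution", 5, "A", "P")
        assert apply_edits(a, [edit]).residues == b.residues

    def test_gene_mismatch_rejected(self):
        a = ProteinSequence(id="a", residues="ACD", gene="G1")
        b = ProteinSequence(id="b", residues="ACD", gene="G2")
        with pytest.raises(UsageError, match="gene mismatch"):
            diff_alleles(a, b)

    def test_contiguous_deletion_recovered(self):
        a = ProteinSequence(id="a", residues="MKLVWYPQ", gene="G")
        b = ProteinSequence(id="b", residues="MKLPQ", gene="G")
        edits = diff_alleles(a, b)
        assert all(e.kind == "deletion" for e in edits)
        assert apply_edits(a, edits).residues == b.residues

    def test_contiguous_insertion_recovered(self):
        a = ProteinSequence(id="a", residues="MKLPQ", gene="G")
        b = ProteinSequence(id="b", residues="MKLVWYPQ", gene="G")
        edits = diff_alleles(a, b)
        assert [e.kind for e in edits] == ["insertion"]
        assert apply_edits(a, edits).residues == b.residues

    def test_indel_plus_substitution_not_comparable(self):
        a = ProteinSequence(id="a", residues="MKLVWYPQ", gene="G")
        b = ProteinSequence(id="b", residues="MALPQ", gene="G")
        with pytest.raises(NotComparableError):
            diff_alleles(a, b)

    def test_round_trip_on_random_equal_length_pairs(self):
        """diff then apply reproduces the target on 100 random pairs."""
        rng = np.random.default_rng(7)
        letters = sorted(STANDARD_AA)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            base = "".join(rng.choice(letters, n))
            chars = list(base)
            for pos in rng.choice(n, size=int(rng.integers(0, 4)), replace=False):
                chars[pos] = letters[int(rng.integers(20))]
            other = "".join(chars)
            a = ProteinSequence(id="a", residues=base, gene="G")
            b = ProteinSequence(id="b", residues=other, gene="G")
            edits = diff_alleles(a, b)
            assert apply_edits(a, edits).residues == other
            if base == other:
                assert edits == []


class TestEditListConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "edits.yaml"
        p.write_text(
            "edits:\n"
            "  - {kind: substitution, position: 4, ref: T, alt: A}\n"
            "  - {kind: deletion, position: 2, ref: C}\n"
        )
        edits = load_edit_list(p)
        assert edits[0] == VariantEdit("substitution", 4, "T", "A")
        assert edits[1] == VariantEdit("deletion", 2, "C", "")
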