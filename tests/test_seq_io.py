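from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salmhc import seq_io
from salmhc.seq_io import (
    FormatError,
    PairingError,
    SequenceRecord,
    read_fasta,
    read_fastq,
    read_fastq_pairs,
    read_primer_scheme,
    reverse_complement,
    translate,
    write_fasta,
    write_fastq,
)

nt_strings = st.text(alphabet="ACGTN", min_size=1, max_size=120)


def test_fasta_single_record(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">x desc\nACGT\n")
    recs = read_fasta(p)
    assert len(recs) == 1
    assert recs[0].id == "x" and recs[0].description == "desc"
    assert recs[0].residues == "ACGT"


def test_fasta_empty_file_and_order(tmp_path):
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    assert read_fasta(empty) == []
    multi = tmp_path / "m.fasta"
    multi.write_text(">a\nAA\n>b\nCC\n>c\nGG\n")
    assert [r.id for r in read_fasta(multi)] == ["a", "b", "c"]


def test_fasta_empty_sequence_is_error(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">ok\nACGT\n>broken\n>next\nAC\n")
    with pytest.raises(FormatError, match="broken"):
        read_fasta(p)


@given(nt_strings)
@settings(deadline=None, max_examples=50)
def test_fasta_round_trip(tmp_path_factory, seq):
    p = tmp_path_factory.mktemp("rt") / "rt.fasta"
    rec = SequenceRecord("id1", seq, "some description")
    write_fasta([rec], p)
    back = read_fasta(p)
    assert back == [rec]


def test_fastq_round_trip_and_phred33(tmp_path):
    p = tmp_path / "r.fastq"
    p.write_text("@r1\nACGT\n+\nIIII\n")
    recs = read_fastq(p)
    assert recs[0].qualities == (40, 40, 40, 40)  # 'I' is Phred 40
    out = tmp_path / "out.fastq"
    write_fastq(recs, out)
    assert out.read_text() == p.read_text()


def test_fastq_pairs_match_and_mismatch(tmp_path):
    r1 = tmp_path / "r1.fastq"
    r2 = tmp_path / "r2.fastq"
    r1.write_text("@a/1\nACGT\n+\nIIII\n@b/1\nACGT\n+\nIIII\n")
    r2.write_text("@a/2\nTTTT\n+\nIIII\n@b/2\nTTTT\n+\nIIII\n")
    pairs = read_fastq_pairs(r1, r2)
    assert len(pairs) == 2
    r2.write_text("@a/2\nTTTT\n+\nIIII\n")
    with pytest.raises(PairingError):
        read_fastq_pairs(r1, r2)
    r2.write_text("@zz/2\nTTTT\n+\nIIII\n@b/2\nTTTT\n+\nIIII\n")
    with pytest.raises(PairingError, match="zz"):
        read_fastq_pairs(r1, r2)


def test_reverse_complement_basics():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AAC") == "GTT"
    assert reverse_complement("NAT") == "ATN"
    with pytest.raises(ValueError):
        reverse_complement("ACGU")


@given(nt_strings)
@settings(deadline=None)
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


@pytest.mark.parametrize(
    "nt,frame,expected",
    [
        ("ATGAAA", 0, "MK"),
        ("TATGAAA", 1, "MK"),
        ("TAA", 0, "*"),
        ("ATGA", 0, "M"),  # trailing partial codon dropped
        ("ANTGGG", 0, "XG"),  # N codon -> X
    ],
)
def test_translate(nt, frame, expected):
    assert translate(nt, frame) == expected


@given(nt_strings)
@settings(deadline=None)
def test_translate_length(seq):
    assert len(translate(seq, 0)) == len(seq) // 3


def test_load_reference_library_bundled(library):
    by_locus = {}
    for a in library:
        by_locus.setdefault(a.locus, []).append(a)
    assert set(by_locus) == {"UBA", "DAA", "DAB"}
    uba = {str(a.name) for a in by_locus["UBA"]}
    assert "Sasa-UBA*07:01" in uba
    assert all(a.mhc_class == "I" for a in by_locus["UBA"])
    assert all(a.mhc_class == "II" for a in by_locus["DAA"] + by_locus["DAB"])
    # translations carry no internal stops (clean frames by construction)
    assert all("*" not in a.aa_seq for a in library)


def test_load_reference_library_duplicate_and_bad_names(tmp_path):
    p = tmp_path / "lib.fasta"
    p.write_text(">Sasa-UBA*01:01\n" + "ATG" * 20 + "\n>Sasa-UBA*01:01\n" + "ATG" * 20 + "\n")
    with pytest.raises(FormatError, match="duplicate"):
        seq_io.load_reference_library(p)
    p.write_text(">not_an_allele\n" + "ATG" * 20 + "\n")
    with pytest.raises(FormatError, match="not_an_allele"):
        seq_io.load_reference_library(p)


def test_load_reference_library_old_style_header(tmp_path):
    p = tmp_path / "lib.fasta"
    p.write_text(">Sasa-DAA*0101\n" + "ATGGCT" * 10 + "\n")
    [allele] = seq_io.load_reference_library(p)
    assert allele.name.group == 1 and allele.name.protein == 1
    assert allele.locus == "DAA" and allele.mhc_class == "II"


def test_primer_scheme_validation(tmp_path, scheme):
    assert set(scheme.genes()) == {"UBA", "DAA", "DAB"}
    assert len(scheme.forwards["UBA"]) == 2
    bad = tmp_path / "bad.tsv"
    bad.write_text(
        "gene\trole\tlabel\tsequence\n"
        "X\tforward\tf1\tACGTACGTAC\n"
        "X\tforward\tf2\tACGTACGTACGG\n"  # f1 is a prefix of f2
        "X\treverse\tr1\tGGGGCCCC\n"
    )
    with pytest.raises(FormatError, match="prefix"):
        read_primer_scheme(bad)


def test_phred64_heuristic_warns(tmp_path):
    p = tmp_path / "p64.fastq"
    # Phred+64 'h' ~ Q40 reads decoded as +33 give absurd Q71
    p.write_text("@r\nACGT\n+\nhhhh\n")
    with pytest.warns(UserWarning, match="Phred"):
        read_fastq(p)
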