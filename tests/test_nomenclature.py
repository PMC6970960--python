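from __future__ import annotations

import random

import pytest

from salmhc.nomenclature import (
    AlleleName,
    AlleleNameError,
    aa_difference,
    parse_allele_name,
    propose_name,
)


class FakeAllele:
    """Minimal library entry: name + region-restricted sequences."""

    def __init__(self, name: str, nt: str, aa: str):
        self.name = parse_allele_name(name)
        self.nt_seq = nt
        self.aa_seq = aa


def identity_aligner(a: str, b: str) -> tuple[str, str]:
    assert len(a) == len(b)
    return a, b


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Sasa-UBA*01:01:01:01", (1, 1, 1, 1)),
        ("Sasa-DAA*0101", (1, 1, None, None)),
        ("Sasa-DAA*010102", (1, 1, 2, None)),
        ("MHC-Sasa-DAA*0101", (1, 1, None, None)),
        ("UBA*07:01", (7, 1, None, None)),
        ("Sasa-UBA*35", (35, None, None, None)),
    ],
)
def test_parse_allele_name(text, expected):
    n = parse_allele_name(text)
    assert (n.group, n.protein, n.synonymous, n.noncoding) == expected


@pytest.mark.parametrize("bad", ["Sasa-DAA*011", "Sasa-DAA*01:1", "Sasa-DAA", "DAA01:01"])
def test_parse_errors(bad):
    with pytest.raises(AlleleNameError):
        parse_allele_name(bad)


def test_format_round_trip_on_fixture_names(library):
    for allele in library:
        text = str(allele.name)
        assert str(parse_allele_name(text)) == text
        assert ":" in text  # canonical rendering is new-style


def test_name_field_dependency():
    with pytest.raises(AlleleNameError):
        AlleleName("Sasa", "UBA", 1, None, 1)  # synonymous without protein


def test_aa_difference():
    assert aa_difference("MKL", "MKL") == 0
    assert aa_difference("MKL", "MQL") == 1
    assert aa_difference("MKL-", "MQLV") == 2  # mismatch + gap-vs-residue
    with pytest.raises(ValueError):
        aa_difference("", "")


def _library(locus: str, entries: list[tuple[str, str, str]]) -> list[FakeAllele]:
    return [FakeAllele(f"Sasa-{locus}*{n}", nt, aa) for n, nt, aa in entries]


def _mutate_aa(aa: str, k: int) -> str:
    out = list(aa)
    for i in range(k):
        out[i] = "W" if out[i] != "W" else "F"
    return "".join(out)


BASE_AA = "MKLVEQSTRDAYGHIP"
BASE_NT = "ATG" * len(BASE_AA)  # nt content only matters for identity checks


@pytest.mark.parametrize(
    "locus,d,expected_status",
    [
        ("UBA", 1, "new_protein"),
        ("UBA", 3, "new_protein"),  # class I boundary: below 4
        ("UBA", 4, "new_group"),
        ("DAA", 2, "new_protein"),  # class II boundary: below 3
        ("DAA", 3, "new_group"),
        ("DAB", 3, "new_group"),
    ],
)
def test_threshold_boundaries(locus, d, expected_status):
    lib = _library(locus, [("01:01", BASE_NT, BASE_AA), ("02:01", BASE_NT, _mutate_aa(BASE_AA, 10))])
    cand = _mutate_aa(BASE_AA, d)
    prop = propose_name(cand, "C" * len(BASE_NT), locus, lib, aligner=identity_aligner)
    assert prop.status == expected_status
    assert prop.aa_diff_to_closest == d
    if expected_status == "new_protein":
        assert prop.proposed.group == 1 and prop.proposed.protein == 2
    else:
        assert prop.proposed.group == 3 and prop.proposed.protein == 1


def test_known_and_ambiguous_and_synonymous():
    lib = _library(
        "DAA",
        [
            ("01:01", BASE_NT, BASE_AA),
            ("01:02", BASE_NT, BASE_AA),  # indistinguishable within the region
            ("02:01", "GGG" * len(BASE_AA), _mutate_aa(BASE_AA, 8)),
        ],
    )
    amb = propose_name(BASE_AA, BASE_NT, "DAA", lib, aligner=identity_aligner)
    assert amb.status == "ambiguous_within_amplicon"
    assert [str(n) for n in amb.co_closest] == ["Sasa-DAA*01:01", "Sasa-DAA*01:02"]

    uniq = _library("DAA", [("01:01", BASE_NT, BASE_AA), ("02:01", "G" * 48, _mutate_aa(BASE_AA, 8))])
    known = propose_name(BASE_AA, BASE_NT, "DAA", uniq, aligner=identity_aligner)
    assert known.status == "known" and str(known.proposed) == "Sasa-DAA*01:01"
    assert not known.requires_verification

    # same protein, different nucleotides -> new synonymous number
    syn = propose_name(BASE_AA, "T" + BASE_NT[1:], "DAA", uniq, aligner=identity_aligner)
    assert syn.status == "new_synonymous"
    assert (syn.proposed.group, syn.proposed.protein, syn.proposed.synonymous) == (1, 1, 2)


def test_uba_3501_plus_two_aa_proposes_3502():
    lib = _library(
        "UBA",
        [
            ("35:01", BASE_NT, BASE_AA),
            ("13:01", "G" * 48, _mutate_aa(BASE_AA, 12)),
        ],
    )
    cand = _mutate_aa(BASE_AA, 2)
    prop = propose_name(cand, "C" * 48, "UBA", lib, aligner=identity_aligner)
    assert prop.status == "new_protein"
    assert str(prop.proposed) == "Sasa-UBA*35:02"
    assert str(prop.base_allele) == "Sasa-UBA*35:01"
    assert prop.requires_verification


def test_proposal_invariant_under_library_permutation():
    lib = _library(
        "UBA",
        [
            ("02:01", "A" * 48, _mutate_aa(BASE_AA, 6)),
            ("35:01", BASE_NT, BASE_AA),
            ("13:01", "G" * 48, _mutate_aa(BASE_AA, 12)),
        ],
    )
    cand = _mutate_aa(BASE_AA, 2)
    rng = random.Random(0)
    baseline = propose_name(cand, "C" * 48, "UBA", lib, aligner=identity_aligner)
    for _ in range(5):
        shuffled = lib[:]
        rng.shuffle(shuffled)
        prop = propose_name(cand, "C" * 48, "UBA", shuffled, aligner=identity_aligner)
        assert prop.status == baseline.status
        assert str(prop.proposed) == str(baseline.proposed)


def test_empty_library_is_configuration_error():
    with pytest.raises(ValueError, match="empty"):
        propose_name(BASE_AA, BASE_NT, "UBA", [], aligner=identity_aligner)
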