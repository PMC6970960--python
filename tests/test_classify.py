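from __future__ import annotations

import itertools
import random

import pytest

from salmhc.classify import (
    adjust_frame,
    align_pair,
    amplified_region,
    classify_candidate,
    find_closest,
    global_align,
    slice_library,
)
from salmhc.seq_io import translate


def _count_stops_all_trims(nt: str) -> dict[tuple[int, int], int]:
    out = {}
    for l, r in itertools.product(range(3), repeat=2):
        if (len(nt) - l - r) % 3 == 0:
            out[(l, r)] = translate(nt[l : len(nt) - r] if r else nt[l:], 0).count("*")
    return out


def test_adjust_frame_in_frame_orf():
    orf = "ATGGCTAAAGGG" * 4
    res = adjust_frame(orf)
    assert (res.left, res.right) == (0, 0)
    assert res.clean and res.aa == translate(orf)


def test_adjust_frame_with_leading_offset_matches_enumeration():
    rng = random.Random(7)
    codons = ["ATG", "GCT", "AAA", "GGG", "TGC", "CTT", "GAA", "CAT", "ATC", "CCA", "GTT", "TAC"]
    orf = "".join(rng.choice(codons) for _ in range(14))
    shifted = "T" + orf
    res = adjust_frame(shifted)
    enumerated = _count_stops_all_trims(shifted)
    best = min(enumerated.values())
    assert enumerated[(res.left, res.right)] == best
    assert (res.left, res.right) == (1, 0)


def test_adjust_frame_all_frames_stopped_is_flagged():
    dirty = "TTAA" * 10  # period-4 repeat puts a TAA stop into every frame
    res = adjust_frame(dirty)
    assert not res.clean
    assert res.n_stops >= 1


@pytest.mark.parametrize(
    "a,b,alphabet,identity,similarity",
    [
        ("ACGTACGT", "ACGTACGT", "nt", 100.0, 100.0),
        ("MKLVMKLV", "MKLVMKLV", "aa", 100.0, 100.0),
        ("MKLV", "MRLV", "aa", 75.0, 100.0),  # K/R scores positive in BLOSUM62
    ],
)
def test_align_pair_identity_similarity(a, b, alphabet, identity, similarity):
    res = align_pair(a, b, alphabet)
    assert res.identity == pytest.approx(identity)
    assert res.similarity == pytest.approx(similarity)
    assert res.similarity >= res.identity


def test_align_pair_disjoint_alphabets_degenerate():
    res = align_pair("AAAA", "TTTT", "nt")
    assert res.identity == 0.0 and res.similarity == 0.0 and res.score == 0.0


def test_global_align_trims_overhangs():
    x, y = global_align("MKLV", "KLV", "aa")
    assert x == "KLV" and y == "KLV"


def test_amplified_region_exact_and_fuzzy(library, primers):
    fwd = primers[("DAA", "forward", "DAA_F")]
    rev = primers[("DAA", "reverse", "DAA_R")]
    ref = library[0].nt_seq if library[0].locus == "DAA" else None
    daa = [a for a in library if a.locus == "DAA"][0]
    i, j = amplified_region(daa.nt_seq, fwd, rev)
    assert daa.nt_seq[i - len(fwd) : i] == fwd
    # a single mismatch inside the primer site still locates via local alignment
    mutated = daa.nt_seq[: i - 10] + ("A" if daa.nt_seq[i - 10] != "A" else "C") + daa.nt_seq[i - 9 :]
    i2, j2 = amplified_region(mutated, fwd, rev)
    assert abs(i2 - i) <= 2 and j2 == j


def test_find_closest_self_and_two_aa_neighbour(library, novel_alleles, primers, insert_of):
    fwd = primers[("UBA", "forward", "UBA1_F")]
    rev = primers[("UBA", "reverse", "UBA_R")]
    regions = slice_library(library, fwd, rev, "UBA")
    assert len(regions) == 7

    # a library allele's own region: identity 100, sibling agrees
    self_seq = regions[2].nt_seq
    hits, sibling, discordant = find_closest(self_seq, regions)
    assert hits[0].nt_identity == pytest.approx(100.0)
    assert str(sibling) == str(hits[0].name)
    assert not discordant

    # the sequence two amino acids from UBA*35:01 must land on it
    cand = insert_of(novel_alleles["AS7UBAs1"], fwd, rev)
    hits2, sibling2, _ = find_closest(cand, regions)
    assert str(hits2[0].name) == "Sasa-UBA*35:01"


def test_find_closest_requires_two_alleles(library, primers):
    fwd = primers[("UBA", "forward", "UBA1_F")]
    rev = primers[("UBA", "reverse", "UBA_R")]
    regions = slice_library(library, fwd, rev, "UBA")
    with pytest.raises(ValueError):
        find_closest(regions[0].nt_seq, regions[:1])


def test_tree_concordance_on_bundled_library(library, primers):
    """Identity criterion and NJ sibling agree for every bundled allele."""
    for gene, flabel in [("UBA", "UBA1_F"), ("DAA", "DAA_F"), ("DAB", "DAB1_F")]:
        fwd = dict({k[2]: v for k, v in primers.items() if k[0] == gene and k[1] == "forward"})[flabel]
        rev = {k[2]: v for k, v in primers.items() if k[0] == gene and k[1] == "reverse"}.popitem()[1]
        regions = slice_library(library, fwd, rev, gene)
        for entry in regions:
            hits, sibling, discordant = find_closest(entry.nt_seq, regions)
            co_best = {str(h.name) for h in hits if h.nt_identity == hits[0].nt_identity}
            # co-best set rather than strict equality: DAA*01:01/01:02 are
            # deliberately indistinguishable over the amplified region
            assert str(entry.name) in co_best
            assert not discordant


def test_classify_candidate_statuses(library, novel_alleles, primers, insert_of):
    fwd = primers[("DAA", "forward", "DAA_F")]
    rev = primers[("DAA", "reverse", "DAA_R")]
    known_full = [a for a in library if str(a.name) == "Sasa-DAA*04:01"][0].nt_seq
    rep = classify_candidate("c1", insert_of(known_full, fwd, rev), "DAA", library, fwd, rev)
    assert rep.proposal.status == "known"
    assert rep.frame_trim == (0, 0) and rep.clean_frame

    amb_full = [a for a in library if str(a.name) == "Sasa-DAA*01:02"][0].nt_seq
    rep2 = classify_candidate("c2", insert_of(amb_full, fwd, rev), "DAA", library, fwd, rev)
    assert rep2.proposal.status == "ambiguous_within_amplicon"
    assert {str(n) for n in rep2.proposal.co_closest} == {"Sasa-DAA*01:01", "Sasa-DAA*01:02"}

    fwd_u = primers[("UBA", "forward", "UBA4_F")]
    rev_u = primers[("UBA", "reverse", "UBA_R")]
    rep3 = classify_candidate(
        "c3", insert_of(novel_alleles["AS5UBAs1"], fwd_u, rev_u), "UBA", library, fwd_u, rev_u
    )
    assert rep3.proposal.status == "new_group"
    assert rep3.proposal.aa_diff_to_closest >= 4
    assert any("transmembrane" in w for w in rep3.warnings)
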