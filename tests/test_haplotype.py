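from __future__ import annotations

import itertools
import random

import pytest

from salmhc.haplotype import compare_haplotype_sets, phase_two_locus


def test_all_homozygous_cohort_resolves_in_step_one():
    calls = {
        "A1": {"DAA": ["x"], "DAB": ["p"]},
        "A2": {"DAA": ["y"], "DAB": ["q"]},
    }
    res = phase_two_locus(calls)
    assert res.unresolved_animals == []
    assert {h.pair for h in res.haplotypes} == {("x", "p"), ("y", "q")}


def test_single_daa_with_two_dabs_pairs_with_both_and_warns():
    calls = {"AS5": {"DAA": ["DAA*06:01"], "DAB": ["DAB*06:01", "AS5DABs2"]}}
    res = phase_two_locus(calls)
    assert {h.pair for h in res.haplotypes} == {
        ("DAA*06:01", "DAB*06:01"),
        ("DAA*06:01", "AS5DABs2"),
    }
    assert any("AS5" in w for w in res.warnings)


def test_double_heterozygote_resolved_by_known_haplotype():
    calls = {
        "hom": {"DAA": ["a"], "DAB": ["p"]},
        "het": {"DAA": ["a", "b"], "DAB": ["p", "q"]},
    }
    res = phase_two_locus(calls)
    assert res.per_animal_phase["het"] == [("a", "p"), ("b", "q")]
    assert res.unresolved_animals == []


def test_equal_parsimony_tie_is_surfaced_not_broken():
    calls = {"only": {"DAA": ["a", "b"], "DAB": ["p", "q"]}}
    res = phase_two_locus(calls)
    assert res.unresolved_animals == ["only"]
    assert all(h.status == "ambiguous" for h in res.haplotypes)
    assert len(res.alternative_phasings["only"]) == 2


def _simulate_cohort(rng: random.Random, n_animals: int, pool: list[tuple[str, str]]):
    truth = {}
    calls = {}
    for i in range(n_animals):
        h1, h2 = rng.choice(pool), rng.choice(pool)
        truth[f"A{i}"] = frozenset({h1, h2})
        calls[f"A{i}"] = {
            "DAA": sorted({h1[0], h2[0]}),
            "DAB": sorted({h1[1], h2[1]}),
        }
    return truth, calls


def test_simulated_pool_recovered_when_every_haplotype_is_phase_known():
    """Cohorts drawn from a fixed haplotype pool (no recombination) are
    recovered exactly whenever each pool haplotype occurs in at least one
    phase-known (not double-heterozygous) animal."""
    pool = [("a", "p"), ("b", "q"), ("c", "r"), ("d", "s"), ("a", "q")]
    rng = random.Random(99)
    tested = 0
    for _ in range(200):
        truth, calls = _simulate_cohort(rng, 14, pool)
        phase_known = set()
        for animal, loci in calls.items():
            if len(loci["DAA"]) == 1 or len(loci["DAB"]) == 1:
                phase_known.update(truth[animal])
        used = set().union(*truth.values())
        if not used <= phase_known:
            continue
        res = phase_two_locus(calls)
        assert res.unresolved_animals == []
        for animal, pairs in res.per_animal_phase.items():
            assert frozenset(pairs) == truth[animal]
        tested += 1
    assert tested >= 5


def test_exhaustive_fallback_agrees_with_iterative_resolution():
    """When Clark iteration alone fully resolves a cohort, the exhaustive
    minimum-haplotype search must choose the same phasing."""
    calls = {
        "h1": {"DAA": ["a"], "DAB": ["p"]},
        "h2": {"DAA": ["b"], "DAB": ["q"]},
        "d1": {"DAA": ["a", "b"], "DAB": ["p", "q"]},
        "d2": {"DAA": ["a", "c"], "DAB": ["p", "r"]},
    }
    res = phase_two_locus(calls)
    assert res.unresolved_animals == []
    iterative = {a: sorted(p) for a, p in res.per_animal_phase.items()}

    # brute force over all phasings of the two double heterozygotes
    def pairs_of(animal, bit):
        daa = sorted(set(calls[animal]["DAA"]))
        dab = sorted(set(calls[animal]["DAB"]))
        return [(daa[0], dab[bit]), (daa[1], dab[1 - bit])]

    base = {("a", "p"), ("b", "q")}
    best = None
    for b1, b2 in itertools.product((0, 1), repeat=2):
        pool = base | set(pairs_of("d1", b1)) | set(pairs_of("d2", b2))
        if best is None or len(pool) < best[0]:
            best = (len(pool), b1, b2)
    assert iterative["d1"] == sorted(pairs_of("d1", best[1]))
    assert iterative["d2"] == sorted(pairs_of("d2", best[2]))


def test_every_haplotype_consistent_with_supporters(genotype_table):
    calls = {}
    for _, r in genotype_table.iterrows():
        if r["gene"] not in ("DAA", "DAB"):
            continue
        alleles = [r["allele_1"]] + ([r["allele_2"]] if isinstance(r["allele_2"], str) else [])
        calls.setdefault(r["animal"], {})[r["gene"]] = alleles
    res = phase_two_locus(calls)
    for h in res.haplotypes:
        for animal in h.supporting_animals:
            assert h.daa_allele in calls[animal]["DAA"]
            assert h.dab_allele in calls[animal]["DAB"]


def test_compare_haplotype_sets():
    inferred = [("DAA*02:01", "DAB*02:01"), ("DAA*09:01", "DAB*07:01")]
    shared, novel = compare_haplotype_sets(inferred, [("DAA*02:01", "DAB*02:01")])
    assert shared == [("DAA*02:01", "DAB*02:01")]
    assert novel == [("DAA*09:01", "DAB*07:01")]
    shared2, novel2 = compare_haplotype_sets(inferred, [])
    assert shared2 == [] and len(novel2) == 2
    shared3, novel3 = compare_haplotype_sets(inferred, inferred)
    assert novel3 == []
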