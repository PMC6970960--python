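"""Parsimony phasing of the two linked class II loci (DAA and DAB).

The salmon DAA and DAB genes sit ~3 kb apart on chromosome 12, so their
alleles segregate as haplotypes.  Phasing follows Clark's rule: animals
homozygous at one or both loci contribute unambiguous haplotypes; a double
heterozygote is resolved when exactly one of its two possible phasings
re-uses at least one already-known haplotype; whatever remains at the
fixpoint is resolved by exhaustive search minimising the number of
distinct haplotypes, with equal-parsimony ties surfaced as ambiguous
rather than silently broken.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = ["Haplotype", "PhasingResult", "phase_two_locus", "compare_haplotype_sets"]

Pair = tuple[str, str]  # (daa allele label, dab allele label)


@dataclass
class Haplotype:
    daa_allele: str
    dab_allele: str
    supporting_animals: list[str]
    status: str = "resolved"  # resolved | ambiguous
    annotations: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.supporting_animals)

    @property
    def pair(self) -> Pair:
        return (self.daa_allele, self.dab_allele)


@dataclass
class PhasingResult:
    haplotypes: list[Haplotype]
    per_animal_phase: dict[str, list[Pair]]
    unresolved_animals: list[str]
    alternative_phasings: dict[str, list[list[Pair]]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _normalise(alleles: Sequence[str]) -> list[str]:
    uniq = sorted(set(alleles))
    if not 1 <= len(uniq) <= 2:
        raise ValueError(f"expected 1-2 alleles per locus, got {uniq}")
    return uniq


def phase_two_locus(genotype_calls: Mapping[str, Mapping[str, Sequence[str]]]) -> PhasingResult:
    """Phase DAA-DAB genotypes across a cohort.

    ``genotype_calls`` maps animal -> {"DAA": [alleles], "DAB": [alleles]}
    with one or two allele labels per locus.
    """
    phases: dict[str, list[Pair]] = {}
    warnings: list[str] = []
    pending: list[str] = []

    for animal in sorted(genotype_calls):
        loci = genotype_calls[animal]
        daa = _normalise(loci["DAA"])
        dab = _normalise(loci["DAB"])
        if len(daa) == 1 and len(dab) == 1:
            phases[animal] = [(daa[0], dab[0]), (daa[0], dab[0])]
        elif len(daa) == 1:
            phases[animal] = [(daa[0], dab[0]), (daa[0], dab[1])]
            warnings.append(
                f"{animal}: one DAA but two DAB alleles; phased {daa[0]} with both "
                "DABs (homozygous DAA, or one DAA segregating on two haplotypes)"
            )
        elif len(dab) == 1:
            phases[animal] = [(daa[0], dab[0]), (daa[1], dab[0])]
        else:
            pending.append(animal)

    known: set[Pair] = {p for pairs in phases.values() for p in pairs}

    # Clark iteration: resolve a double heterozygote when exactly one phasing
    # re-uses known haplotypes.
    progress = True
    while progress and pending:
        progress = False
        for animal in list(pending):
            daa = _normalise(genotype_calls[animal]["DAA"])
            dab = _normalise(genotype_calls[animal]["DAB"])
            opt_a = [(daa[0], dab[0]), (daa[1], dab[1])]
            opt_b = [(daa[0], dab[1]), (daa[1], dab[0])]
            k_a = sum(p in known for p in opt_a)
            k_b = sum(p in known for p in opt_b)
            chosen = None
            if k_a >= 1 and k_b == 0:
                chosen = opt_a
            elif k_b >= 1 and k_a == 0:
                chosen = opt_b
            if chosen is not None:
                phases[animal] = chosen
                known.update(chosen)
                pending.remove(animal)
                progress = True

    unresolved: list[str] = []
    alternatives: dict[str, list[list[Pair]]] = {}
    if pending:
        _exhaustive_phase(genotype_calls, pending, phases, known, unresolved, alternatives)

    haplotypes = _collect(phases, unresolved, alternatives)
    _annotate_crossovers(haplotypes)
    return PhasingResult(haplotypes, phases, unresolved, alternatives, warnings)


def _exhaustive_phase(calls, pending, phases, known, unresolved, alternatives) -> None:
    """Minimise the number of distinct haplotypes over all 2^m assignments."""
    if len(pending) > 25:
        raise ValueError(f"{len(pending)} unresolved double heterozygotes: search infeasible")
    options = []
    for animal in pending:
        daa = _normalise(calls[animal]["DAA"])
        dab = _normalise(calls[animal]["DAB"])
        options.append(
            (
                animal,
                [(daa[0], dab[0]), (daa[1], dab[1])],
                [(daa[0], dab[1]), (daa[1], dab[0])],
            )
        )
    best_cost = None
    best_assignments: list[tuple[int, ...]] = []
    for bits in itertools.product((0, 1), repeat=len(options)):
        pool = set(known)
        for (animal, a, b), bit in zip(options, bits):
            pool.update(a if bit == 0 else b)
        cost = len(pool)
        if best_cost is None or cost < best_cost:
            best_cost, best_assignments = cost, [bits]
        elif cost == best_cost:
            best_assignments.append(bits)
    for idx, (animal, a, b) in enumerate(options):
        picks = {bits[idx] for bits in best_assignments}
        if len(picks) == 1:
            chosen = a if picks.pop() == 0 else b
            phases[animal] = chosen
            known.update(chosen)
        else:
            unresolved.append(animal)
            alternatives[animal] = [a, b]


def _collect(phases, unresolved, alternatives) -> list[Haplotype]:
    support: dict[Pair, set[str]] = {}
    status: dict[Pair, str] = {}
    for animal, pairs in phases.items():
        for p in set(pairs):
            support.setdefault(p, set()).add(animal)
            status.setdefault(p, "resolved")
    for animal, opts in alternatives.items():
        for pairs in opts:
            for p in set(pairs):
                support.setdefault(p, set()).add(animal)
                status[p] = "ambiguous"
    return [
        Haplotype(p[0], p[1], sorted(animals), status[p])
        for p, animals in sorted(support.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]


def _annotate_crossovers(haplotypes: list[Haplotype]) -> None:
    """Flag haplotypes that look like single-crossover products of two others."""
    pairs = [h.pair for h in haplotypes]
    for h in haplotypes:
        shares_daa = any(p != h.pair and p[0] == h.daa_allele for p in pairs)
        shares_dab = any(p != h.pair and p[1] == h.dab_allele for p in pairs)
        if shares_daa and shares_dab:
            h.annotations.append(
                "possible crossover product (DAA and DAB each shared with another haplotype)"
            )


def compare_haplotype_sets(
    inferred: Iterable, reference_list: Iterable
) -> tuple[list[Pair], list[Pair]]:
    """Split inferred haplotypes into (shared with reference, novel)."""

    def as_pair(h) -> Pair:
        return h.pair if hasattr(h, "pair") else (str(h[0]), str(h[1]))

    inferred_pairs = [as_pair(h) for h in inferred]
    ref = {as_pair(h) for h in reference_list}
    shared = sorted(p for p in set(inferred_pairs) if p in ref)
    novel = sorted(p for p in set(inferred_pairs) if p not in ref)
    return shared, novel
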