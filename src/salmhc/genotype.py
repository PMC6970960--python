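"""Jumping-PCR chimera detection and per-animal genotype calling.

Jumping PCR produces artefact sequences in which a partially extended
strand re-anneals to the other allele, so every position where the two
parental alleles differ carries one parent's base — but in a combination
distinct from either parent.  The check runs on nucleotide sequences
(strictly more informative than the amino-acid pattern it implies) and by
default tolerates zero novel bases at invariant positions: a single novel
substitution rescues a candidate from chimera status.

Genotypes assume one classical locus per gene, hence at most two alleles
per animal: the two top-ranked variants are provisional parents, every
lower-ranked candidate is chimera-checked against them, and whatever
survives below the abundance floor is dropped as sub-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "ChimeraVerdict",
    "CandidateCall",
    "GenotypeCall",
    "variable_sites",
    "chimera_check",
    "call_genotype",
]

DEFAULT_ALLOWED_NOVEL = 0
DEFAULT_MIN_FRACTION = 0.01


@dataclass(frozen=True)
class ChimeraVerdict:
    is_chimera: bool
    parent_pattern: tuple[int, ...]  # per variable site: 1 or 2
    n_variable_sites: int
    n_novel_positions: int
    warnings: tuple[str, ...] = ()


def variable_sites(p1: str, p2: str) -> list[int]:
    """Positions where two pairwise-aligned parents differ (gap = a state)."""
    if len(p1) != len(p2):
        raise ValueError("parents must be pairwise-aligned to equal length")
    return [i for i, (a, b) in enumerate(zip(p1, p2)) if a != b]


def chimera_check(
    candidate: str, p1: str, p2: str, allowed_novel: int = DEFAULT_ALLOWED_NOVEL
) -> ChimeraVerdict:
    """Is ``candidate`` a site-combination recombinant of ``p1`` and ``p2``?

    True iff the candidate differs from both parents, matches one of the two
    parental bases at *every* variable site using both parents at least
    once, and carries at most ``allowed_novel`` mismatches against the
    parental consensus at invariant positions.
    """
    if p1 == p2:
        return ChimeraVerdict(False, (), 0, 0, ("parents are identical: no variable sites",))
    if len(candidate) != len(p1) or len(p1) != len(p2):
        # substitution-pattern test needs one shared coordinate frame
        return ChimeraVerdict(
            False, (), 0, 0, ("length mismatch: indel-bearing candidate not testable",)
        )
    sites = variable_sites(p1, p2)
    if candidate == p1 or candidate == p2:
        return ChimeraVerdict(False, (), len(sites), 0)
    pattern: list[int] = []
    for i in sites:
        c = candidate[i]
        if c == p1[i]:
            pattern.append(1)
        elif c == p2[i]:
            pattern.append(2)
        else:
            return ChimeraVerdict(False, (), len(sites), 0)
    novel = sum(
        1
        for i, (a, b) in enumerate(zip(p1, p2))
        if a == b and candidate[i] != a
    )
    is_chimera = 1 in pattern and 2 in pattern and novel <= allowed_novel
    return ChimeraVerdict(is_chimera, tuple(pattern), len(sites), novel)


@dataclass
class CandidateCall:
    """One collapsed candidate with its abundance and classification label."""

    candidate_id: str
    residues: str
    count: int
    fraction: float
    label: str  # allele name, ambiguity set, or novel-sequence label
    report: object | None = None


@dataclass
class GenotypeCall:
    animal: str
    gene: str
    alleles: list[CandidateCall]
    zygosity: str | None  # homozygous | heterozygous | None for no-call
    excluded_chimeras: list[tuple[CandidateCall, ChimeraVerdict]] = field(default_factory=list)
    excluded_subthreshold: list[CandidateCall] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    no_call_reason: str | None = None

    @property
    def allele_labels(self) -> list[str]:
        return [c.label for c in self.alleles]


def call_genotype(
    candidates: Sequence[CandidateCall],
    animal: str = "",
    gene: str = "",
    min_fraction: float = DEFAULT_MIN_FRACTION,
    allowed_novel: int = DEFAULT_ALLOWED_NOVEL,
) -> GenotypeCall:
    """Call a per-animal, per-gene genotype from abundance-ranked candidates."""
    ranked = sorted(candidates, key=lambda c: (-c.count, c.residues))
    if not ranked:
        return GenotypeCall(animal, gene, [], None, no_call_reason="no candidates")
    call = GenotypeCall(animal, gene, [], None)
    survivors: list[CandidateCall] = [ranked[0]]
    if len(ranked) > 1:
        p1, p2 = ranked[0].residues, ranked[1].residues
        if ranked[1].fraction >= min_fraction:
            survivors.append(ranked[1])
        else:
            call.excluded_subthreshold.append(ranked[1])
        for cand in ranked[2:]:
            verdict = chimera_check(cand.residues, p1, p2, allowed_novel)
            if verdict.is_chimera:
                call.excluded_chimeras.append((cand, verdict))
            elif cand.fraction < min_fraction:
                call.excluded_subthreshold.append(cand)
            else:
                survivors.append(cand)
    if len(survivors) == 1:
        call.alleles = survivors
        call.zygosity = "homozygous"
    elif len(survivors) == 2:
        call.alleles = survivors
        call.zygosity = "heterozygous"
    else:
        call.alleles = survivors[:2]
        call.zygosity = "heterozygous"
        extra = ", ".join(c.candidate_id for c in survivors[2:])
        call.warnings.append(
            f"{len(survivors)} non-chimeric candidates above threshold ({extra} kept "
            "out of the call): possible extra locus or gene duplication"
        )
    return call
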