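"""Fish-MHC allele nomenclature: parsing, conversion and name proposals.

Names follow the colon-delimited convention used for human HLA alleles,
adapted to fish: ``Sasa-UBA*01:01:01:01`` is species prefix, locus, then
allele group, protein, synonymous and non-coding fields.  The legacy
concatenated style (``Sasa-DAA*0101``, ``Sasa-DAA*010102``) is accepted and
converted: the first two digits are the group, the next two the protein and
a trailing two-to-three digit block the synonymous field.

A new allele *group* requires at least 4 amino-acid differences from every
existing allele for class I loci and 3 for class II; a smaller
non-synonymous difference yields a new *protein* within the closest
allele's group; a nucleotide-only difference yields a new *synonymous*
number.  All distances are evaluated over the amplified region only, so
every proposal carries a verification flag: official naming requires new
PCR and Sanger sequencing of a longer stretch of the coding sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "AlleleName",
    "NameProposal",
    "AlleleNameError",
    "CLASS_THRESHOLD",
    "parse_allele_name",
    "aa_difference",
    "propose_name",
]

#: minimum amino-acid differences (to *every* library allele) for a new group
CLASS_THRESHOLD = {"I": 4, "II": 3}

_LOCUS_CLASS = {"UBA": "I", "DAA": "II", "DAB": "II"}

_NAME_RE = re.compile(
    r"^(?:MHC-)?(?P<sp>[A-Z][a-z]{3})-(?P<locus>[A-Z]{2,4}[0-9]?)\*(?P<fields>[0-9:]+)$"
)


class AlleleNameError(ValueError):
    """Text does not parse as an IPD-MHC-style allele name."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """Structured allele name; later fields require all earlier ones."""

    species_prefix: str
    locus: str
    group: int
    protein: int | None = None
    synonymous: int | None = None
    noncoding: int | None = None

    def __post_init__(self) -> None:
        fields = (self.protein, self.synonymous, self.noncoding)
        seen_none = False
        for f in fields:
            if f is None:
                seen_none = True
            elif seen_none:
                raise AlleleNameError(f"{self}: field present after a missing field")

    def __str__(self) -> str:
        parts = [f"{self.group:02d}"]
        for f in (self.protein, self.synonymous, self.noncoding):
            if f is None:
                break
            parts.append(f"{f:02d}")
        return f"{self.species_prefix}-{self.locus}*" + ":".join(parts)

    @property
    def mhc_class(self) -> str | None:
        return _LOCUS_CLASS.get(self.locus)

    def short(self) -> str:
        """Locus-local form, e.g. ``UBA*07:01`` (how Table-style reports print it)."""
        return str(self).split("-", 1)[1]


def parse_allele_name(text: str, default_species: str = "Sasa") -> AlleleName:
    """Parse old concatenated or new colon-delimited allele names.

    Bare locus-local names (``UBA*07:01``) are accepted and given
    ``default_species``.
    """
    text = text.strip()
    if "-" not in text.split("*")[0]:
        text = f"{default_species}-{text}"
    m = _NAME_RE.match(text)
    if not m:
        raise AlleleNameError(f"cannot parse allele name {text!r}")
    sp, locus, fields = m.group("sp"), m.group("locus"), m.group("fields")
    if ":" in fields:
        parts = fields.split(":")
        if not 1 <= len(parts) <= 4:
            raise AlleleNameError(f"{text!r}: expected 1-4 colon fields")
        widths_ok = all(
            (len(p) == 2) or (i == 2 and len(p) == 3) for i, p in enumerate(parts)
        )
        if not widths_ok or any(not p.isdigit() for p in parts):
            raise AlleleNameError(f"{text!r}: malformed name fields")
        nums = [int(p) for p in parts] + [None] * (4 - len(parts))
    else:
        # legacy concatenated digits: 2 | 4 | 6 | 7 digits
        if len(fields) == 2:
            nums = [int(fields), None, None, None]
        elif len(fields) == 4:
            nums = [int(fields[:2]), int(fields[2:]), None, None]
        elif len(fields) in (6, 7):
            nums = [int(fields[:2]), int(fields[2:4]), int(fields[4:]), None]
        else:
            raise AlleleNameError(
                f"{text!r}: legacy style needs 2, 4, 6 or 7 digits, got {len(fields)}"
            )
    return AlleleName(sp, locus, nums[0], nums[1], nums[2], nums[3])


def aa_difference(aa1: str, aa2: str) -> int:
    """Differences between two *pre-aligned* amino-acid strings.

    A gap opposite a residue counts as one difference; a zero-length overlap
    is undefined.
    """
    if len(aa1) != len(aa2):
        raise ValueError("aa_difference requires pre-aligned, equal-length strings")
    if not aa1:
        raise ValueError("zero-length overlap: amino-acid comparison undefined")
    return sum(1 for a, b in zip(aa1, aa2) if a != b)


@dataclass
class NameProposal:
    """Outcome of comparing a candidate against the official allele library."""

    status: str  # known | new_synonymous | new_protein | new_group | ambiguous_within_amplicon
    base_allele: AlleleName | None
    proposed: AlleleName | None
    aa_diff_to_closest: int
    nt_identical: bool
    co_closest: list[AlleleName] = field(default_factory=list)
    requires_verification: bool = True  # amplicon-region evidence only
    notes: list[str] = field(default_factory=list)


def _default_global_aligner(a: str, b: str) -> tuple[str, str]:
    from .classify import global_align  # alignment machinery lives with classify

    return global_align(a, b, alphabet="aa")


def propose_name(
    candidate_aa: str,
    candidate_nt: str,
    locus: str,
    library: Sequence,
    aligner: Callable[[str, str], tuple[str, str]] | None = None,
) -> NameProposal:
    """Classify a candidate against the library and propose a name.

    ``library`` entries need ``name`` (AlleleName), ``nt_seq`` and ``aa_seq``
    attributes, with sequences already restricted to the amplified region so
    the comparison is like-for-like (the classifier slices them).
    """
    entries = [e for e in library if e.name.locus == locus]
    if not entries:
        raise ValueError(f"empty reference library for locus {locus}")
    mhc_class = _LOCUS_CLASS.get(locus)
    if mhc_class is None:
        raise ValueError(f"unknown locus {locus!r}")
    threshold = CLASS_THRESHOLD[mhc_class]
    align = aligner or _default_global_aligner

    scored = []
    for e in entries:
        a1, a2 = align(candidate_aa, e.aa_seq)
        d = aa_difference(a1, a2)
        nt_same = candidate_nt == e.nt_seq
        nt_diff = _nt_mismatch_estimate(candidate_nt, e.nt_seq)
        scored.append((d, nt_diff, str(e.name), e, nt_same))
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    best_d = scored[0][0]
    co_closest = [t[3].name for t in scored if t[0] == best_d]
    closest = scored[0][3]
    notes = [f"distances computed over the amplified region of locus {locus} only"]

    nt_identical_entries = [t[3] for t in scored if t[4]]
    if best_d == 0 and nt_identical_entries:
        if len(nt_identical_entries) == 1:
            return NameProposal(
                "known", nt_identical_entries[0].name, nt_identical_entries[0].name,
                0, True, co_closest, requires_verification=False, notes=notes,
            )
        names = sorted((e.name for e in nt_identical_entries), key=str)
        notes.append(
            "amplified region cannot discriminate "
            + " / ".join(str(n) for n in names)
        )
        return NameProposal(
            "ambiguous_within_amplicon", None, None, 0, True, list(names), notes=notes
        )
    sp = closest.name.species_prefix
    if best_d == 0:
        syn = _next_synonymous(entries, closest.name)
        proposed = AlleleName(sp, locus, closest.name.group, closest.name.protein or 1, syn)
        return NameProposal("new_synonymous", closest.name, proposed, 0, False, co_closest, notes=notes)
    if best_d < threshold:
        group = closest.name.group
        protein = max((e.name.protein or 1) for e in entries if e.name.group == group) + 1
        proposed = AlleleName(sp, locus, group, protein)
        return NameProposal("new_protein", closest.name, proposed, best_d, False, co_closest, notes=notes)
    # a new group requires clearing the threshold against *all* library alleles
    if all(t[0] >= threshold for t in scored):
        group = max(e.name.group for e in entries) + 1
        proposed = AlleleName(sp, locus, group, 1)
        return NameProposal("new_group", closest.name, proposed, best_d, False, co_closest, notes=notes)
    # unreachable when best_d >= threshold implies all >= best_d; kept for clarity
    proposed = AlleleName(sp, locus, closest.name.group,
                          max((e.name.protein or 1) for e in entries if e.name.group == closest.name.group) + 1)
    return NameProposal("new_protein", closest.name, proposed, best_d, False, co_closest, notes=notes)


def _next_synonymous(entries: Sequence, base: AlleleName) -> int:
    existing = [
        (e.name.synonymous or 1)
        for e in entries
        if e.name.group == base.group and (e.name.protein or 1) == (base.protein or 1)
    ]
    return (max(existing) if existing else 1) + 1


def _nt_mismatch_estimate(a: str, b: str) -> int:
    """Cheap tie-break key: Hamming distance when lengths agree, else length gap."""
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)
    return abs(len(a) - len(b)) + min(len(a), len(b))
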