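"""Candidate classification: frame adjustment, alignment, closest allele.

Candidates (collapsed merged amplicons, primers already stripped) are
frame-trimmed by 0-2 nt at either end to minimise internal stop codons,
translated, and compared with the official allele library restricted to
the same amplified region.  The primary closest-allele criterion is best
pairwise nucleotide identity under local alignment; a neighbour-joining
guide tree over the same pairwise distances provides the tree-sibling
cross-check, and any discordance between the two is flagged.

Alignment scoring follows the EMBOSS water defaults the original analysis
used: nucleotide match +5 / mismatch -4, BLOSUM62 for protein, gap open 10
and extend 0.5.  Identity is identical aligned positions over alignment
length; similarity additionally counts positive-scoring substitutions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align.substitution_matrices import Array as _SubstArray
from Bio.Align import substitution_matrices

from .nomenclature import NameProposal, propose_name
from .seq_io import ReferenceAllele, reverse_complement, translate

__all__ = [
    "FrameAdjust",
    "AlignmentResult",
    "ClosestHit",
    "RegionAllele",
    "ClassificationReport",
    "adjust_frame",
    "align_pair",
    "global_align",
    "amplified_region",
    "slice_library",
    "find_closest",
    "classify_candidate",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _nt_matrix() -> _SubstArray:
    alpha = "ACGTN"
    m = _SubstArray(alpha, dims=2)
    for x in alpha:
        for y in alpha:
            m[x, y] = 0.0 if "N" in (x, y) else (5.0 if x == y else -4.0)
    return m


_NT_MATRIX = _nt_matrix()

GAP_OPEN = -10.0
GAP_EXTEND = -0.5


def _make_aligner(alphabet: str, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _NT_MATRIX if alphabet == "nt" else _BLOSUM62
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    if mode == "global":  # free end gaps: align over the shared region only
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    return al


_ALIGNERS = {
    ("nt", "local"): _make_aligner("nt", "local"),
    ("aa", "local"): _make_aligner("aa", "local"),
    ("nt", "global"): _make_aligner("nt", "global"),
    ("aa", "global"): _make_aligner("aa", "global"),
}


@dataclass(frozen=True)
class FrameAdjust:
    left: int
    right: int
    aa: str
    n_stops: int

    @property
    def clean(self) -> bool:
        return self.n_stops == 0


def adjust_frame(nt: str, reference_frame_hint: int | None = None) -> FrameAdjust:
    """Trim 0-2 nt from either end so the translation minimises internal stops.

    All nine (left, right) trims with a codon-multiple remainder are
    enumerated; ties break to the smallest left then right trim.  A hint
    (expected left trim) only reorders ties.  When every frame contains a
    stop the best one is still returned with ``clean == False`` — the
    candidate is reported but is likely an artefact.
    """
    if len(nt) < 30:
        raise ValueError(f"sequence of {len(nt)} nt is too short for frame adjustment")
    best: tuple[int, int, int, str] | None = None  # stops, l, r, aa
    for l, r in itertools.product(range(3), repeat=2):
        if (len(nt) - l - r) % 3 != 0:
            continue
        sub = nt[l : len(nt) - r] if r else nt[l:]
        aa = translate(sub, 0)
        stops = aa.count("*")
        hint_penalty = 0 if reference_frame_hint is None or l == reference_frame_hint else 1
        cand = (stops, hint_penalty, l, r, aa)
        if best is None or cand[:4] < best[:4]:
            best = cand
    assert best is not None
    stops, _, l, r, aa = best
    return FrameAdjust(l, r, aa, stops)


@dataclass(frozen=True)
class AlignmentResult:
    identity: float  # percent over alignment length
    similarity: float
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)


def _column_stats(a: str, b: str, matrix) -> tuple[int, int]:
    ident = simil = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            simil += 1
        elif matrix[x, y] > 0:
            simil += 1
    return ident, simil


def align_pair(a: str, b: str, alphabet: str = "nt") -> AlignmentResult:
    """Local (Smith-Waterman) alignment with percent identity/similarity.

    A zero-length best local alignment (disjoint sequences) is reported as
    identity 0 / similarity 0.
    """
    if not a or not b:
        raise ValueError("align_pair requires nonempty sequences")
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    aligner = _ALIGNERS[(alphabet, "local")]
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, "", "", 0.0)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    matrix = aligner.substitution_matrix
    ident, simil = _column_stats(aligned_a, aligned_b, matrix)
    length = len(aligned_a)
    return AlignmentResult(
        100.0 * ident / length, 100.0 * simil / length, aligned_a, aligned_b, best.score
    )


def global_align(a: str, b: str, alphabet: str = "aa") -> tuple[str, str]:
    """Global alignment with free end gaps; returns the aligned strings with
    terminal-overhang columns removed (comparison over the shared region)."""
    aligner = _ALIGNERS[(alphabet, "global")]
    best = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    start, stop = 0, len(aligned_a)
    while start < stop and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    while stop > start and (aligned_a[stop - 1] == "-" or aligned_b[stop - 1] == "-"):
        stop -= 1
    return aligned_a[start:stop], aligned_b[start:stop]


class RegionError(ValueError):
    """A primer site cannot be located in a reference sequence."""


def amplified_region(ref_nt: str, fwd_primer: str, rev_primer: str) -> tuple[int, int]:
    """Locate the amplified insert (exclusive of both primers) in a reference.

    Exact primer-site match is tried first, then a local-alignment fallback
    requiring >= 80% identity over the primer.
    """
    rev_site = reverse_complement(rev_primer)
    start = ref_nt.find(fwd_primer)
    if start >= 0:
        ins_start = start + len(fwd_primer)
    else:
        ins_start = _locate(ref_nt, fwd_primer)[1]
    end = ref_nt.find(rev_site, ins_start)
    if end >= 0:
        ins_end = end
    else:
        ins_end = _locate(ref_nt, rev_site)[0]
    if ins_end <= ins_start:
        raise RegionError("reverse primer site precedes the forward site")
    return ins_start, ins_end


def _locate(ref_nt: str, site: str) -> tuple[int, int]:
    res = align_pair(ref_nt, site, "nt")
    if not res.aligned_a or res.identity < 80.0:
        raise RegionError(f"primer site {site!r} not found in reference")
    aligner = _ALIGNERS[("nt", "local")]
    blocks = aligner.align(ref_nt, site)[0].aligned[0]
    return int(blocks[0][0]), int(blocks[-1][1])


@dataclass(frozen=True)
class RegionAllele:
    """A library allele restricted to one primer pair's amplified region."""

    name: object
    nt_seq: str
    aa_seq: str


_REGION_CACHE: dict[tuple, RegionAllele | None] = {}


def slice_library(
    library: list[ReferenceAllele], fwd_primer: str, rev_primer: str, locus: str
) -> list[RegionAllele]:
    """Restrict every library allele of ``locus`` to the amplified region."""
    out = []
    for ref in library:
        if ref.locus != locus:
            continue
        key = (str(ref.name), len(ref.nt_seq), fwd_primer, rev_primer)
        if key not in _REGION_CACHE:
            try:
                i, j = amplified_region(ref.nt_seq, fwd_primer, rev_primer)
            except RegionError:
                _REGION_CACHE[key] = None
            else:
                region = ref.nt_seq[i:j]
                _REGION_CACHE[key] = RegionAllele(ref.name, region, adjust_frame(region).aa)
        sliced = _REGION_CACHE[key]
        if sliced is not None:
            out.append(sliced)
    return out


@dataclass(frozen=True)
class ClosestHit:
    name: object
    nt_identity: float
    nt_similarity: float
    aa_identity: float
    aa_similarity: float


_REF_DIST_CACHE: dict[tuple, dict[tuple[str, str], float]] = {}


def find_closest(
    candidate_nt: str, library_for_locus: list[RegionAllele], candidate_aa: str | None = None
) -> tuple[list[ClosestHit], object, bool]:
    """Best-identity closest allele plus the NJ guide-tree sibling.

    Returns (hits sorted by nt identity desc, sibling name, discordant flag);
    ``discordant`` is set when the tree sibling is not among the co-best
    identity hits.
    """
    if len(library_for_locus) < 2:
        raise ValueError("closest-allele search needs a library of >= 2 alleles")
    if candidate_aa is None:
        candidate_aa = adjust_frame(candidate_nt).aa
    hits = []
    cand_dist: dict[str, float] = {}
    for entry in library_for_locus:
        nt = align_pair(candidate_nt, entry.nt_seq, "nt")
        aa = align_pair(candidate_aa, entry.aa_seq, "aa")
        hits.append(ClosestHit(entry.name, nt.identity, nt.similarity, aa.identity, aa.similarity))
        cand_dist[str(entry.name)] = 1.0 - nt.identity / 100.0
    hits.sort(key=lambda h: (-h.nt_identity, str(h.name)))
    best_identity = hits[0].nt_identity
    co_best = {str(h.name) for h in hits if h.nt_identity == best_identity}

    sibling = _nj_sibling(candidate_nt, library_for_locus, cand_dist)
    discordant = str(sibling) not in co_best
    return hits, sibling, discordant


def _nj_sibling(
    candidate_nt: str, library: list[RegionAllele], cand_dist: dict[str, float]
) -> object:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    names = sorted(str(e.name) for e in library)
    by_name = {str(e.name): e for e in library}
    key = (tuple(names), tuple(len(e.nt_seq) for e in library))
    if key not in _REF_DIST_CACHE:
        dists: dict[tuple[str, str], float] = {}
        for a, b in itertools.combinations(names, 2):
            res = align_pair(by_name[a].nt_seq, by_name[b].nt_seq, "nt")
            dists[(a, b)] = 1.0 - res.identity / 100.0
        _REF_DIST_CACHE[key] = dists
    dists = _REF_DIST_CACHE[key]

    ids = ["__candidate__"] + names
    matrix = [[0.0] * len(ids) for _ in ids]
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i >= j:
                continue
            if a == "__candidate__":
                d = cand_dist[b]
            else:
                d = dists[(a, b)] if (a, b) in dists else dists[(b, a)]
            matrix[i][j] = matrix[j][i] = d
    tree = nj(DistanceMatrix(matrix, ids))
    tip = tree.find("__candidate__")
    # nearest other tip by patristic distance = the sister leaf
    others = [t for t in tree.tips() if t.name != "__candidate__"]
    sibling_name = min(others, key=lambda t: (tip.distance(t), t.name)).name
    return by_name[sibling_name].name


@dataclass
class ClassificationReport:
    candidate_id: str
    frame_trim: tuple[int, int]
    aa_seq: str
    clean_frame: bool
    closest: list[ClosestHit]
    nj_sibling: object
    tree_discordant: bool
    proposal: NameProposal
    warnings: list[str] = field(default_factory=list)

    @property
    def allele_label(self) -> str:
        """Stable cross-animal label for genotype/haplotype bookkeeping."""
        p = self.proposal
        if p.status == "known":
            return str(p.proposed)
        if p.status == "ambiguous_within_amplicon":
            return "/".join(str(n) for n in p.co_closest)
        return f"{p.proposed}(proposed:{p.status})" if p.proposed else self.candidate_id


def classify_candidate(
    candidate_id: str,
    candidate_nt: str,
    locus: str,
    library: list[ReferenceAllele],
    fwd_primer: str,
    rev_primer: str,
) -> ClassificationReport:
    """Full classification: frame trim -> align -> closest -> name proposal."""
    region_lib = slice_library(library, fwd_primer, rev_primer, locus)
    if len(region_lib) < 2:
        raise ValueError(f"library for locus {locus} has < 2 alleles with this primer pair")
    frame = adjust_frame(candidate_nt)
    hits, sibling, discordant = find_closest(candidate_nt, region_lib, frame.aa)
    proposal = propose_name(
        frame.aa, candidate_nt, locus, region_lib, aligner=lambda a, b: global_align(a, b, "aa")
    )
    warnings = list(proposal.notes)
    if not frame.clean:
        warnings.append("no clean reading frame: internal stops in every trim; likely artefact")
    if discordant:
        warnings.append("identity-based closest allele and NJ tree sibling disagree")
    if locus == "UBA" and proposal.status != "known":
        warnings.append(
            "official UBA submission requires the three extracellular domains and "
            "the transmembrane domain; verify by new PCR and Sanger sequencing"
        )
    return ClassificationReport(
        candidate_id=candidate_id,
        frame_trim=(frame.left, frame.right),
        aa_seq=frame.aa,
        clean_frame=frame.clean,
        closest=hits,
        nj_sibling=sibling,
        tree_discordant=discordant,
        proposal=proposal,
        warnings=warnings,
    )
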