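# Methods

## The typing problem

Atlantic salmon has one classical MHC class I locus (UBA) and one classical
class II alpha/beta pair (DAA/DAB) about 3 kb apart on chromosome 12, so a
diploid animal carries at most two alleles per gene and its class II
alleles travel as DAA–DAB haplotypes. The assay amplifies cDNA with
gene-specific first-PCR primers, sequences 300 bp overlapping read pairs,
and reduces each animal × gene cell to one or two allele sequences. The
statistical signal is abundance: true alleles dominate the collapsed-read
ranking, while PCR and sequencing artefacts trail behind it.

## Stage-by-stage model and parameters

**Quality trimming.** 3′ trim at the first sliding window (length 4) whose
mean Phred drops below `q_threshold` (default Q20); leading bases of the
failing window that are individually above threshold are kept. A read
suffix exactly matching a ≥ 8 nt prefix of a configured adapter is removed.
Pairs with a mate under `min_len` (default 100 nt) are rejected. The
defaults are deliberately mild: the pipeline's error tolerance lives in the
merge consensus and the abundance filter, not in aggressive trimming.

**Primer demultiplexing.** Anchored exact prefix match of the forward
primer on R1 and the gene's reverse primer on R2, zero mismatches, primers
stripped. Exactness is a feature, not a limitation: a primer-region
mismatch means the oligo would at best mis-prime, and the cost of one lost
read is negligible at amplicon depths. Scheme validation rejects forward
primers that are prefixes of one another, so bucket order cannot matter.

**Overlap merging.** R2 is reverse-complemented and every relative offset
of the two reads is scored by mismatch density inside the overlap
(substitution-only; N matches anything). Lowest density wins, ties go to
the longest overlap; the merge fails if the best density exceeds
`max_mismatch_density` (default 0.25) — reported as `too_divergent` when
the best placement overlaps ≥ 25 nt and `no_overlap` otherwise — or if no
placement reaches `min_overlap` (default 10). Negative offsets ("outie"
placements, amplicon shorter than the read) are scanned too and any
overhang is excluded from the merged output. Consensus: agreeing bases take
the max quality; disagreeing take the higher-quality base with quality
|q1 − q2| floored at 2.

**Collapse and candidate selection.** Exact-sequence dereplication, ranked
by count descending with lexicographic tie-break (deterministic across
runs). Candidates are the top `top_n` = 5 variants with fraction
≥ `min_fraction` = 1% of merged reads. The 1% floor sits at the low end of
observed top-variant fractions so that true alleles disadvantaged by
primer-efficiency differences (observed down to ~4 k reads beside ~19 k)
survive. The floor presumes amplicon-scale depth: at a few hundred reads
per cell a duplicated error read can cross 1% and masquerade as a
rank-2 allele (see limitations).

**Frame adjustment and alignment.** 0–2 nt are trimmed from either end, the
nine (left, right) combinations with codon-multiple remainders enumerated,
and the translation with the fewest internal stops kept (ties: smallest
left, then right trim); a candidate with stops in every frame is reported
but flagged as a likely artefact. Pairwise alignment is local
Smith–Waterman with nucleotide match +5 / mismatch −4, BLOSUM62 for
protein, gap open 10 / extend 0.5 (a gap of length L costs
open + (L−1)·extend). Identity is identical columns over alignment length;
similarity additionally counts positive-scoring substitutions. All
identity computations against the reference library are restricted to the
amplified region of the candidate's own primer pair, located in each
reference by exact match with a local-alignment fallback (≥ 80% identity
required over the primer).

**Closest allele.** Primary criterion: best pairwise nucleotide identity —
objective and order-independent. The guide-tree sibling (neighbour-joining
on 1 − identity/100 distances over candidate + library) is retained as a
cross-check because tree siblings can depend on alignment and joining
order; discordance between the two is flagged in the report, never
silently resolved.

**Nomenclature.** Names are species–locus plus colon-delimited group :
protein : synonymous : non-coding fields. New-group thresholds: ≥ 4 aa to
*every* library allele for class I, ≥ 3 for class II; below that, a
non-synonymous difference proposes the next protein number in the closest
allele's group, and a nucleotide-only difference the next synonymous
number. Amino-acid distances are evaluated over the amplified region only
— whether the official thresholds should apply to the full coding sequence
is not settled — so every proposal carries a flag that full-length
verification (new PCR + Sanger) is required before official naming, and
class I proposals additionally note the database requirement for all three
extracellular domains plus the transmembrane domain. Ties for closest
allele break by higher nucleotide identity, then lexicographically; all
co-closest names are reported. cDNA cannot observe the non-coding field,
so it is never proposed.

**Chimera exclusion.** Jumping PCR (a partially extended strand
re-annealing to the other allele) produces sequences whose variable sites
mix the two parental alleles. A rank ≥ 3 candidate is excluded as a
chimera iff it differs from both provisional parents (the two top-ranked
variants), matches a parental base at *every* variable site, uses both
parents at least once, and carries at most `allowed_novel` = 0 mismatches
at invariant positions — one genuinely novel base rescues a candidate. The
check runs on nucleotides (strictly more informative than the implied
amino-acid pattern) and requires the three sequences to share one
coordinate frame; an indel-bearing candidate is not testable by this
pattern and is left in with a warning. Only the two provisional parents
are considered as sources, matching the single re-association event the
artefact model describes; no abundance-weighted multi-parent search.

**Genotype call.** After exclusions, one surviving candidate calls a
homozygote, two a heterozygote; more than two calls the top two with a
"possible extra locus/duplication" warning. Homozygosity is a negative
finding (rank 2 chimeric or sub-threshold) — no statistical test of allele
balance is applied.

**Haplotype phasing.** Clark parsimony: (i) animals homozygous at ≥ 1 locus
yield unambiguous haplotypes (an animal with one DAA and two DAB alleles is
phased as that DAA with both DABs, with a warning — the data cannot
distinguish a homozygous alpha from one alpha shared by two haplotypes);
(ii) iterate: a double heterozygote resolves when exactly one of its two
phasings re-uses a known haplotype; (iii) at fixpoint, remaining double
heterozygotes are resolved by exhaustive search (≤ 2^m assignments,
refused above m = 25) minimising the number of distinct haplotypes.
Equal-parsimony alternatives are surfaced as ambiguous. A haplotype whose
DAA and DAB each recur in other haplotypes is annotated "possible
crossover product" — annotation only, no recombination inference.

## The synthetic data and what it does not show

`simdata` emulates the library design: amplicons carrying first-PCR primers
at the termini, 300 bp overlapping pairs, i.i.d. substitution errors,
per-cell allelic imbalance, and single-breakpoint chimeras with the
breakpoint uniform between the parents' first and last variable sites
(outside that interval the recombinant is indistinguishable from a
parent). Qualities follow a constant or linear 3′-declining model and are
independent of the injected errors. Not modelled: indel sequencing errors,
PCR-cycle amplification bias, polymerase error accumulation, index
hopping, cross-sample contamination, and primer-site polymorphism beyond
the one engineered case. Passing tests therefore demonstrate the logic of
demultiplexing, merging, ranking, chimera exclusion, classification and
phasing — not robustness to indels or contamination in real libraries.

The bundled reference library is likewise synthetic (`synthlib`),
constructed to reproduce the *relations* the logic depends on: disjoint
group-defining codon blocks putting any two groups well past the naming
thresholds, 1–2 aa protein differences within groups, a protein pair
differing only outside the amplicon (indistinguishable by the assay, as
happens for real class II alpha alleles), a 1 aa pair inside it, a
sequence exactly 2 aa from a named allele, and alternative forward-primer
sites with one engineered primer-site mutation. Absolute identities to
real IPD-MHC alleles are not reproduced, only these orderings and
threshold relations.

## Numerical and design choices

* Determinism throughout: collapse tie-breaks are lexicographic, proposal
  tie-breaks are identity-then-name, the simulator is a single seeded RNG
  stream over sorted animals and genes, phasing ties are surfaced rather
  than broken.
* Merging scans all offsets via base-wise correlation (N-containing reads
  fall back to a direct scan); identical read pairs are merged once via a
  cache keyed on sequences and qualities.
* Degenerate inputs are outcomes, not errors: empty FASTQ gives a no-call
  cell; identical chimera parents give a trivially false verdict with a
  warning; a candidate with stops in every frame stays in the report.
* The test suite checks the pipeline's own simulated cohort (nine animals
  × three genes) at 2000 read pairs per cell with 0.1%/base error and 5%
  chimeras; scoring is at amplicon resolution, i.e. the called candidate
  sequences must equal the set of true amplified-region sequences —
  alleles identical over the amplicon are inherently unresolvable and are
  reported as an ambiguity set for Sanger follow-up. Problem sizes were
  chosen so a full run completes in about a minute on one core.

## Known limitations

* Substitution-only merging and chimera testing: indel-bearing artefacts
  are neither merged correctly nor chimera-testable; they surface as
  unmerged pairs or warned candidates.
* The abundance floor is depth-relative; below ~500 merged reads per cell
  duplicated error reads can reach 1% and inflate heterozygosity.
* Classification quality is bounded by the reference snapshot: a stale
  library inflates "new allele" proposals.
* Phasing assumes no recombination within the cohort and reports, but does
  not model, possible crossover products.
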