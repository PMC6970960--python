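# salmhc — amplicon-based MHC genotyping for Atlantic salmon

`salmhc` genotypes the three classical MHC genes of Atlantic salmon
(*Salmo salar*) — the class I locus **UBA** and the tightly linked class II
loci **DAA** and **DAB** — from Illumina paired-end amplicon sequencing of
cDNA, and infers DAA–DAB haplotypes across a cohort. It is aimed at
immunogenetics groups monitoring MHC diversity in wild and farmed salmonid
populations, where per-animal allele calls and class II haplotypes are the
unit of interest.

## What the pipeline does

For each animal (one pair of index-demultiplexed FASTQ files, 300 bp reads):

1. **preprocess** — sliding-window quality trimming (Q20, window 4,
   min length 100) and adapter removal, then demultiplexing into per-gene,
   per-forward-primer buckets by *exact* anchored primer match (zero
   mismatches); primers are stripped.
2. **merge_pairs** — overlap-merging of each read pair into a full-length
   amplicon: every relative placement is scored by mismatch density, the
   lowest-density overlap wins, and disagreements are resolved toward the
   higher-quality base.
3. **collapse** — dereplication into unique variants ranked by read count;
   the top 5 variants at ≥ 1% of merged reads become allele candidates.
4. **classify** — frame-trim (0–2 nt per end, minimising internal stops),
   translate, and align each candidate against a reference allele library
   restricted to the amplified region (Smith–Waterman, nt +5/−4, BLOSUM62,
   gap 10/0.5). The closest allele by nucleotide identity is cross-checked
   against the candidate's sibling in a neighbour-joining guide tree.
5. **nomenclature** — names follow the colon-delimited convention
   (`Sasa-UBA*01:01:01:01` = group:protein:synonymous:non-coding). A
   candidate ≥ 4 aa (class I) or ≥ 3 aa (class II) from every library
   allele is proposed as a new *group*; a smaller non-synonymous distance
   as a new *protein* in the closest allele's group; a nucleotide-only
   difference as a new *synonymous* number. Candidates identical to several
   alleles over the amplicon are flagged ambiguous.
6. **genotype** — one classical locus per gene implies at most two alleles
   per animal. The two top candidates are provisional parents; every
   lower-ranked candidate whose variable-site pattern mixes the two parents
   (jumping-PCR signature: every variable position carries a parental base,
   both parents used, no novel bases) is excluded as a chimera.
7. **haplotype** — Clark-style parsimony phasing of DAA–DAB across animals:
   haplotypes from locus-homozygous animals seed an iteration that resolves
   double heterozygotes; any remainder is settled by exhaustive search
   minimising distinct haplotypes, with ties reported, never broken.

A **simdata** module generates cohorts with known genotypes, primer
structure, sequencing errors, allelic imbalance and jumping-PCR chimeras,
so the whole pipeline is testable offline. The bundled reference library is
a *synthetic* stand-in (see `salmhc.synthlib`) that reproduces the distance
relationships the logic depends on; real analyses should point `--library`
at an IPD-MHC FASTA snapshot.

## Worked example

Phase the bundled study genotype table (nine river-caught animals):

```bash
salmhc haplotype --genotypes src/salmhc/data/table_genotypes.tsv --out haplotypes.tsv
```

`haplotypes.tsv` (columns daa, dab, support, animals, status, annotations):

```
daa	dab	support	animals	status	annotations
DAA*06:01	DAB*06:01	4	AS1,AS2,AS5,AS7	resolved
DAA*01:02	DAB*08:01	2	AS3,AS8	resolved
DAA*02:01	DAB*02:01	2	AS6,AS7	resolved
DAA*03:02	DAB*20:01	2	AS2,AS9	resolved
DAA*04:01	DAB*09:01	2	AS1,AS10	resolved	possible crossover product (...)
DAA*09:01	DAB*07:01	2	AS3,AS9	resolved
DAA*04:01	DAB*09:02	1	AS8	resolved
DAA*06:01	AS5DABs2	1	AS5	resolved
DAA*09:01	DAB*09:01	1	AS6	resolved	possible crossover product (...)
```

Reading this: the cohort carries two previously known class II haplotypes
(`DAA*02:01–DAB*02:01`, `DAA*06:01–DAB*06:01`) and four novel haplotypes
each supported by two animals. `DAA*04:01–DAB*09:01` and
`DAA*09:01–DAB*09:01` are flagged as a possible crossover pair, and animal
AS5 carries one DAA allele against two DAB alleles (stderr warning): either
a homozygous DAA or one alpha allele segregating on two haplotypes.

A full read-level run on simulated data:

```bash
salmhc simulate --spec myspec.json --out-dir sim/
salmhc run --fastq-dir sim/ \
    --scheme src/salmhc/data/primer_scheme.tsv \
    --library src/salmhc/data/reference_library.synthetic.fasta \
    --out-dir out/
```

which writes `genotypes.tsv`, `haplotypes.tsv`, per-candidate
classification reports and a per-stage read-count JSON (input → retained →
assigned per bucket → merged → variants → candidates).

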