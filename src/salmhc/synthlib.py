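"""Deterministic *synthetic* reference allele library for offline work.

The bundled snapshot files (``data/reference_library.synthetic.fasta``,
``data/novel_alleles.synthetic.fasta``) are generated by this module: they
are not real IPD-MHC sequences but constructed cDNAs that reproduce the
relationships the typing logic depends on:

* every allele carries the real first-PCR primer sites at the expected
  positions (two alternative forward sites for UBA and DAB);
* allele *groups* of one locus differ at disjoint codon blocks, so any two
  groups differ by well over the naming threshold (4 aa for class I, 3 aa
  for class II), while proteins within a group differ by 1-2 aa;
* ``DAA*01:01`` and ``DAA*01:02`` differ by one codon *outside* the
  amplified region, so the amplicon cannot discriminate them;
* ``DAB*09:02`` is one amino acid from ``DAB*09:01`` inside the amplicon;
* the novel set holds the unnamed study sequences: five new-group UBA
  alleles (the two AS5 ones with a broken UBA1 forward-primer site, which
  is why that animal needs the alternative UBA4 primer), one sequence two
  amino acids from ``UBA*35:01``, and one new-group DAB allele;
* frame 0 of every sequence translates without internal stops.

Everything is a pure function of the fixed seed, so the shipped snapshot
can be regenerated and byte-compared in tests.
"""

from __future__ import annotations

import numpy as np

from .seq_io import SequenceRecord, reverse_complement, translate

__all__ = [
    "PRIMERS",
    "SNAPSHOT_SEED",
    "build_synthetic_references",
    "primer_scheme_rows",
]

SNAPSHOT_SEED = 20191112

#: first-PCR primer sequences (gene, role, label -> sequence)
PRIMERS = {
    ("UBA", "forward", "UBA1_F"): "CTGGGAATAGGCCTTCTACAT",
    ("UBA", "forward", "UBA4_F"): "GGCATCTGCAGTAACCCACT",
    ("UBA", "reverse", "UBA_R"): "TCCAGATACTTCTTCAGCCAC",
    ("DAA", "forward", "DAA_F"): "TGCTGGCAGGTGTATGCAGAA",
    ("DAA", "reverse", "DAA_R"): "GGTGAAATCAGCGTTGGGGT",
    ("DAB", "forward", "DAB1_F"): "ATGTCGATGTCTATCTTCTG",
    ("DAB", "forward", "DAB2_F"): "TTCTGCGTTTCCCTGACCC",
    ("DAB", "reverse", "DAB_R"): "GTACCAGTCCCCGTTAGCCAG",
}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# cds layouts: feature name -> (start, fixed sequence or filler length)
def _layouts() -> dict[str, list[tuple[str, object]]]:
    p = {k[2]: v for k, v in PRIMERS.items()}
    rc = reverse_complement
    return {
        "UBA": [
            ("leader", 24),
            ("UBA1_F", p["UBA1_F"]),        # at 24, phase 0
            ("spacer", 30),
            ("UBA4_F", p["UBA4_F"]),        # at 75, phase 0
            ("core", 400),
            ("UBA_R", rc(p["UBA_R"])),      # at 495, phase 0
            ("tail", 24),
        ],
        "DAA": [
            ("leader", 24),
            ("DAA_F", p["DAA_F"]),          # at 24, phase 0
            ("core", 420),
            ("DAA_R", rc(p["DAA_R"])),      # at 465, phase 0
            ("tail", 36),
        ],
        "DAB": [
            ("DAB1_F", p["DAB1_F"]),        # at 0
            ("spacer", 25),
            ("DAB2_F", p["DAB2_F"]),        # at 45, phase 0
            ("core", 401),
            ("DAB_R", rc(p["DAB_R"])),      # at 465, phase 0
            ("tail", 24),
        ],
    }


# codon blocks (cds codon indices) marking each allele group; disjoint per locus
_GROUP_CODONS = {
    "UBA": {g: list(range(40 + 6 * i, 46 + 6 * i)) for i, g in enumerate(
        ["02", "06", "07", "13", "20", "34", "35",
         "AS2UBAs1", "AS2UBAs2", "AS5UBAs1", "AS5UBAs2", "AS9UBAs2"])},
    "DAA": {g: list(range(22 + 5 * i, 27 + 5 * i)) for i, g in enumerate(
        ["01", "02", "03", "04", "06", "09"])},
    "DAB": {g: list(range(28 + 5 * i, 33 + 5 * i)) for i, g in enumerate(
        ["02", "06", "07", "08", "09", "20", "AS5DABs2"])},
}

# protein-level single/double codon edits (codon index, see module docstring)
_DAA_0102_TAIL_CODON = 163   # nt 489-491, beyond the reverse-primer site
_DAB_0902_CORE_CODON = 100   # inside the amplicon
_UBA_3502_CODONS = (120, 121)  # inside the amplicon, outside all group blocks


def _build_base(locus: str, rng: np.random.Generator) -> tuple[str, dict[str, tuple[int, int]]]:
    """Assemble one locus' base cds: fixed primer sites + random filler,
    repaired until frame 0 is free of stop codons."""
    seq: list[str] = []
    fixed = np.zeros(0, dtype=bool)
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    flags: list[bool] = []
    for name, item in _layouts()[locus]:
        if isinstance(item, int):
            frag = "".join(rng.choice(list(_BASES), size=item))
            flags.extend([False] * item)
        else:
            frag = item
            flags.extend([True] * len(item))
        spans[name] = (pos, pos + len(frag))
        seq.append(frag)
        pos += len(frag)
    s = list("".join(seq))
    fixed = np.array(flags)
    for _ in range(1000):
        stops = [
            i for i in range(0, len(s) - 2, 3) if "".join(s[i : i + 3]) in _STOPS
        ]
        if not stops:
            break
        for i in stops:
            editable = [j for j in (i, i + 1, i + 2) if not fixed[j]]
            if not editable:
                raise AssertionError(f"{locus}: stop codon inside fixed primer site")
            j = editable[int(rng.integers(len(editable)))]
            s[j] = _BASES[int(rng.integers(4))]
    else:
        raise AssertionError(f"{locus}: could not repair stop codons")
    return "".join(s), spans


def _mutate_codon(seq: str, codon_idx: int, rng: np.random.Generator) -> str:
    """Replace one codon with a codon encoding a *different* amino acid."""
    i = codon_idx * 3
    old = seq[i : i + 3]
    old_aa = translate(old)
    for _ in range(100):
        new = "".join(rng.choice(list(_BASES), size=3))
        if new in _STOPS or new == old:
            continue
        if translate(new) != old_aa:
            return seq[:i] + new + seq[i + 3 :]
    raise AssertionError("could not find a non-synonymous replacement codon")


def _apply_group(seq: str, locus: str, group: str, rng: np.random.Generator) -> str:
    for codon_idx in _GROUP_CODONS[locus][group]:
        seq = _mutate_codon(seq, codon_idx, rng)
    return seq


def build_synthetic_references(
    seed: int = SNAPSHOT_SEED,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Build (official library records, novel study-sequence records)."""
    rng = np.random.default_rng(seed)
    bases = {locus: _build_base(locus, rng) for locus in ("UBA", "DAA", "DAB")}

    official: list[SequenceRecord] = []
    novel: list[SequenceRecord] = []

    def rec(name: str, seq: str, kind: str) -> SequenceRecord:
        assert "*" not in translate(seq), f"{name}: internal stop"
        return SequenceRecord(name, seq, f"synthetic {kind} sequence")

    # ---- UBA (class I) -------------------------------------------------
    uba_base, _ = bases["UBA"]
    group_seq: dict[str, str] = {
        g: _apply_group(uba_base, "UBA", g, rng) for g in _GROUP_CODONS["UBA"]
    }
    for g in ["02", "06", "07", "13", "20", "34", "35"]:
        official.append(rec(f"Sasa-UBA*{g}:01", group_seq[g], "official-allele"))
    uba3502 = group_seq["35"]
    for c in _UBA_3502_CODONS:
        uba3502 = _mutate_codon(uba3502, c, rng)
    novel.append(rec("AS7UBAs1", uba3502, "novel (2 aa from UBA*35:01)"))
    for label in ["AS2UBAs1", "AS2UBAs2", "AS9UBAs2"]:
        novel.append(rec(label, group_seq[label], "novel new-group"))
    for label in ["AS5UBAs1", "AS5UBAs2"]:
        seq = _break_uba1_site(group_seq[label])
        novel.append(rec(label, seq, "novel new-group, UBA1 primer site mutated"))

    # ---- DAA (class II alpha) ------------------------------------------
    daa_base, _ = bases["DAA"]
    daa_group = {g: _apply_group(daa_base, "DAA", g, rng) for g in _GROUP_CODONS["DAA"]}
    official.append(rec("Sasa-DAA*01:01", daa_group["01"], "official-allele"))
    official.append(
        rec(
            "Sasa-DAA*01:02",
            _mutate_codon(daa_group["01"], _DAA_0102_TAIL_CODON, rng),
            "official-allele (differs from 01:01 outside the amplicon)",
        )
    )
    official.append(rec("Sasa-DAA*02:01", daa_group["02"], "official-allele"))
    official.append(rec("Sasa-DAA*03:02", daa_group["03"], "official-allele"))
    official.append(rec("Sasa-DAA*04:01", daa_group["04"], "official-allele"))
    official.append(rec("Sasa-DAA*06:01", daa_group["06"], "official-allele"))
    official.append(rec("Sasa-DAA*09:01", daa_group["09"], "official-allele"))

    # ---- DAB (class II beta) -------------------------------------------
    dab_base, _ = bases["DAB"]
    dab_group = {g: _apply_group(dab_base, "DAB", g, rng) for g in _GROUP_CODONS["DAB"]}
    for g in ["02", "06", "07", "08", "20"]:
        official.append(rec(f"Sasa-DAB*{g}:01", dab_group[g], "official-allele"))
    official.append(rec("Sasa-DAB*09:01", dab_group["09"], "official-allele"))
    official.append(
        rec(
            "Sasa-DAB*09:02",
            _mutate_codon(dab_group["09"], _DAB_0902_CORE_CODON, rng),
            "official-allele (1 aa from 09:01 inside the amplicon)",
        )
    )
    novel.append(rec("AS5DABs2", dab_group["AS5DABs2"], "novel new-group"))

    _check_primer_sites(official, novel)
    return official, novel


def _break_uba1_site(seq: str) -> str:
    """One substitution inside the UBA1 forward-primer site (exact-match
    demultiplexing with that primer then fails, as for the AS5 alleles)."""
    site = PRIMERS[("UBA", "forward", "UBA1_F")]
    start = seq.find(site)
    assert start >= 0
    pos = start + 10  # codon GGC -> GAC (Gly -> Asp), no stop
    assert seq[pos] == "G"
    return seq[:pos] + "A" + seq[pos + 1 :]


def _check_primer_sites(official, novel) -> None:
    for recs, allow_broken in ((official, False), (novel, True)):
        for r in recs:
            for (gene, role, label), p in PRIMERS.items():
                site = p if role == "forward" else reverse_complement(p)
                locus = _locus_of(r.id)
                if locus != gene:
                    continue
                n = r.residues.count(site)
                broken_ok = allow_broken and label == "UBA1_F" and r.id.startswith("AS5")
                assert n == 1 or broken_ok, f"{r.id}: {label} site count {n}"


def _locus_of(name: str) -> str:
    for locus in ("UBA", "DAA", "DAB"):
        if locus in name:
            return locus
    raise ValueError(name)


def primer_scheme_rows() -> list[tuple[str, str, str, str]]:
    """Rows (gene, role, label, sequence) for the bundled scheme TSV."""
    return [(g, role, lab, seq) for (g, role, lab), seq in PRIMERS.items()]
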