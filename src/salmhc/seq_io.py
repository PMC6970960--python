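"""FASTA/FASTQ IO, primer schemes and the reference allele library.

Sequence records are thin immutable containers over what Biopython parses;
all residues are uppercased on input and RNA ``U`` is mapped to ``T`` (the
assay sequences cDNA). Qualities are Phred+33 integer lists.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "ReferenceAllele",
    "PrimerScheme",
    "FormatError",
    "PairingError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_fastq_pairs",
    "reverse_complement",
    "translate",
    "load_reference_library",
    "read_primer_scheme",
]

_NT_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_MATE_SUFFIX = re.compile(r"(/[12]|\.[12])$")

LOCUS_CLASS = {"UBA": "I", "DAA": "II", "DAB": "II"}


class FormatError(ValueError):
    """A sequence file violates its format contract."""


class PairingError(ValueError):
    """R1/R2 files do not pair up."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence, optionally with per-base Phred qualities."""

    id: str
    residues: str
    description: str = ""
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise FormatError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, stop: int | None = None) -> "SequenceRecord":
        stop = len(self.residues) if stop is None else stop
        quals = None if self.qualities is None else self.qualities[start:stop]
        return SequenceRecord(self.id, self.residues[start:stop], self.description, quals)


@dataclass(frozen=True)
class ReferenceAllele:
    """A library allele: IPD-MHC-style name plus nucleotide and protein sequence."""

    name: "object"  # nomenclature.AlleleName; kept loose to avoid a hard cycle
    locus: str
    mhc_class: str
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if LOCUS_CLASS.get(self.locus) != self.mhc_class:
            raise ValueError(
                f"{self.name}: locus {self.locus} is class {LOCUS_CLASS.get(self.locus)}, "
                f"not {self.mhc_class}"
            )


@dataclass
class PrimerScheme:
    """Per-gene forward primer(s) and the single reverse primer (first-PCR scheme)."""

    forwards: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    reverses: dict[str, tuple[str, str]] = field(default_factory=dict)
    gene_locus: dict[str, str] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.forwards)

    def validate(self) -> None:
        for gene in self.forwards:
            if gene not in self.reverses:
                raise FormatError(f"gene {gene}: no reverse primer in scheme")
        all_fwd = [(lab, seq) for g in self.forwards for lab, seq in self.forwards[g]]
        for i, (lab_a, a) in enumerate(all_fwd):
            for lab_b, b in all_fwd[i + 1 :]:
                if a.startswith(b) or b.startswith(a):
                    raise FormatError(
                        f"forward primers {lab_a} and {lab_b} are prefixes of one "
                        "another; exact-prefix demultiplexing would be ambiguous"
                    )
        for lab, seq in all_fwd + list(self.reverses.values()):
            if not seq or set(seq) - set("ACGT"):
                raise FormatError(f"primer {lab}: invalid sequence {seq!r}")

    def buckets(self) -> list[tuple[str, str]]:
        """All (gene, forward-label) demultiplexing targets, in scheme order."""
        return [(g, lab) for g in self.genes() for lab, _ in self.forwards[g]]


def _clean_residues(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; header split at the first whitespace into id/description."""
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            line = _find_line(path, ">")
            raise FormatError(f"{path}:{line}: FASTA header without an identifier")
        if len(rec.seq) == 0:
            line = _find_line(path, f">{rec.description}")
            raise FormatError(f"{path}:{line}: record {rec.id!r} has an empty sequence")
        records.append(
            SequenceRecord(rec.id, _clean_residues(str(rec.seq)), _after_id(rec.description))
        )
    return records


def _after_id(description: str) -> str:
    parts = description.split(None, 1)
    return parts[1] if len(parts) == 2 else ""


def _find_line(path: Path, prefix: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.rstrip("\n") == prefix or line.startswith(prefix + " ") or (
                prefix == ">" and line.rstrip() == ">"
            ):
                return i
    return 0


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ, Phred+33. Warns when qualities look like Phred+64."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = tuple(rec.letter_annotations["phred_quality"])
        records.append(
            SequenceRecord(rec.id, _clean_residues(str(rec.seq)), _after_id(rec.description), quals)
        )
    _warn_if_phred64(records, path)
    return records


def _warn_if_phred64(records: Sequence[SequenceRecord], path: str | Path) -> None:
    quals = [q for rec in records for q in (rec.qualities or ())]
    if quals and min(quals) >= 26 and sum(quals) / len(quals) > 42:
        warnings.warn(
            f"{path}: qualities look like Phred+64 (min {min(quals)}); "
            "this reader assumes Phred+33",
            stacklevel=3,
        )


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r}: FASTQ output requires qualities")
            qline = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qline}\n")


def _strip_mate(read_id: str) -> str:
    return _MATE_SUFFIX.sub("", read_id)


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Read an R1/R2 FASTQ pair; ids must match after stripping mate suffixes."""
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise PairingError(
            f"{path_r1} has {len(r1)} records but {path_r2} has {len(r2)}"
        )
    for a, b in zip(r1, r2):
        if _strip_mate(a.id) != _strip_mate(b.id):
            raise PairingError(f"unpaired read ids {a.id!r} vs {b.id!r}")
    return list(zip(r1, r2))


def reverse_complement(nt: str) -> str:
    bad = set(nt) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide symbols {sorted(bad)} in sequence")
    return nt.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame_offset: int = 0) -> str:
    """Standard-code translation of complete codons from ``frame_offset``.

    Stops are emitted as ``*``; codons containing N translate to ``X``; a
    trailing partial codon is dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    sub = nt[frame_offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def load_reference_library(fasta_path: str | Path) -> list[ReferenceAllele]:
    """Load a local FASTA snapshot of official alleles.

    Headers must parse as IPD-MHC-style names (old concatenated or new
    colon-delimited style); the protein sequence is derived with the same
    frame-adjustment rule the classifier applies to candidates.
    """
    from .classify import adjust_frame  # local import: classify depends on seq_io
    from .nomenclature import AlleleNameError, parse_allele_name

    alleles: list[ReferenceAllele] = []
    seen: set[str] = set()
    for rec in read_fasta(fasta_path):
        try:
            name = parse_allele_name(rec.id)
        except AlleleNameError as exc:
            raise FormatError(f"{fasta_path}: unparseable allele header {rec.id!r}: {exc}")
        key = str(name)
        if key in seen:
            raise FormatError(f"{fasta_path}: duplicate allele name {key}")
        seen.add(key)
        frame = adjust_frame(rec.residues)
        alleles.append(
            ReferenceAllele(
                name=name,
                locus=name.locus,
                mhc_class=LOCUS_CLASS[name.locus],
                nt_seq=rec.residues,
                aa_seq=frame.aa,
            )
        )
    return alleles


def read_primer_scheme(tsv_path: str | Path) -> PrimerScheme:
    """Read a primer scheme TSV with columns gene, role, label, sequence."""
    scheme = PrimerScheme()
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "role", "label", "sequence"]
        if header != expected:
            raise FormatError(f"{tsv_path}: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise FormatError(f"{tsv_path}:{lineno}: expected 4 columns")
            gene, role, label, seq = parts
            seq = _clean_residues(seq)
            if role == "forward":
                scheme.forwards.setdefault(gene, []).append((label, seq))
            elif role == "reverse":
                if gene in scheme.reverses:
                    raise FormatError(f"{tsv_path}:{lineno}: second reverse primer for {gene}")
                scheme.reverses[gene] = (label, seq)
            else:
                raise FormatError(f"{tsv_path}:{lineno}: role must be forward|reverse")
            if gene in LOCUS_CLASS:
                scheme.gene_locus[gene] = gene
    scheme.validate()
    return scheme
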