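"""Synthetic paired-end amplicon reads with a per-read truth table.

The generator emulates the sequencing design the pipeline targets:
overlapping 300 bp read pairs over first-PCR amplicons that carry the
primer sequences at the fragment termini, one library per animal.  Knobs:
per-gene read depth, per-base substitution error, allelic imbalance for
heterozygotes, and jumping-PCR chimeras (single re-association event, so
one breakpoint, drawn uniformly between the parents' first and last
variable sites — a breakpoint outside that interval would reproduce a
parent, not a detectable chimera).

Deliberately not modelled: indel errors, PCR-cycle-resolved amplification
bias, index hopping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_io import PrimerScheme, SequenceRecord, reverse_complement

__all__ = ["GeneSim", "SimulationSpec", "SimulatedCohort", "simulate", "cohort_spec_from_table"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneSim:
    """One animal x gene cell: which alleles, their balance, which primer."""

    alleles: tuple[str, ...]  # 1-2 allele labels present in the library
    balance: float = 0.5  # probability a read comes from alleles[0] (het only)
    forward_label: str | None = None  # None: first primer matching all alleles

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("1 or 2 alleles per gene per animal")
        if not 0.0 < self.balance < 1.0:
            raise ValueError("balance must be in (0, 1)")


@dataclass
class SimulationSpec:
    library: dict[str, str]  # allele label -> full nucleotide sequence
    scheme: PrimerScheme
    animals: dict[str, dict[str, GeneSim]]  # animal -> gene -> cell
    reads_per_gene: int = 1000
    read_len: int = 300
    error_rate: float = 0.0
    chimera_rate: float = 0.0
    quality_model: tuple = ("linear", 38, 28)  # or ("constant", q)
    seed: int = 0


@dataclass
class SimulatedCohort:
    reads: dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]]
    truth: pd.DataFrame
    amplicons: dict[tuple[str, str], dict[str, str]]  # (animal, gene) -> label -> amplicon


def _amplicon(full: str, fwd: str, rev: str) -> str | None:
    """Forward primer + amplified region + reverse-complemented reverse primer."""
    rev_site = reverse_complement(rev)
    i = full.find(fwd)
    if i < 0:
        return None
    j = full.find(rev_site, i + len(fwd))
    if j < 0:
        return None
    return full[i : j + len(rev_site)]


def _pick_forward(cell: GeneSim, gene: str, spec: SimulationSpec) -> tuple[str, str, str]:
    rev = spec.scheme.reverses[gene][1]
    forwards = spec.scheme.forwards[gene]
    if cell.forward_label is not None:
        forwards = [(lab, seq) for lab, seq in forwards if lab == cell.forward_label]
        if not forwards:
            raise ValueError(f"{gene}: no forward primer labelled {cell.forward_label!r}")
    for lab, seq in forwards:
        if all(_amplicon(spec.library[a], seq, rev) for a in cell.alleles):
            return lab, seq, rev
    raise ValueError(
        f"{gene}: no forward primer amplifies all of {cell.alleles} "
        "(primer site missing or mutated in the template)"
    )


def _qualities(spec: SimulationSpec, n: int) -> tuple[int, ...]:
    kind = spec.quality_model[0]
    if kind == "constant":
        return (int(spec.quality_model[1]),) * n
    if kind == "linear":
        q5, q3 = spec.quality_model[1], spec.quality_model[2]
        return tuple(int(round(q)) for q in np.linspace(q5, q3, n))
    raise ValueError(f"unknown quality model {kind!r}")


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> tuple[str, list[int]]:
    if error_rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.shape[0]) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode(), [int(i) for i in hits]


def simulate(spec: SimulationSpec) -> SimulatedCohort:
    """Generate per-animal read pairs plus the truth table.

    A fixed seed gives byte-identical output.  For heterozygous cells each
    pair's template is allele 1 with probability ``balance``, or — with
    probability ``chimera_rate`` — a single-breakpoint recombinant of the
    two alleles.  R1 is the first ``read_len`` nt of the top strand, R2 the
    first ``read_len`` nt of the bottom strand.
    """
    rng = np.random.default_rng(spec.seed)
    reads: dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]] = {}
    amplicons: dict[tuple[str, str], dict[str, str]] = {}
    truth_rows: list[dict] = []

    for animal in sorted(spec.animals):
        r1s: list[SequenceRecord] = []
        r2s: list[SequenceRecord] = []
        for gene in sorted(spec.animals[animal]):
            cell = spec.animals[animal][gene]
            lab, fwd, rev = _pick_forward(cell, gene, spec)
            amps = {a: _amplicon(spec.library[a], fwd, rev) for a in cell.alleles}
            amplicons[(animal, gene)] = dict(amps)
            chim_rate = spec.chimera_rate
            var_sites: list[int] = []
            if len(cell.alleles) == 2:
                a0, a1 = (amps[cell.alleles[0]], amps[cell.alleles[1]])
                if len(a0) == len(a1):
                    var_sites = [i for i, (x, y) in enumerate(zip(a0, a1)) if x != y]
            if chim_rate > 0 and len(var_sites) < 2:
                if len(cell.alleles) == 1:
                    msg = f"{animal}/{gene}: homozygous cell, chimeras impossible"
                else:
                    msg = f"{animal}/{gene}: <2 variable sites, chimeras undetectable"
                warnings.warn(msg + "; chimera rate coerced to 0")
                chim_rate = 0.0
            for k in range(spec.reads_per_gene):
                read_id = f"{animal}_{gene}_{k}"
                is_chimera = False
                breakpoint_ = -1
                if len(cell.alleles) == 2 and chim_rate > 0 and rng.random() < chim_rate:
                    is_chimera = True
                    breakpoint_ = int(rng.integers(var_sites[0] + 1, var_sites[-1] + 1))
                    order = (0, 1) if rng.random() < 0.5 else (1, 0)
                    pa = amps[cell.alleles[order[0]]]
                    pb = amps[cell.alleles[order[1]]]
                    template = pa[:breakpoint_] + pb[breakpoint_:]
                    label = f"chimera({cell.alleles[order[0]]}|{cell.alleles[order[1]]})"
                elif len(cell.alleles) == 2:
                    pick = 0 if rng.random() < cell.balance else 1
                    label = cell.alleles[pick]
                    template = amps[label]
                else:
                    label = cell.alleles[0]
                    template = amps[label]
                top = template[: spec.read_len]
                bottom = reverse_complement(template)[: spec.read_len]
                top, err1 = _add_errors(top, spec.error_rate, rng)
                bottom, err2 = _add_errors(bottom, spec.error_rate, rng)
                r1s.append(SequenceRecord(read_id, top, "", _qualities(spec, len(top))))
                r2s.append(SequenceRecord(read_id, bottom, "", _qualities(spec, len(bottom))))
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "animal": animal,
                        "gene": gene,
                        "forward_label": lab,
                        "template": label,
                        "is_chimera": is_chimera,
                        "breakpoint": breakpoint_,
                        "errors_r1": ",".join(map(str, err1)),
                        "errors_r2": ",".join(map(str, err2)),
                    }
                )
        reads[animal] = (r1s, r2s)
    return SimulatedCohort(reads, pd.DataFrame(truth_rows), amplicons)


def cohort_spec_from_table(
    reads_per_gene: int = 1000,
    error_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
    balance_range: tuple[float, float] | None = None,
) -> SimulationSpec:
    """A cohort spec reproducing the bundled study genotype table.

    Allelic balance defaults to 0.5 everywhere; with ``balance_range`` each
    heterozygous cell draws its balance uniformly from that interval
    (seeded independently of the read stream).
    """
    from .resources import bundled_library, bundled_novel_alleles, bundled_scheme, table_genotypes

    library = {str(a.name.short()): a.nt_seq for a in bundled_library()}
    library.update(bundled_novel_alleles())
    scheme = bundled_scheme()
    df = table_genotypes()
    rng = np.random.default_rng(seed + 1)
    animals: dict[str, dict[str, GeneSim]] = {}
    for _, row in df.iterrows():
        alleles = [row["allele_1"]]
        if isinstance(row["allele_2"], str) and row["allele_2"]:
            alleles.append(row["allele_2"])
        balance = 0.5
        if balance_range is not None and len(alleles) == 2:
            balance = float(rng.uniform(*balance_range))
        animals.setdefault(row["animal"], {})[row["gene"]] = GeneSim(
            tuple(alleles), balance, row["forward_primer"]
        )
    return SimulationSpec(
        library=library,
        scheme=scheme,
        animals=animals,
        reads_per_gene=reads_per_gene,
        error_rate=error_rate,
        chimera_rate=chimera_rate,
        seed=seed,
    )
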