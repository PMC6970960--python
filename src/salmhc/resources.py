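"""Loaders for the bundled data files (primer scheme, snapshots, fixture table)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .seq_io import (
    PrimerScheme,
    ReferenceAllele,
    load_reference_library,
    read_fasta,
    read_primer_scheme,
)

__all__ = [
    "data_path",
    "bundled_scheme",
    "bundled_library",
    "bundled_novel_alleles",
    "table_genotypes",
]


def data_path(name: str) -> Path:
    with resources.as_file(resources.files("salmhc").joinpath("data").joinpath(name)) as p:
        return Path(p)


def bundled_scheme() -> PrimerScheme:
    return read_primer_scheme(data_path("primer_scheme.tsv"))


def bundled_library() -> list[ReferenceAllele]:
    """The synthetic snapshot of official alleles (see `salmhc.synthlib`)."""
    return load_reference_library(data_path("reference_library.synthetic.fasta"))


def bundled_novel_alleles() -> dict[str, str]:
    """Novel study sequences (unnamed alleles) as label -> nucleotide string."""
    return {r.id: r.residues for r in read_fasta(data_path("novel_alleles.synthetic.fasta"))}


def table_genotypes() -> pd.DataFrame:
    """The published per-animal genotype table, typed in as a fixture."""
    df = pd.read_csv(data_path("table_genotypes.tsv"), sep="\t", dtype={"count_1": "Int64", "count_2": "Int64"})
    return df
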