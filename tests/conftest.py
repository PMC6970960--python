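from __future__ import annotations

import pytest

from salmhc.resources import (
    bundled_library,
    bundled_novel_alleles,
    bundled_scheme,
    table_genotypes,
)
from salmhc.seq_io import reverse_complement
from salmhc.synthlib import PRIMERS


@pytest.fixture(scope="session")
def library():
    return bundled_library()


@pytest.fixture(scope="session")
def novel_alleles():
    return bundled_novel_alleles()


@pytest.fixture(scope="session")
def scheme():
    return bundled_scheme()


@pytest.fixture(scope="session")
def genotype_table():
    return table_genotypes()


@pytest.fixture(scope="session")
def primers():
    return PRIMERS


def amplicon_insert(full_nt: str, fwd: str, rev: str) -> str:
    """The amplified region between (exclusive of) the two primers."""
    i = full_nt.find(fwd)
    j = full_nt.find(reverse_complement(rev), i + len(fwd))
    assert i >= 0 and j >= 0
    return full_nt[i + len(fwd) : j]


@pytest.fixture(scope="session")
def insert_of():
    return amplicon_insert
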