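"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from rbpkit.motif_store import MotifRecord, SynonymTable


def naive_locate(seq: str, pattern: str) -> list[int]:
    """Sliding-window exact search, 1-based offsets, overlaps included.

    Independent oracle for FM-index locate.
    """
    n, m = len(seq), len(pattern)
    return [i + 1 for i in range(n - m + 1) if seq[i : i + m] == pattern]


def naive_count(seq: str, pattern: str) -> int:
    return len(naive_locate(seq, pattern))


def random_rna(rng: random.Random, length: int, alphabet: str = "ACGU") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


@pytest.fixture
def synonym_table() -> SynonymTable:
    table = SynonymTable()
    table.add("Homo sapiens", "CUGBP1", "CELF1")
    table.add("Homo sapiens", "SFRS1", "SRSF1")
    return table


@pytest.fixture
def toy_records() -> list[MotifRecord]:
    return [
        MotifRecord(
            gene_name="SRSF1",
            motif="ACGCGCC",
            organism="Homo sapiens",
            experiment="SELEX",
            gene_id="ENSG00000136450",
            synonyms=["SFRS1", "ASF"],
            domain="RRM",
        ),
        MotifRecord(
            gene_name="RBM8A",
            motif="ACGCGCC",
            organism="Homo sapiens",
            experiment="SELEX",
            gene_id="ENSG00000265241",
            domain="RRM",
        ),
        MotifRecord(
            gene_name="CELF1",
            motif="UGUGUG",
            organism="Homo sapiens",
            experiment="EMSA",
            gene_id="ENSG00000149187",
            synonyms=["CUGBP1"],
            domain="RRM",
        ),
        MotifRecord(
            gene_name="CELF1",
            motif="UGUGUG",
            organism="Mus musculus",
            experiment="EMSA",
            gene_id="ENSMUSG00000005506",
            domain="RRM",
        ),
    ]
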