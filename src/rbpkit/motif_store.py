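"""Motif records: data model, gene-name normalization, distinctness, query, TSV I/O.

A :class:`MotifRecord` ties one binding motif to the RNA-binding protein
(RBP) that recognises it, the experiment that identified it, and the
organism it was observed in.  Because source literature uses inconsistent
gene nomenclature (the same human protein appears as CUGBP1 in one source
and CELF1 in another), records are normalised against a per-organism
synonym table before any deduplication or querying.

A motif is a *distinct entry* if it binds a different RBP, was identified
with a different experimental approach, or was identified in a different
organism — so the dedup key is (motif, gene_name, experiment, organism).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import iupac

logger = logging.getLogger(__name__)

#: Motif lengths accepted for database records.
MIN_MOTIF_LEN = 4
MAX_MOTIF_LEN = 12

#: Column order of the motif TSV interchange format.
TSV_COLUMNS = (
    "gene_name",
    "synonyms",
    "gene_id",
    "organism",
    "motif",
    "len",
    "experiment",
    "pubmed",
    "domain",
    "matrix_id",
    "quality_score",
)


@dataclass
class MotifRecord:
    """One motif x RBP x experiment x organism entry with provenance.

    ``motif`` is an IUPAC nucleotide string of length 4-12 on the RNA
    alphabet; ``quality_score`` is the probability of the motif under its
    associated position probability matrix (see :mod:`rbpkit.pwm`).
    """

    gene_name: str
    motif: str
    organism: str = ""
    experiment: str = ""
    gene_id: str = ""
    pubmed_id: str = ""
    domain: str = ""
    matrix_id: str = ""
    quality_score: float = 1.0
    synonyms: list[str] = field(default_factory=list)

    def validate(self) -> None:
        """Raise ``ValueError`` if an invariant is violated."""
        iupac.normalize_motif(self.motif)  # raises on a bad character
        if not MIN_MOTIF_LEN <= len(self.motif) <= MAX_MOTIF_LEN:
            raise ValueError(
                f"motif {self.motif!r} has length {len(self.motif)}, outside "
                f"[{MIN_MOTIF_LEN}, {MAX_MOTIF_LEN}]"
            )
        if not 0.0 <= self.quality_score <= 1.0:
            raise ValueError(f"quality_score {self.quality_score} outside [0, 1]")

    @property
    def dedup_key(self) -> tuple[str, str, str, str]:
        return (self.motif, self.gene_name, self.experiment, self.organism)


class SynonymTable:
    """Per-organism mapping from alias gene names to official names.

    Official names are fixed points: looking up a name that is already
    official (or simply unknown) returns it unchanged.
    """

    def __init__(self, mapping: dict[tuple[str, str], str] | None = None):
        # keys are (organism, alias) with alias uppercased for lookup
        self._map: dict[tuple[str, str], str] = {}
        if mapping:
            for (organism, alias), official in mapping.items():
                self.add(organism, alias, official)

    def add(self, organism: str, alias: str, official: str) -> None:
        self._map[(organism, alias.upper())] = official
        # official names must be fixed points of the mapping
        self._map.setdefault((organism, official.upper()), official)

    def official_name(self, organism: str, name: str) -> str:
        return self._map.get((organism, name.upper()), name)

    def has_organism(self, organism: str) -> bool:
        return any(org == organism for org, _ in self._map)

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        """Read a 3-column TSV ``organism  alias  official``."""
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                return table
            for row in reader:
                if len(row) < 3:
                    continue
                table.add(row[0], row[1], row[2])
        return table


def normalize_record(raw: MotifRecord, table: SynonymTable) -> MotifRecord:
    """Normalise one record: official gene name, RNA-alphabet motif.

    The motif is uppercased with T unified to U.  If the synonym table maps
    the record's gene name (for its organism) to a different official name,
    the record is renamed and the alias appended to its synonyms.  An
    organism absent from the table is not fatal: a warning is logged and
    only the motif normalisation is applied.

    Idempotent: normalising twice equals normalising once.
    """
    if not raw.gene_name:
        raise ValueError("record has an empty gene_name")
    motif = iupac.normalize_motif(raw.motif)
    out = replace(raw, motif=motif, synonyms=list(raw.synonyms))
    if not table.has_organism(raw.organism):
        logger.warning(
            "organism %r not present in the synonym table; gene name %r left as-is",
            raw.organism,
            raw.gene_name,
        )
        return out
    official = table.official_name(raw.organism, raw.gene_name)
    if official != out.gene_name:
        if out.gene_name not in out.synonyms:
            out.synonyms.append(out.gene_name)
        out.gene_name = official
    return out


def distinct_entries(records: Sequence[MotifRecord]) -> list[MotifRecord]:
    """Deduplicate records on (motif, gene_name, experiment, organism).

    The first occurrence of each key is retained and input order is
    preserved.  The same motif bound by two different RBPs — e.g. ACGCGCC
    recognised by both SRSF1 and RBM8A — stays two distinct entries, as do
    identical motif/RBP pairs from different experiments or organisms.
    """
    seen: set[tuple[str, str, str, str]] = set()
    out: list[MotifRecord] = []
    for rec in records:
        if rec.dedup_key not in seen:
            seen.add(rec.dedup_key)
            out.append(rec)
    return out


@dataclass
class QueryCriteria:
    """Conjunctive filter over motif records; unset fields do not constrain.

    String fields match case-insensitively; ``synonym`` matches against the
    record's synonym list, ``min_len``/``max_len`` bound the motif length.
    """

    gene_name: str | None = None
    synonym: str | None = None
    gene_id: str | None = None
    organism: str | None = None
    experiment: str | None = None
    domain: str | None = None
    motif: str | None = None
    min_len: int | None = None
    max_len: int | None = None

    def validate(self) -> None:
        if (
            self.min_len is not None
            and self.max_len is not None
            and self.min_len > self.max_len
        ):
            raise ValueError(
                f"min_len ({self.min_len}) exceeds max_len ({self.max_len})"
            )

    def matches(self, rec: MotifRecord) -> bool:
        def eq(a: str | None, b: str) -> bool:
            return a is None or a.lower() == b.lower()

        if not (
            eq(self.gene_name, rec.gene_name)
            and eq(self.gene_id, rec.gene_id)
            and eq(self.organism, rec.organism)
            and eq(self.experiment, rec.experiment)
            and eq(self.domain, rec.domain)
            and eq(self.motif, rec.motif)
        ):
            return False
        if self.synonym is not None and self.synonym.lower() not in (
            s.lower() for s in rec.synonyms
        ):
            return False
        if self.min_len is not None and len(rec.motif) < self.min_len:
            return False
        if self.max_len is not None and len(rec.motif) > self.max_len:
            return False
        return True


def query(
    records: Iterable[MotifRecord], criteria: QueryCriteria
) -> list[MotifRecord]:
    """Return the records matching *all* set criteria (AND semantics)."""
    criteria.validate()
    return [rec for rec in records if criteria.matches(rec)]


def read_records(path: str | Path) -> list[MotifRecord]:
    """Read motif records from the TSV interchange format.

    The header must contain every mandatory column; synonyms are
    semicolon-delimited.  A malformed motif raises ``ValueError`` with the
    offending line number.
    """
    records: list[MotifRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a TSV header")
        missing = [c for c in TSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing mandatory column {missing[0]!r}")
        for lineno, row in enumerate(reader, start=2):
            motif = row["motif"]
            try:
                iupac.normalize_motif(motif)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            synonyms = [s for s in row["synonyms"].split(";") if s]
            records.append(
                MotifRecord(
                    gene_name=row["gene_name"],
                    synonyms=synonyms,
                    gene_id=row["gene_id"],
                    organism=row["organism"],
                    motif=motif,
                    experiment=row["experiment"],
                    pubmed_id=row["pubmed"],
                    domain=row["domain"],
                    matrix_id=row["matrix_id"],
                    quality_score=float(row["quality_score"]),
                )
            )
    return records


def write_records(records: Iterable[MotifRecord], path: str | Path) -> None:
    """Write records as TSV; ``read_records`` inverts this bit-exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.gene_name,
                    ";".join(rec.synonyms),
                    rec.gene_id,
                    rec.organism,
                    rec.motif,
                    len(rec.motif),
                    rec.experiment,
                    rec.pubmed_id,
                    rec.domain,
                    rec.matrix_id,
                    repr(rec.quality_score),
                ]
            )
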