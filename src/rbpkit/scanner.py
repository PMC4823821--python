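"""Exact multi-motif scanning over FASTA input via a BWT/FM-index.

Motif hits are perfect matches only: the index is built over the
concatenated input sequences (each multi-FASTA entry separated by a
sentinel so matches never span entries) and queried by FM-index backward
search.  Ambiguous IUPAC motifs are expanded to their concrete strings
before querying, which keeps the index a pure exact-match structure.

Coordinates are 1-based: offset 1 is the first nucleotide of the entry.
Overlapping occurrences are all reported — the enrichment statistics in
:mod:`rbpkit.enrichment` normalise by the number of possible start
positions, which counts overlapping placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from . import iupac
from .motif_store import MAX_MOTIF_LEN, MIN_MOTIF_LEN, MotifRecord

logger = logging.getLogger(__name__)

#: Default cap on total input length, in nucleotides.
DEFAULT_INPUT_CAP = 20_000

#: Entry separator / terminator used inside the index text.  Both sort below
#: the nucleotide alphabet and can never occur in a query pattern.
_SEP = "#"
_TERM = "$"

_ALPHABET = set("ACGUN")


def normalize_sequence(seq: str) -> str:
    """Uppercase, T -> U, and reduce ambiguity codes to N.

    Scanning is exact matching on concrete letters, so any IUPAC ambiguity
    letter in the *input sequence* is unknowable and becomes N (which
    matches nothing).  Characters outside the IUPAC alphabet raise.
    """
    out = []
    for i, ch in enumerate(seq.upper().replace("T", "U")):
        if ch in _ALPHABET:
            out.append(ch)
        elif ch in iupac.MEMBERS:
            out.append("N")
        else:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i + 1}")
    return "".join(out)


@dataclass
class SequenceSet:
    """Ordered, named nucleotide sequences (one per FASTA entry)."""

    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("sequence names must be unique")
        self.entries = [(n, normalize_sequence(s)) for n, s in self.entries]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.entries)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def length_of(self, name: str) -> int:
        for n, s in self.entries:
            if n == name:
                return len(s)
        raise KeyError(name)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        entries = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not entries:
            raise ValueError(f"{path}: no FASTA entries found")
        return cls(entries)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, seq in self.entries:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _build_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), vectorised)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        diff = np.ones(n, dtype=bool)
        diff[1:] = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


class SequenceIndex:
    """FM-index over a :class:`SequenceSet` supporting exact count/locate.

    Holds the BWT of the concatenated text, per-character cumulative
    occurrence tables, the C (chars-smaller) table, and a sampled suffix
    array resolved through LF-mapping.  Construction is deterministic.
    """

    SA_SAMPLE_RATE = 8

    def __init__(self, seqs: SequenceSet, input_cap: int = DEFAULT_INPUT_CAP):
        if len(seqs) == 0:
            raise ValueError("cannot index an empty sequence set")
        if seqs.total_length > input_cap:
            raise ValueError(
                f"input is {seqs.total_length} nt, above the {input_cap:,}-nt limit"
            )
        self.seqs = seqs
        # Entry i occupies [starts[i], starts[i] + len_i) in the text;
        # separators stop matches from spanning entries.
        parts: list[str] = []
        starts: list[int] = []
        pos = 0
        for _, seq in seqs:
            starts.append(pos)
            parts.append(seq + _SEP)
            pos += len(seq) + 1
        text = "".join(parts)[:-1] + _TERM
        self._text = text
        self._starts = np.array(starts, dtype=np.int64)
        self._lengths = np.array([len(s) for _, s in seqs], dtype=np.int64)

        codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        sa = _build_suffix_array(codes)
        bwt_codes = codes[(sa - 1) % len(codes)]
        self._sa_len = len(sa)
        self.bwt = bwt_codes.tobytes().decode("ascii")

        # C table and full cumulative occurrence counts per character.
        chars = sorted(set(text))
        counts = {c: int(np.sum(codes == ord(c))) for c in chars}
        self._C: dict[str, int] = {}
        acc = 0
        for c in chars:
            self._C[c] = acc
            acc += counts[c]
        self._occ: dict[str, np.ndarray] = {}
        for c in chars:
            cum = np.zeros(len(text) + 1, dtype=np.int64)
            np.cumsum(bwt_codes == ord(c), out=cum[1:])
            self._occ[c] = cum

        # Text-position-sampled suffix array for locate via LF-stepping.
        sampled_rows = np.where(sa % self.SA_SAMPLE_RATE == 0)[0]
        self._sa_samples: dict[int, int] = {
            int(r): int(sa[r]) for r in sampled_rows
        }

    # -- core FM-index machinery -------------------------------------------

    def _lf(self, row: int) -> int:
        c = self.bwt[row]
        return self._C[c] + int(self._occ[c][row])

    def _backward_search(self, pattern: str) -> tuple[int, int]:
        """SA interval [lo, hi) of suffixes prefixed by ``pattern``."""
        lo, hi = 0, self._sa_len
        for ch in reversed(pattern):
            if ch not in self._C:
                return 0, 0
            lo = self._C[ch] + int(self._occ[ch][lo])
            hi = self._C[ch] + int(self._occ[ch][hi])
            if lo >= hi:
                return 0, 0
        return lo, hi

    def _resolve(self, row: int) -> int:
        """Text position of SA row, via LF steps to the nearest sample."""
        steps = 0
        while row not in self._sa_samples:
            row = self._lf(row)
            steps += 1
        return (self._sa_samples[row] + steps) % self._sa_len

    def reconstruct_text(self) -> str:
        """Invert the BWT back to the concatenated text (sanity invariant)."""
        out = []
        row = self.bwt.index(_TERM)  # row whose suffix is the full text
        for _ in range(self._sa_len):
            out.append(self.bwt[row])
            row = self._lf(row)
        # walking LF from that row yields text[n-1], text[n-2], ..., text[0]
        return "".join(reversed(out))

    # -- public queries ----------------------------------------------------

    def count(self, motif: str) -> int:
        """Number of perfect-match occurrences of a concrete motif."""
        motif = normalize_sequence(motif)
        if "N" in motif:
            return 0  # N is unknown; it never matches anything
        lo, hi = self._backward_search(motif)
        return hi - lo

    def locate(self, motif: str) -> list[tuple[str, int]]:
        """All perfect-match positions of a concrete motif.

        Returns (sequence_name, 1-based offset) pairs sorted by input
        sequence order then offset; overlapping occurrences are all
        reported.  A motif containing N never matches.
        """
        motif = normalize_sequence(motif)
        if not motif:
            raise ValueError("cannot locate an empty motif")
        if "N" in motif:
            return []  # N is unknown; it never matches anything
        lo, hi = self._backward_search(motif)
        hits: list[tuple[int, int]] = []
        for row in range(lo, hi):
            pos = self._resolve(row)
            seq_i = int(np.searchsorted(self._starts, pos, side="right")) - 1
            local = pos - int(self._starts[seq_i])
            # separators can never start a nucleotide match, so local is
            # always inside the entry
            hits.append((seq_i, local + 1))
        hits.sort()
        names = [n for n, _ in self.seqs]
        return [(names[i], off) for i, off in hits]


@dataclass
class ScanHit:
    """One motif occurrence in one scanned sequence.

    ``offset`` is 1-based; ``matched`` is the concrete string found at
    that position (equal to ``record.motif`` unless the record's motif is
    ambiguous); ``multiplicity`` is t, the number of occurrences of the
    record's motif in this sequence (overlaps counted).
    """

    sequence_name: str
    offset: int
    matched: str
    record: MotifRecord
    multiplicity: int = 1


def scan(
    seqs: SequenceSet,
    records: Sequence[MotifRecord],
    organism: str | None = None,
    min_len: int | None = None,
    max_len: int | None = None,
    input_cap: int = DEFAULT_INPUT_CAP,
    index: SequenceIndex | None = None,
) -> list[ScanHit]:
    """Scan sequences for every motif in ``records``, with optional filters.

    Records can be restricted by organism and/or motif length before
    scanning.  Ambiguous motifs are expanded via
    :func:`rbpkit.iupac.iupac_expand`; every expansion is located exactly.
    Records whose motif length falls outside 4-12 nt are skipped with a
    warning.  Hits carry their record and the multiplicity t of the
    record's motif in that sequence.
    """
    if index is None:
        index = SequenceIndex(seqs, input_cap=input_cap)

    selected: list[MotifRecord] = []
    for rec in records:
        if organism is not None and rec.organism.lower() != organism.lower():
            continue
        if min_len is not None and len(rec.motif) < min_len:
            continue
        if max_len is not None and len(rec.motif) > max_len:
            continue
        if not MIN_MOTIF_LEN <= len(rec.motif) <= MAX_MOTIF_LEN:
            logger.warning(
                "skipping record %s/%s: motif length %d outside [%d, %d]",
                rec.gene_name,
                rec.motif,
                len(rec.motif),
                MIN_MOTIF_LEN,
                MAX_MOTIF_LEN,
            )
            continue
        selected.append(rec)

    hits: list[ScanHit] = []
    for rec in selected:
        # hits per sequence for this record, across all expansions
        per_seq: dict[str, list[tuple[int, str]]] = {}
        for concrete in iupac.iupac_expand(rec.motif):
            for seq_name, offset in index.locate(concrete):
                per_seq.setdefault(seq_name, []).append((offset, concrete))
        for seq_name, occ in per_seq.items():
            occ.sort()
            t = len(occ)
            for offset, concrete in occ:
                hits.append(
                    ScanHit(
                        sequence_name=seq_name,
                        offset=offset,
                        matched=concrete,
                        record=rec,
                        multiplicity=t,
                    )
                )
    order = {name: i for i, (name, _) in enumerate(seqs)}
    hits.sort(key=lambda h: (order[h.sequence_name], h.offset, h.record.dedup_key))
    return hits


def write_hits(hits: Iterable[ScanHit], path: str | Path) -> None:
    """Write scan hits as TSV: sequence, offset, motif, provenance, t."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\toffset\tmotif\tgene_name\torganism\texperiment\tt\n")
        for h in hits:
            fh.write(
                f"{h.sequence_name}\t{h.offset}\t{h.record.motif}\t"
                f"{h.record.gene_name}\t{h.record.organism}\t"
                f"{h.record.experiment}\t{h.multiplicity}\n"
            )
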