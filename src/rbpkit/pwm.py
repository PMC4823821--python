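"""Position probability matrices (PPMs) and motif quality scores.

A PPM gives, for each motif position, the probability of observing each of
A, C, G, U.  Matrices are built either from aligned *winner sequences* —
the selection-experiment outputs (e.g. SELEX rounds) showing strong
binding — as per-position empirical frequencies with no pseudocounts, or
from an IUPAC consensus string by spreading probability uniformly over
each letter's member nucleotides.

The quality score of a motif m of length l under a matrix M is

    S = prod_{i=1..l} P(m_i | M),

the probability of observing the motif under the matrix.  A motif whose
matrix comes from a single winner sequence (single-sequence experiments
such as EMSA or UV cross-linking) therefore scores exactly 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import iupac

#: Column order of every PPM.
ALPHABET = "ACGU"
_INDEX = {ch: i for i, ch in enumerate(ALPHABET)}

#: Tolerance on column normalisation.
COLUMN_TOL = 1e-9


@dataclass
class PPM:
    """Per-position nucleotide probability matrix over {A, C, G, U}.

    ``probs`` has shape (length, 4) in A, C, G, U column order; every row
    sums to 1 within 1e-9.  Database motifs are 4-12 nt; shorter matrices
    are permitted for unit-scale work.
    """

    probs: np.ndarray
    matrix_id: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"PPM must have shape (length, 4), got {self.probs.shape}")
        if np.any(self.probs < 0):
            raise ValueError("PPM entries must be non-negative")
        sums = self.probs.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > COLUMN_TOL)[0]
        if bad.size:
            raise ValueError(
                f"PPM column {bad[0] + 1} sums to {sums[bad[0]]!r}, not 1"
            )

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def prob(self, position: int, letter: str) -> float:
        """P(letter | M) at a 0-based position; IUPAC letters sum members."""
        col = self.probs[position]
        return float(sum(col[_INDEX[nt]] for nt in iupac.members(letter)))

    def consensus(self) -> str:
        """Most probable nucleotide per position (ties broken A<C<G<U)."""
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


def ppm_from_winners(
    winners: Sequence[str], matrix_id: str = ""
) -> PPM:
    """Build a PPM of per-position empirical frequencies from aligned winners.

    Winner sequences must be non-empty, equal-length and concrete
    (A/C/G/U after T->U) — ragged sets need aligning first, and ambiguity
    codes are rejected.  No pseudocounts are added: an unobserved
    nucleotide has probability exactly 0.
    """
    if not winners:
        raise ValueError("at least one winner sequence is required")
    seqs = [w.upper().replace("T", "U") for w in winners]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("winner sequences must all have the same length")
    if length == 0:
        raise ValueError("winner sequences must be non-empty")
    counts = np.zeros((length, 4), dtype=float)
    for s in seqs:
        for i, ch in enumerate(s):
            if ch not in _INDEX:
                raise ValueError(
                    f"winner sequence {s!r} contains {ch!r} at position {i + 1}; "
                    "winners must be concrete A/C/G/U"
                )
            counts[i, _INDEX[ch]] += 1
    return PPM(counts / len(seqs), matrix_id=matrix_id)


def ppm_from_iupac(motif: str, matrix_id: str = "") -> PPM:
    """Build a PPM from an IUPAC consensus, members equally likely.

    Position i assigns probability 1/|members(motif_i)| to each member
    nucleotide and 0 elsewhere; R gives {A: 0.5, G: 0.5}, N gives 0.25
    each.  Used when the underlying winner sequences are not annotated.
    """
    motif = iupac.normalize_motif(motif)
    if not motif:
        raise ValueError("motif must be non-empty")
    probs = np.zeros((len(motif), 4), dtype=float)
    for i, ch in enumerate(motif):
        mem = iupac.members(ch)
        for nt in mem:
            probs[i, _INDEX[nt]] = 1.0 / len(mem)
    return PPM(probs, matrix_id=matrix_id)


def quality_score(motif: str, ppm: PPM) -> float:
    """Probability of a motif under a PPM: the product of column probabilities.

    For an ambiguous motif letter, P(m_i | M) is the summed column
    probability over its member nucleotides, so an IUPAC-derived matrix
    scores its own consensus as 1.0.  Always in [0, 1].
    """
    motif = iupac.normalize_motif(motif)
    if len(motif) != ppm.length:
        raise ValueError(
            f"motif length {len(motif)} does not match PPM length {ppm.length}"
        )
    score = 1.0
    for i, ch in enumerate(motif):
        score *= ppm.prob(i, ch)
    # guard against float drift on summed ambiguous columns
    return min(score, 1.0)


# Re-exported here because scanners expand ambiguous motifs before matching.
iupac_expand = iupac.iupac_expand


def write_ppms(ppms: Iterable[PPM], path: str | Path) -> None:
    """Write matrices in text form: a ``>matrix_id`` header line, then one
    row per position of four tab-separated probabilities in A,C,G,U order."""
    with open(path, "w", encoding="utf-8") as fh:
        for ppm in ppms:
            fh.write(f">{ppm.matrix_id}\n")
            for row in ppm.probs:
                fh.write("\t".join(repr(float(p)) for p in row) + "\n")


def read_ppms(path: str | Path) -> list[PPM]:
    """Inverse of :func:`write_ppms`."""
    ppms: list[PPM] = []
    matrix_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if matrix_id is not None:
            if not rows:
                raise ValueError(f"matrix {matrix_id!r} has no probability rows")
            ppms.append(PPM(np.array(rows), matrix_id=matrix_id))

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                matrix_id = line[1:]
                rows = []
            else:
                rows.append([float(x) for x in line.split("\t")])
    flush()
    return ppms
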