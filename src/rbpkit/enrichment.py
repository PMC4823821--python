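"""Genomic-functional-context (GFC) backgrounds and log-odds enrichment.

Short motifs match almost any sequence by chance, so raw hits need a
biological yardstick.  Each scanned motif is compared against three
background sequence populations from the organism of interest — all exons
with 250 nt of flank (``exon250``), all introns (``intron``) and all
coding sequences (``cds``).  For a motif of length l_m found t times in an
input sequence of length l_s:

    Obs = t / (l_s - l_m + 1)
    Exp = c_m / sum_i (len(s_i) - l_m + 1)        over background sequences
    OR  = log2(Obs / Exp)

where c_m counts the motif's (overlapping) occurrences in the background.
OR > 0 means the motif is denser in the input than in the context.  When a
motif never occurs in a background (Exp = 0) the ratio is undefined and
reported as the ``UNDEFINED`` sentinel rather than smoothed.

Backgrounds are supplied as FASTA per context and organism; counting goes
through the same FM-index as the scanner so overlap conventions agree.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import iupac
from .scanner import ScanHit, SequenceIndex, SequenceSet

#: The three genomic functional contexts.
CONTEXTS = ("exon250", "intron", "cds")

#: Sentinel for a log-odds ratio that is mathematically undefined (the
#: motif never occurs in the background, Exp = 0).
UNDEFINED = "undefined"

#: Sentinel for a context with no background available for the organism.
UNAVAILABLE = "unavailable"


def observed_frequency(t: int, l_s: int, l_m: int) -> float:
    """Observed motif frequency: occurrences over possible start positions.

    Obs = t / (l_s - l_m + 1); overlapping placements are counted, so t may
    run up to the full number of start positions.
    """
    if l_m < 1:
        raise ValueError("motif length must be at least 1")
    if l_s < l_m:
        raise ValueError(
            f"sequence length {l_s} is shorter than motif length {l_m}"
        )
    if t < 0:
        raise ValueError("occurrence count t cannot be negative")
    return t / (l_s - l_m + 1)


@dataclass
class GFCBackground:
    """Occurrence counts for one context/organism background population.

    ``counts`` maps each motif (as given, possibly ambiguous) to c_m, its
    total overlapping occurrences across the background sequences;
    ``positions`` maps motif length l_m to D_l = sum_i max(0, len(s_i) -
    l_m + 1), the number of possible placements.  ``fasta_digest`` records
    a SHA-256 over the normalised background so counts are attributable.
    """

    context: str
    organism: str
    counts: dict[str, int]
    positions: dict[int, int]
    fasta_digest: str = ""

    def expected_frequency(self, motif: str, l_m: int | None = None) -> float:
        """Exp = c_m / D_l for one motif; raises if D_l is zero."""
        if l_m is None:
            l_m = len(motif)
        if motif not in self.counts:
            raise KeyError(
                f"motif {motif!r} was not counted in the {self.context} background"
            )
        d = self.positions.get(l_m, 0)
        if d <= 0:
            raise ValueError(
                f"background {self.context}/{self.organism} has no possible "
                f"positions for motifs of length {l_m}"
            )
        return self.counts[motif] / d


def build_background(
    context_fasta: SequenceSet,
    motifs: Sequence[str],
    context: str,
    organism: str = "",
    input_cap: int = 10**9,
) -> GFCBackground:
    """Count motif occurrences in one background sequence population.

    Ambiguous motifs are expanded and their expansion counts summed under
    the motif as given.  Occurrences overlap; each background sequence
    shorter than the motif contributes zero positions.
    """
    if len(context_fasta) == 0 or context_fasta.total_length == 0:
        raise ValueError("background FASTA must be non-empty")
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}, got {context!r}")
    index = SequenceIndex(context_fasta, input_cap=input_cap)
    counts: dict[str, int] = {}
    positions: dict[int, int] = {}
    for motif in motifs:
        motif_n = iupac.normalize_motif(motif)
        c = sum(index.count(x) for x in iupac.iupac_expand(motif_n))
        counts[motif_n] = c
        l_m = len(motif_n)
        if l_m not in positions:
            positions[l_m] = sum(
                max(0, len(seq) - l_m + 1) for _, seq in context_fasta
            )
    digest = hashlib.sha256(
        "".join(f">{n}\n{s}\n" for n, s in context_fasta).encode()
    ).hexdigest()
    return GFCBackground(
        context=context,
        organism=organism,
        counts=counts,
        positions=positions,
        fasta_digest=digest,
    )


def expected_frequency(bg: GFCBackground, motif: str, l_m: int | None = None) -> float:
    """Module-level convenience for :meth:`GFCBackground.expected_frequency`."""
    return bg.expected_frequency(iupac.normalize_motif(motif), l_m)


def log_odds(obs: float, exp: float):
    """log2(Obs / Exp), or the ``UNDEFINED`` sentinel when Exp = 0.

    Only found motifs are scored, so obs must be positive.
    """
    if obs <= 0:
        raise ValueError("log-odds is only defined for found motifs (obs > 0)")
    if exp == 0:
        return UNDEFINED
    return math.log2(obs / exp)


@dataclass
class ScoredHit:
    """A scan hit annotated with Obs and per-context log-odds ratios.

    ``odds`` maps each context name to a float OR, or to ``UNDEFINED``
    (motif absent from that background) or ``UNAVAILABLE`` (no background
    supplied for that context/organism).
    """

    hit: ScanHit
    obs: float
    odds: dict[str, object] = field(default_factory=dict)


def score_hits(
    hits: Sequence[ScanHit],
    backgrounds: Mapping[str, GFCBackground],
    seqs: SequenceSet,
) -> list[ScoredHit]:
    """Annotate scan hits with Obs and the three context log-odds ratios.

    ``backgrounds`` maps context names (any subset of exon250/intron/cds)
    to count tables; hits whose record's organism differs from a
    background's organism get ``UNAVAILABLE`` for that context.  Obs uses
    the length of the multi-FASTA entry in which the hit occurs.
    """
    lengths = {name: len(seq) for name, seq in seqs}
    scored: list[ScoredHit] = []
    for hit in hits:
        l_s = lengths[hit.sequence_name]
        l_m = len(hit.record.motif)
        obs = observed_frequency(hit.multiplicity, l_s, l_m)
        odds: dict[str, object] = {}
        for context in CONTEXTS:
            bg = backgrounds.get(context)
            if bg is None or (
                bg.organism
                and hit.record.organism
                and bg.organism.lower() != hit.record.organism.lower()
            ):
                odds[context] = UNAVAILABLE
                continue
            try:
                exp = bg.expected_frequency(hit.record.motif, l_m)
            except KeyError:
                odds[context] = UNAVAILABLE
                continue
            odds[context] = log_odds(obs, exp)
        scored.append(ScoredHit(hit=hit, obs=obs, odds=odds))
    return scored


def write_background(bg: GFCBackground, path: str | Path) -> None:
    """Write a background count table as TSV: context, organism, motif, c, D."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("context\torganism\tmotif\tc\tD\n")
        for motif in sorted(bg.counts):
            d = bg.positions[len(motif)]
            fh.write(f"{bg.context}\t{bg.organism}\t{motif}\t{bg.counts[motif]}\t{d}\n")


def read_background(path: str | Path) -> GFCBackground:
    """Inverse of :func:`write_background`."""
    counts: dict[str, int] = {}
    positions: dict[int, int] = {}
    context = organism = ""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["context", "organism", "motif", "c", "D"]
        if header != expected:
            raise ValueError(f"{path}: expected header {expected}, got {header}")
        for line in fh:
            context, organism, motif, c, d = line.rstrip("\n").split("\t")
            counts[motif] = int(c)
            positions[len(motif)] = int(d)
    if not counts:
        raise ValueError(f"{path}: background table has no rows")
    return GFCBackground(
        context=context, organism=organism, counts=counts, positions=positions
    )


def write_scored_hits(scored: Iterable[ScoredHit], path: str | Path) -> None:
    """Scan-hit TSV extended with Obs and the Exon250/CDS/intron columns."""

    def fmt(v: object) -> str:
        return f"{v:.6g}" if isinstance(v, float) else str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "sequence\toffset\tmotif\tgene_name\torganism\texperiment\tt\t"
            "obs\texon250\tcds\tintron\n"
        )
        for s in scored:
            h = s.hit
            fh.write(
                f"{h.sequence_name}\t{h.offset}\t{h.record.motif}\t"
                f"{h.record.gene_name}\t{h.record.organism}\t{h.record.experiment}\t"
                f"{h.multiplicity}\t{s.obs:.6g}\t{fmt(s.odds['exon250'])}\t"
                f"{fmt(s.odds['cds'])}\t{fmt(s.odds['intron'])}\n"
            )
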