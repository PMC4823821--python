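"""Deterministic synthetic data for every pipeline stage.

Three generators cover the toolkit's input kinds with recorded ground
truth: FASTA with motifs planted at known offsets (scanner truth),
scan/background FASTA pairs with an exact planted enrichment ratio
(log-odds truth), and toy protein-RNA coordinate files with contacts
planted at requested distances (structural truth).  Each generator is a
pure function of its arguments — the same seed yields byte-identical
output on any platform — so tests and examples never download anything.

The generators emulate the *shape* of real data (FASTA entries, PDB ATOM
records, base composition), not its biology: planted sequences are i.i.d.
background plus inserted motifs, and toy structures are geometric
scaffolds (a glycine chain opposite an RNA strand), not folded molecules.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from .scanner import SequenceSet

_NT = "ACGU"


def _naive_count(seq: str, motif: str) -> int:
    """Overlap-counting sliding-window occurrence count (oracle-grade)."""
    return sum(
        1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
    )


def _naive_find(seq: str, motif: str) -> list[int]:
    """1-based offsets of all (overlapping) occurrences."""
    return [
        i + 1
        for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] == motif
    ]


# ---------------------------------------------------------------------------
# planted-motif FASTA


def gen_planted_fasta(
    seed: int,
    sequence_lengths: list[int],
    plants: list[tuple[int, str, int]],
    alphabet: str = _NT,
    name_prefix: str = "seq",
) -> tuple[SequenceSet, list[tuple[str, int, str]]]:
    """Random FASTA with motifs planted at recorded offsets.

    ``plants`` lists (sequence index, concrete motif, copies); copies are
    placed at random non-overlapping positions over an i.i.d. background
    drawn from ``alphabet``.  Returns the sequence set and a truth table
    of (sequence_name, 1-based offset, motif) for every planted copy —
    chance occurrences of a motif in the background are possible and are
    *not* listed; verify totals with a naive search when exact counts
    matter (or use :func:`gen_background_pair`).
    """
    rng = random.Random(seed)
    seqs = [
        [rng.choice(alphabet) for _ in range(n)] for n in sequence_lengths
    ]
    names = [f"{name_prefix}{i + 1}" for i in range(len(seqs))]
    truth: list[tuple[str, int, str]] = []
    occupied: list[set[int]] = [set() for _ in seqs]
    for seq_i, motif, copies in plants:
        motif = motif.upper().replace("T", "U")
        n = sequence_lengths[seq_i]
        if len(motif) > n:
            raise ValueError(
                f"motif {motif!r} ({len(motif)} nt) does not fit in a {n}-nt sequence"
            )
        for _ in range(copies):
            for _attempt in range(10_000):
                start = rng.randrange(0, n - len(motif) + 1)
                span = set(range(start, start + len(motif)))
                if span.isdisjoint(occupied[seq_i]):
                    occupied[seq_i] |= span
                    seqs[seq_i][start : start + len(motif)] = list(motif)
                    truth.append((names[seq_i], start + 1, motif))
                    break
            else:
                raise ValueError(
                    f"could not place {copies} non-overlapping copies of "
                    f"{motif!r} in a {n}-nt sequence"
                )
    truth.sort(key=lambda t: (t[0], t[1]))
    return SequenceSet([(nm, "".join(s)) for nm, s in zip(names, seqs)]), truth


# ---------------------------------------------------------------------------
# enrichment pair with exact planted ratio


@dataclass
class BackgroundPairTruth:
    """Exact planted counts for one scan/background FASTA pair."""

    motif: str
    t: int  # occurrences in the scan sequence
    scan_positions: int  # l_s - l_m + 1
    c: int  # occurrences in the background
    background_positions: int  # sum over background sequences

    @property
    def log_odds(self) -> float:
        obs = Fraction(self.t, self.scan_positions)
        exp = Fraction(self.c, self.background_positions)
        return math.log2(obs / exp)


def _exact_plant(
    rng: random.Random, motif: str, copies: int, positions: int
) -> str:
    """One sequence of ``positions + len(motif) - 1`` nt containing the
    motif exactly ``copies`` times, built from single-letter filler."""
    l_m = len(motif)
    length = positions + l_m - 1
    if copies * l_m > length:
        raise ValueError(
            f"cannot place {copies} copies of a {l_m}-mer in {length} nt"
        )
    for filler in _NT:  # try fillers until no chance occurrences arise
        seq = [filler] * length
        occupied: set[int] = set()
        placed = 0
        local = random.Random(rng.randrange(2**31))
        for _attempt in range(50_000):
            if placed == copies:
                break
            start = local.randrange(0, length - l_m + 1)
            span = set(range(start, start + l_m))
            if span.isdisjoint(occupied):
                occupied |= span
                seq[start : start + l_m] = list(motif)
                placed += 1
        text = "".join(seq)
        if placed == copies and _naive_count(text, motif) == copies:
            return text
    raise ValueError(
        f"could not construct a sequence with exactly {copies} copies of {motif!r}"
    )


def gen_background_pair(
    seed: int,
    motif: str = "UGCAUG",
    rho: float | int | Fraction = 10,
    background_copies: int = 2,
    positions: int = 400,
) -> tuple[SequenceSet, SequenceSet, BackgroundPairTruth]:
    """A (scan FASTA, context FASTA) pair with exact enrichment ratio rho.

    Both files expose the same number of possible start positions, the
    background holds ``background_copies`` occurrences of ``motif`` and
    the scan sequence holds ``rho * background_copies`` (so rho *
    background_copies must be a non-negative integer).  Occurrence counts
    are exact by construction — verified with a naive sliding-window
    search — so OR = log2(rho) in closed form from the truth counts.
    rho = 0 plants nothing in the scan sequence.
    """
    rho = Fraction(rho)
    if rho < 0:
        raise ValueError("enrichment ratio rho must be non-negative")
    t_frac = rho * background_copies
    if t_frac.denominator != 1:
        raise ValueError(
            f"rho * background_copies = {t_frac} is not an integer; "
            "adjust background_copies"
        )
    t = int(t_frac)
    motif = motif.upper().replace("T", "U")
    rng = random.Random(seed)
    scan_seq = _exact_plant(rng, motif, t, positions)
    ctx_seq = _exact_plant(rng, motif, background_copies, positions)
    scan = SequenceSet([("scan1", scan_seq)])
    ctx = SequenceSet([("ctx1", ctx_seq)])
    truth = BackgroundPairTruth(
        motif=motif,
        t=t,
        scan_positions=positions,
        c=background_copies,
        background_positions=positions,
    )
    return scan, ctx, truth


# ---------------------------------------------------------------------------
# toy protein-RNA structures


@dataclass
class PlantedNucleotide:
    """One RNA residue of a toy complex, with requested contact distances.

    ``polar_dist`` places the residue's O2' atom at exactly that distance
    from the matching protein backbone N; ``carbon_dist`` places its C1'
    at that distance from the protein CA.  ``None`` parks the atom 50 A
    away (no contact of that kind).
    """

    base: str
    polar_dist: float | None = None
    carbon_dist: float | None = None


@dataclass
class ToyStructureTruth:
    """Which residues contact (by kind) and which runs qualify as sites."""

    hbond_residues: list[int]
    vdw_residues: list[int]
    contacted_residues: list[int]
    sites: list[tuple[int, int, str]]  # (start, end, motif)


_FAR = 50.0
_SPACING = 10.0  # residue-to-residue x spacing; isolates contact pairs


def gen_toy_structure(
    nucleotides: list[PlantedNucleotide],
    method: str = "X-ray",
    resolution: float | None = 2.0,
    hbond_cutoff: float = 3.0,
    vdw_cutoff: float = 3.9,
    min_run: int = 4,
    structure_id: str = "TOY1",
    extra_model: bool = False,
) -> tuple[str, ToyStructureTruth]:
    """PDB-format text for a toy protein-RNA complex, plus ground truth.

    One glycine (N + CA atoms) faces each RNA nucleotide, 10 A from its
    neighbours so contacts stay pairwise.  The nucleotide's O2' sits
    ``polar_dist`` from the glycine N and its C1' ``carbon_dist`` from
    the glycine CA, both exact by construction.  Truth is computed
    analytically from the requested distances with the given cutoffs.
    ``extra_model`` appends a second, shifted MODEL (to exercise the
    first-model rule).  Atom pairs closer than 1 A raise.
    """
    for nt in nucleotides:
        if nt.base not in _NT:
            raise ValueError(f"nucleotide base must be one of ACGU, got {nt.base!r}")
        for d in (nt.polar_dist, nt.carbon_dist):
            if d is not None and d < 1.0:
                raise ValueError(f"planted distance {d} A would overlap atoms (< 1 A)")

    method_line = {
        "X-ray": "X-RAY DIFFRACTION",
        "NMR": "SOLUTION NMR",
        "EM": "ELECTRON MICROSCOPY",
    }.get(method, method.upper())

    lines: list[str] = [
        f"HEADER    {'PROTEIN/RNA COMPLEX':<40}{'01-JAN-15':>9}   {structure_id:>4}"
    ]
    lines.append(f"EXPDTA    {method_line}")
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {resolution:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")

    def atom_line(
        serial: int, name: str, resname: str, chain: str, resnum: int,
        x: float, y: float, z: float, element: str,
    ) -> str:
        # PDB fixed columns; atom names starting with a digit stay left-packed
        nm = name if len(name) >= 4 else f" {name:<3}"
        return (
            f"ATOM  {serial:5d} {nm}{'':1}{resname:>3} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}"
        )

    def model_block(shift: float) -> list[str]:
        out: list[str] = []
        serial = 1
        for i, _nt in enumerate(nucleotides, start=1):
            x = _SPACING * i
            out.append(atom_line(serial, "N", "GLY", "A", i, x, 0.0, shift, "N"))
            serial += 1
            out.append(atom_line(serial, "CA", "GLY", "A", i, x, 0.0, shift + 1.5, "C"))
            serial += 1
        out.append("TER")
        for i, nt in enumerate(nucleotides, start=1):
            x = _SPACING * i
            pd = nt.polar_dist if nt.polar_dist is not None else _FAR
            cd = nt.carbon_dist if nt.carbon_dist is not None else _FAR
            out.append(atom_line(serial, "O2'", nt.base, "B", i, x, pd, shift, "O"))
            serial += 1
            out.append(atom_line(serial, "C1'", nt.base, "B", i, x, cd, shift + 1.5, "C"))
            serial += 1
        out.append("TER")
        return out

    if extra_model:
        lines.append("MODEL        1")
        lines.extend(model_block(0.0))
        lines.append("ENDMDL")
        lines.append("MODEL        2")
        lines.extend(model_block(100.0))
        lines.append("ENDMDL")
    else:
        lines.extend(model_block(0.0))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    # analytic truth: within a residue pair the candidate distances are
    # O2'-N = pd, C1'-CA = cd, O2'-CA = sqrt(pd^2+1.5^2), C1'-N = sqrt(cd^2+1.5^2)
    hbond_res: list[int] = []
    vdw_res: list[int] = []
    for i, nt in enumerate(nucleotides, start=1):
        pd = nt.polar_dist if nt.polar_dist is not None else _FAR
        cd = nt.carbon_dist if nt.carbon_dist is not None else _FAR
        if pd <= hbond_cutoff:
            hbond_res.append(i)
        min_any = min(pd, cd)
        if min_any <= vdw_cutoff:
            vdw_res.append(i)
    contacted = sorted(set(hbond_res) | set(vdw_res))

    sites: list[tuple[int, int, str]] = []
    run: list[int] = []
    for i in range(1, len(nucleotides) + 1):
        if i in contacted and (not run or i == run[-1] + 1):
            run.append(i)
        else:
            if len(run) >= min_run:
                sites.append(
                    (run[0], run[-1], "".join(nucleotides[j - 1].base for j in run))
                )
            run = [i] if i in contacted else []
    if len(run) >= min_run:
        sites.append((run[0], run[-1], "".join(nucleotides[j - 1].base for j in run)))

    truth = ToyStructureTruth(
        hbond_residues=hbond_res,
        vdw_residues=vdw_res,
        contacted_residues=contacted,
        sites=sites,
    )
    return pdb_text, truth


def write_toy_structure(pdb_text: str, path: str | Path) -> None:
    Path(path).write_text(pdb_text, encoding="utf-8")
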