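"""IUPAC degenerate nucleotide codes on the RNA alphabet.

Every motif in the toolkit lives on {A, C, G, U}; DNA input is unified to
RNA at ingestion (T -> U).  The 15 IUPAC ambiguity codes map each letter to
the set of concrete nucleotides it denotes, e.g. R -> {A, G}, N -> all four.
"""

from __future__ import annotations

from itertools import product

#: Concrete (unambiguous) RNA nucleotides.
CONCRETE = "ACGU"

#: IUPAC letter -> frozenset of concrete RNA nucleotides it denotes.
MEMBERS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "T": frozenset("U"),  # accepted on input; normalised to U
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: Default ceiling on the number of concrete expansions of one motif.
DEFAULT_EXPANSION_CAP = 4096


def normalize_motif(motif: str) -> str:
    """Uppercase a motif and unify T to U.

    Raises ``ValueError`` naming the offending position if a character is
    not an IUPAC nucleotide code.
    """
    out = motif.upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in MEMBERS:
            raise ValueError(
                f"invalid IUPAC nucleotide {ch!r} at position {i + 1} of motif {motif!r}"
            )
    return out


def members(letter: str) -> frozenset[str]:
    """Concrete nucleotides denoted by one IUPAC letter."""
    try:
        return MEMBERS[letter.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code {letter!r}") from None


def is_concrete(motif: str) -> bool:
    """True if the motif contains only A/C/G/U."""
    return all(ch in CONCRETE for ch in motif)


def expansion_size(motif: str) -> int:
    """Number of concrete strings an IUPAC motif denotes."""
    n = 1
    for ch in motif:
        n *= len(members(ch))
    return n


def iupac_expand(motif: str, cap: int = DEFAULT_EXPANSION_CAP) -> list[str]:
    """Expand an IUPAC motif into the concrete strings it denotes.

    The expansion is the Cartesian product over per-position member sets,
    returned in lexicographic order; a concrete motif expands to itself.
    A ``ValueError`` is raised if the expansion would exceed ``cap``
    strings (default 4096).
    """
    motif = normalize_motif(motif)
    size = expansion_size(motif)
    if size > cap:
        raise ValueError(
            f"motif {motif!r} expands to {size} concrete strings, above the cap of {cap}"
        )
    pools = [sorted(MEMBERS[ch]) for ch in motif]
    return ["".join(p) for p in product(*pools)]
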