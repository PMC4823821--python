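"""Binding-site motifs from protein-RNA 3D complexes.

Many RNA-binding specificities are recoverable from solved complex
structures: if a run of nucleotides sits close enough to the protein to
form hydrogen bonds or van der Waals contacts, its base sequence is a
candidate binding motif.  The pipeline here is distance-based contact
detection: a nucleotide is *contacted* when an N/O atom of the nucleotide
lies within 3.0 A of an N/O atom of the protein (hydrogen bond) or any
atom pair lies within 3.9 A (van der Waals); a *binding site* is a
maximal run of four or more contiguous contacted nucleotides, read 5'->3'.

Extracted motifs are validated against reference motifs for the same
protein by ungapped alignment, classifying pairs by their minimum
mismatch count.

Hydrogen-bond assignment here is purely distance-based; no donor/acceptor
angular criteria are applied.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import iupac

logger = logging.getLogger(__name__)

#: Distance cutoffs in Angstrom, inclusive.
HBOND_CUTOFF = 3.0
VDW_CUTOFF = 3.9

#: X-ray structures must be solved better than this resolution (A).
XRAY_RESOLUTION_CUTOFF = 3.9

#: Minimum contiguous contacted nucleotides forming a binding site.
MIN_RUN = 4

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_NT = {"A", "C", "G", "U"}
_POLAR = {"N", "O"}


@dataclass
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]


@dataclass
class Residue:
    number: int
    icode: str  # insertion code, "" if none
    name: str
    atoms: list[Atom]
    subchain: str = ""  # changes across TER records


@dataclass
class Chain:
    chain_id: str
    polymer_class: str  # protein | rna | other
    residues: list[Residue]


@dataclass
class Structure:
    """A parsed coordinate file, reduced to what contact analysis needs.

    NMR ensembles are reduced to the first model.  Chains are classified
    deterministically from residue names: standard amino acids -> protein,
    A/C/G/U -> rna; modified nucleotides fall outside the RNA residue set
    (they cannot appear in a concrete motif and therefore break runs).
    """

    structure_id: str
    method: str  # X-ray | NMR | EM | unknown
    resolution: float | None
    chains: list[Chain]
    rna_absent: bool = False


def _classify_chain(residues: list[Residue]) -> str:
    n_aa = sum(1 for r in residues if r.name in _AA3)
    n_nt = sum(1 for r in residues if r.name in _NT)
    if n_aa > n_nt:
        return "protein"
    if n_nt > n_aa:
        return "rna"
    return "other"


def _read_header_fields(path: Path) -> tuple[str, str]:
    """(experimental method, id code) from the EXPDTA and HEADER records."""
    method = "unknown"
    id_code = ""
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            if line.startswith("HEADER") and len(line.rstrip()) >= 66:
                id_code = line[62:66].strip()
            elif line.startswith("EXPDTA"):
                text = line[6:].upper()
                if "NMR" in text:
                    method = "NMR"
                elif "X-RAY" in text:
                    method = "X-ray"
                elif "MICROSCOPY" in text or "CRYO-EM" in text:
                    method = "EM"
            elif line.startswith(("ATOM", "MODEL")):
                break
    return method, id_code


def parse_structure(path: str | Path) -> Structure:
    """Parse a PDB-format coordinate file into a :class:`Structure`.

    Resolution comes from the REMARK 2 record when present; only the first
    MODEL of an ensemble is kept.  A file without an RNA chain parses fine
    but is flagged ``rna_absent``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate models found")
    st.setup_entities()  # assigns subchains, splitting at TER records
    model = st[0]

    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            atoms = [
                Atom(
                    name=at.name,
                    element=at.element.name,
                    pos=(at.pos.x, at.pos.y, at.pos.z),
                )
                for at in res
            ]
            residues.append(
                Residue(
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name.strip(),
                    atoms=atoms,
                    subchain=res.subchain,
                )
            )
        if residues:
            chains.append(
                Chain(
                    chain_id=ch.name,
                    polymer_class=_classify_chain(residues),
                    residues=residues,
                )
            )

    resolution = float(st.resolution) if st.resolution > 0 else None
    rna_absent = not any(c.polymer_class == "rna" for c in chains)
    method, id_code = _read_header_fields(path)
    return Structure(
        structure_id=id_code or path.stem,
        method=method,
        resolution=resolution,
        chains=chains,
        rna_absent=rna_absent,
    )


def eligible(s: Structure) -> bool:
    """Whether a structure qualifies for motif extraction.

    NMR and EM structures qualify outright; X-ray structures qualify only
    with a recorded resolution better than 3.9 A.  An X-ray entry without
    a resolution record is rejected with a warning.
    """
    if s.method in ("NMR", "EM"):
        return True
    if s.method == "X-ray":
        if s.resolution is None:
            logger.warning(
                "%s: X-ray structure without a resolution record; ineligible",
                s.structure_id,
            )
            return False
        return s.resolution < XRAY_RESOLUTION_CUTOFF
    logger.warning(
        "%s: unrecognised experimental method %r; ineligible",
        s.structure_id,
        s.method,
    )
    return False


@dataclass
class Contact:
    """One RNA nucleotide's contact with the protein, by kind.

    ``min_distance`` is the smallest qualifying atom-pair distance;
    the protein chain/residue fields identify the closest partner.
    """

    rna_chain: str
    rna_residue_number: int
    nucleotide: str
    kind: str  # hbond | vdw
    min_distance: float
    protein_chain: str
    protein_residue_number: int


def find_contacts(
    s: Structure,
    hbond_cutoff: float = HBOND_CUTOFF,
    vdw_cutoff: float = VDW_CUTOFF,
) -> list[Contact]:
    """Distance-based protein contacts for every RNA nucleotide.

    A nucleotide gets an ``hbond`` contact when any of its N/O atoms lies
    within ``hbond_cutoff`` of any protein N/O atom, and a ``vdw`` contact
    when any atom pair lies within ``vdw_cutoff``.  Cutoffs are inclusive.
    All protein chains are considered jointly; per-kind minimum distances
    and the closest protein residue are recorded.
    """
    if s.rna_absent:
        raise ValueError(f"{s.structure_id}: no RNA chain to analyse")
    protein_atoms: list[tuple[np.ndarray, bool, str, int]] = []
    for ch in s.chains:
        if ch.polymer_class != "protein":
            continue
        for res in ch.residues:
            for at in res.atoms:
                protein_atoms.append(
                    (
                        np.array(at.pos),
                        at.element in _POLAR,
                        ch.chain_id,
                        res.number,
                    )
                )
    if not protein_atoms:
        raise ValueError(f"{s.structure_id}: no protein chain to analyse")

    p_xyz = np.stack([a[0] for a in protein_atoms])
    p_polar = np.array([a[1] for a in protein_atoms])
    p_chain = [a[2] for a in protein_atoms]
    p_resnum = np.array([a[3] for a in protein_atoms])

    contacts: list[Contact] = []
    for ch in s.chains:
        if ch.polymer_class != "rna":
            continue
        for res in ch.residues:
            if res.name not in _NT:
                continue  # modified nucleotide: excluded from motifs
            r_xyz = np.stack([np.array(at.pos) for at in res.atoms])
            r_polar = np.array([at.element in _POLAR for at in res.atoms])
            # all-pairs distances nucleotide x protein
            d = np.linalg.norm(r_xyz[:, None, :] - p_xyz[None, :, :], axis=2)
            for kind, cutoff, mask in (
                ("hbond", hbond_cutoff, np.outer(r_polar, p_polar)),
                ("vdw", vdw_cutoff, np.ones_like(d, dtype=bool)),
            ):
                dm = np.where(mask, d, np.inf)
                min_d = float(dm.min())
                if min_d <= cutoff:
                    j = int(np.unravel_index(dm.argmin(), dm.shape)[1])
                    contacts.append(
                        Contact(
                            rna_chain=ch.chain_id,
                            rna_residue_number=res.number,
                            nucleotide=res.name,
                            kind=kind,
                            min_distance=min_d,
                            protein_chain=p_chain[j],
                            protein_residue_number=int(p_resnum[j]),
                        )
                    )
    return contacts


@dataclass
class BindingSite:
    """A maximal run of >= min_run contiguous contacted nucleotides."""

    structure_id: str
    rna_chain: str
    start_residue: int
    end_residue: int
    motif: str


def call_binding_sites(
    contacts: list[Contact],
    s: Structure,
    min_run: int = MIN_RUN,
) -> list[BindingSite]:
    """Emit binding sites from per-nucleotide contacts.

    A site is a maximal run of consecutive residue numbers within one RNA
    chain in which every nucleotide has at least one contact of either
    kind; runs shorter than ``min_run`` (default 4) are dropped.  Residues
    with insertion codes, modified nucleotides and chain breaks (TER) all
    interrupt runs.  The motif reads 5'->3' by residue number.  The result
    does not depend on the order of the contact list.
    """
    contacted = {(c.rna_chain, c.rna_residue_number) for c in contacts}
    sites: list[BindingSite] = []
    for ch in s.chains:
        if ch.polymer_class != "rna":
            continue
        run: list[Residue] = []

        def flush() -> None:
            if len(run) >= min_run:
                sites.append(
                    BindingSite(
                        structure_id=s.structure_id,
                        rna_chain=ch.chain_id,
                        start_residue=run[0].number,
                        end_residue=run[-1].number,
                        motif="".join(r.name for r in run),
                    )
                )

        for res in sorted(ch.residues, key=lambda r: (r.number, r.icode)):
            ok = (
                res.name in _NT
                and not res.icode
                and (ch.chain_id, res.number) in contacted
            )
            if ok and run:
                same_block = (
                    res.number == run[-1].number + 1
                    and res.subchain == run[-1].subchain
                )
                if not same_block:
                    flush()
                    run = []
            if ok:
                run.append(res)
            else:
                flush()
                run = []
        flush()
    return sites


def ungapped_mismatches(motif_a: str, motif_b: str) -> tuple[int, int]:
    """Best ungapped alignment of two motifs: (offset, mismatch count).

    The shorter motif slides along the longer with full overlap; at each
    offset a position mismatches when the two letters' IUPAC member sets
    are disjoint (so R vs A is a match, R vs U is not).  Returns the
    offset of the shorter within the longer minimising mismatches
    (smallest offset on ties) and that minimum.  The mismatch count is
    symmetric in its arguments.
    """
    a = iupac.normalize_motif(motif_a)
    b = iupac.normalize_motif(motif_b)
    if len(a) < 4 or len(b) < 4:
        raise ValueError("motifs must be at least 4 nt for ungapped alignment")
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best_offset, best_mm = 0, len(short) + 1
    for offset in range(len(long_) - len(short) + 1):
        mm = sum(
            1
            for i, ch in enumerate(short)
            if iupac.members(ch).isdisjoint(iupac.members(long_[offset + i]))
        )
        if mm < best_mm:
            best_offset, best_mm = offset, mm
    return best_offset, best_mm


def mismatch_classes(
    pairs: list[tuple[str, str]]
) -> dict[str, int]:
    """Classify motif pairs by minimum ungapped mismatch count.

    Returns counts for the classes 0, 1, 2 and >2 mismatches — the
    validation summary for extracted-vs-reference motif comparisons.
    """
    classes = {"0": 0, "1": 0, "2": 0, ">2": 0}
    for a, b in pairs:
        _, mm = ungapped_mismatches(a, b)
        key = str(mm) if mm <= 2 else ">2"
        classes[key] += 1
    return classes


def write_sites(sites: list[BindingSite], path: str | Path) -> None:
    """Write binding sites as TSV: structure_id, chain, start, end, motif."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("structure_id\tchain\tstart\tend\tmotif\n")
        for s in sites:
            fh.write(
                f"{s.structure_id}\t{s.rna_chain}\t{s.start_residue}\t"
                f"{s.end_residue}\t{s.motif}\n"
            )
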