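"""Binding-site motifs from a protein-RNA complex.

Generates a toy complex with five nucleotides planted within
hydrogen-bond range of the protein, extracts the binding site and
validates the motif against a reference by ungapped alignment.
"""

import tempfile
from pathlib import Path

from rbpkit import (
    call_binding_sites,
    eligible,
    find_contacts,
    parse_structure,
    ungapped_mismatches,
)
from rbpkit.fixtures import PlantedNucleotide, gen_toy_structure

# five contacted nucleotides (O2' within 2.8 A of a protein N), then two far ones
nts = [PlantedNucleotide(b, polar_dist=2.8) for b in "ACGUA"] + [
    PlantedNucleotide("G"),
    PlantedNucleotide("C"),
]
pdb_text, truth = gen_toy_structure(nts, method="X-ray", resolution=2.1)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.pdb"
    path.write_text(pdb_text)
    s = parse_structure(path)

print(f"{s.structure_id}: {s.method} at {s.resolution} A, eligible = {eligible(s)}")
contacts = find_contacts(s)
print(f"{len(contacts)} contacts on residues "
      f"{sorted({c.rna_residue_number for c in contacts})}")

sites = call_binding_sites(contacts, s)
for site in sites:
    print(f"binding site: chain {site.rna_chain} residues "
          f"{site.start_residue}-{site.end_residue}, motif {site.motif}")
# Only the run of >= 4 contiguous contacted nucleotides qualifies; the
# two distant residues contribute no contacts and no site.

offset, mm = ungapped_mismatches(sites[0].motif, "ACGAA")
print(f"vs reference ACGAA: best offset {offset}, {mm} mismatch(es)")
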