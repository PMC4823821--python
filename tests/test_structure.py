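"""Structure parsing, contact detection, binding-site calling, motif validation."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from rbpkit.fixtures import PlantedNucleotide, gen_toy_structure, write_toy_structure
from rbpkit.structure import (
    Structure,
    call_binding_sites,
    eligible,
    find_contacts,
    mismatch_classes,
    parse_structure,
    ungapped_mismatches,
)


def make_structure(tmp_path, nucleotides, **kwargs):
    pdb_text, truth = gen_toy_structure(nucleotides, **kwargs)
    path = tmp_path / "toy.pdb"
    write_toy_structure(pdb_text, path)
    return parse_structure(path), truth


def brute_force_contacts(s: Structure, hbond_cutoff=3.0, vdw_cutoff=3.9):
    """All-pairs distance scan; independent oracle for find_contacts."""
    polar = {"N", "O"}
    protein = [
        (at, ch.chain_id, res.number)
        for ch in s.chains
        if ch.polymer_class == "protein"
        for res in ch.residues
        for at in res.atoms
    ]
    out = set()
    for ch in s.chains:
        if ch.polymer_class != "rna":
            continue
        for res in ch.residues:
            if res.name not in "ACGU" or len(res.name) != 1:
                continue
            for at in res.atoms:
                for pat, _, _ in protein:
                    d = math.dist(at.pos, pat.pos)
                    if d <= vdw_cutoff:
                        out.add((ch.chain_id, res.number, "vdw"))
                    if (
                        d <= hbond_cutoff
                        and at.element in polar
                        and pat.element in polar
                    ):
                        out.add((ch.chain_id, res.number, "hbond"))
    return out


class TestParseStructure:
    def test_chains_classified_from_residue_names(self, tmp_path):
        s, _ = make_structure(
            tmp_path, [PlantedNucleotide(b, polar_dist=2.8) for b in "ACGUAC"]
        )
        classes = {c.chain_id: c.polymer_class for c in s.chains}
        assert classes == {"A": "protein", "B": "rna"}
        assert [r.name for r in s.chains[1].residues] == list("ACGUAC")
        assert not s.rna_absent

    def test_header_fields_read(self, tmp_path):
        s, _ = make_structure(
            tmp_path,
            [PlantedNucleotide("A", polar_dist=2.8)],
            method="X-ray",
            resolution=2.1,
            structure_id="TOY9",
        )
        assert (s.structure_id, s.method, s.resolution) == ("TOY9", "X-ray", 2.1)

    def test_nmr_ensemble_reduced_to_first_model(self, tmp_path):
        s, _ = make_structure(
            tmp_path,
            [PlantedNucleotide("A", polar_dist=2.8)],
            method="NMR",
            resolution=None,
            extra_model=True,
        )
        n_atoms = sum(len(r.atoms) for c in s.chains for r in c.residues)
        assert n_atoms == 4  # one model's worth: 2 protein + 2 RNA atoms

    def test_protein_only_file_flagged_rna_absent(self, tmp_path):
        pdb_text, _ = gen_toy_structure([PlantedNucleotide("A")])
        # keep only the protein chain
        lines = [
            l
            for l in pdb_text.splitlines()
            if not (l.startswith("ATOM") and " B" in l[20:23])
        ]
        path = tmp_path / "protein_only.pdb"
        path.write_text("\n".join(lines) + "\n")
        s = parse_structure(path)
        assert s.rna_absent
        with pytest.raises(ValueError, match="no RNA"):
            find_contacts(s)

    def test_unreadable_file_rejected(self, tmp_path):
        missing = tmp_path / "nope.pdb"
        with pytest.raises((ValueError, FileNotFoundError)):
            parse_structure(missing)


class TestEligibility:
    @pytest.mark.parametrize(
        "method,resolution,expect",
        [
            ("X-ray", 2.1, True),
            ("X-ray", 3.8, True),
            ("X-ray", 3.9, False),  # strictly better than the cutoff
            ("X-ray", 4.1, False),
            ("NMR", None, True),
            ("EM", None, True),
        ],
    )
    def test_method_resolution_rules(self, tmp_path, method, resolution, expect):
        s, _ = make_structure(
            tmp_path,
            [PlantedNucleotide("A", polar_dist=2.8)],
            method=method,
            resolution=resolution,
        )
        assert eligible(s) is expect

    def test_xray_without_resolution_ineligible_with_warning(self, tmp_path, caplog):
        s, _ = make_structure(
            tmp_path,
            [PlantedNucleotide("A", polar_dist=2.8)],
            method="X-ray",
            resolution=None,
        )
        with caplog.at_level("WARNING"):
            assert eligible(s) is False
        assert any("resolution" in m for m in caplog.messages)


class TestFindContacts:
    def test_planted_polar_pair_within_cutoff_gives_hbond_and_vdw(self, tmp_path):
        s, _ = make_structure(tmp_path, [PlantedNucleotide("A", polar_dist=2.9)])
        kinds = {c.kind for c in find_contacts(s)}
        assert kinds == {"hbond", "vdw"}
        hb = next(c for c in find_contacts(s) if c.kind == "hbond")
        assert hb.min_distance == pytest.approx(2.9, abs=1e-6)
        assert (hb.rna_chain, hb.rna_residue_number, hb.nucleotide) == ("B", 1, "A")

    def test_carbon_pair_gives_vdw_only(self, tmp_path):
        s, _ = make_structure(tmp_path, [PlantedNucleotide("C", carbon_dist=3.5)])
        kinds = {c.kind for c in find_contacts(s)}
        assert kinds == {"vdw"}

    def test_pair_beyond_both_cutoffs_gives_nothing(self, tmp_path):
        s, _ = make_structure(tmp_path, [PlantedNucleotide("G", carbon_dist=4.2)])
        assert find_contacts(s) == []

    @pytest.mark.parametrize("d,expect_hbond", [(2.9, True), (3.0, True), (3.1, False)])
    def test_hbond_cutoff_boundary_inclusive(self, tmp_path, d, expect_hbond):
        s, _ = make_structure(tmp_path, [PlantedNucleotide("U", polar_dist=d)])
        has_hbond = any(c.kind == "hbond" for c in find_contacts(s))
        assert has_hbond is expect_hbond

    @pytest.mark.parametrize("d,expect_vdw", [(3.8, True), (3.9, True), (4.0, False)])
    def test_vdw_cutoff_boundary_inclusive(self, tmp_path, d, expect_vdw):
        s, _ = make_structure(tmp_path, [PlantedNucleotide("U", carbon_dist=d)])
        has_vdw = any(c.kind == "vdw" for c in find_contacts(s))
        assert has_vdw is expect_vdw

    def test_agrees_with_all_pairs_brute_force(self, tmp_path):
        """Vectorised contact detection must equal the all-pairs oracle."""
        cases = [
            [PlantedNucleotide(b, polar_dist=pd, carbon_dist=cd)
             for b, pd, cd in zip("ACGUACGU", pds, cds)]
            for pds, cds in [
                ([2.5, 2.9, 3.0, 3.1, 3.5, None, 2.0, None],
                 [None, 3.5, None, 3.8, 3.9, 4.0, None, 3.4]),
                ([None] * 8, [3.4, 3.5, 3.6, 3.7, 3.8, 3.9, 4.0, 4.1]),
            ]
        ]
        for nts in cases:
            s, _ = make_structure(tmp_path, nts)
            got = {
                (c.rna_chain, c.rna_residue_number, c.kind)
                for c in find_contacts(s)
            }
            assert got == brute_force_contacts(s)

    def test_shrinking_vdw_cutoff_never_adds_contacts(self, tmp_path):
        nts = [
            PlantedNucleotide("A", carbon_dist=d)
            for d in (3.2, 3.5, 3.8, 4.1, 4.4)
        ]
        s, _ = make_structure(tmp_path, nts)
        counts = [
            len([c for c in find_contacts(s, vdw_cutoff=v) if c.kind == "vdw"])
            for v in (4.5, 4.0, 3.9, 3.6, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCallBindingSites:
    def test_five_contacted_nucleotides_give_one_site(self, tmp_path):
        s, truth = make_structure(
            tmp_path, [PlantedNucleotide(b, polar_dist=2.8) for b in "ACGUA"]
        )
        sites = call_binding_sites(find_contacts(s), s)
        assert [(x.start_residue, x.end_residue, x.motif) for x in sites] == [
            (1, 5, "ACGUA")
        ]
        assert truth.sites == [(1, 5, "ACGUA")]

    def test_three_contacted_nucleotides_give_no_site(self, tmp_path):
        s, _ = make_structure(
            tmp_path, [PlantedNucleotide(b, polar_dist=2.8) for b in "ACG"]
        )
        assert call_binding_sites(find_contacts(s), s) == []

    def test_gap_splits_runs_into_two_sites(self, tmp_path):
        nts = (
            [PlantedNucleotide(b, polar_dist=2.8) for b in "ACGU"]
            + [PlantedNucleotide("A")]  # uncontacted spacer
            + [PlantedNucleotide(b, polar_dist=2.8) for b in "GUACGU"]
        )
        s, _ = make_structure(tmp_path, nts)
        sites = call_binding_sites(find_contacts(s), s)
        assert [(x.start_residue, x.end_residue, x.motif) for x in sites] == [
            (1, 4, "ACGU"),
            (6, 11, "GUACGU"),
        ]

    def test_result_independent_of_contact_order(self, tmp_path):
        s, _ = make_structure(
            tmp_path, [PlantedNucleotide(b, polar_dist=2.8) for b in "ACGUAC"]
        )
        contacts = find_contacts(s)
        assert call_binding_sites(list(reversed(contacts)), s) == call_binding_sites(
            contacts, s
        )

    @pytest.mark.parametrize("run_len", range(1, 9))
    def test_min_run_threshold_exact(self, tmp_path, run_len):
        """Sites appear exactly for contacted runs of four or more."""
        nts = [PlantedNucleotide("A", polar_dist=2.8) for _ in range(run_len)]
        s, _ = make_structure(tmp_path, nts)
        sites = call_binding_sites(find_contacts(s), s)
        if run_len >= 4:
            assert [x.motif for x in sites] == ["A" * run_len]
        else:
            assert sites == []


class TestUngappedMismatches:
    def test_identical_motifs(self):
        assert ungapped_mismatches("ACGU", "ACGU") == (0, 0)

    def test_single_nucleotide_difference(self):
        assert ungapped_mismatches("ACGU", "ACGA") == (0, 1)

    def test_shorter_slides_to_best_offset(self):
        assert ungapped_mismatches("ACGU", "UACGU") == (1, 0)

    def test_iupac_member_overlap_is_a_match(self):
        assert ungapped_mismatches("RCGU", "ACGU") == (0, 0)
        assert ungapped_mismatches("YCGU", "ACGU") == (0, 1)  # Y={C,U} vs A disjoint

    def test_mismatch_count_symmetric(self):
        for a, b in [("ACGU", "UGCA"), ("ACGUA", "CGU" + "A" * 3), ("GGGG", "CCCCGG")]:
            assert ungapped_mismatches(a, b)[1] == ungapped_mismatches(b, a)[1]

    def test_too_short_motifs_rejected(self):
        with pytest.raises(ValueError):
            ungapped_mismatches("ACG", "ACGU")

    def test_mismatch_class_summary(self):
        pairs = [
            ("ACGU", "ACGU"),  # 0
            ("ACGU", "ACGA"),  # 1
            ("ACGU", "AAAU"),  # 2
            ("ACGU", "UGCA"),  # >2 at every offset
        ]
        assert mismatch_classes(pairs) == {"0": 1, "1": 1, "2": 1, ">2": 1}
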