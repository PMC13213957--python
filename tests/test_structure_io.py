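"""Parsing, ligand flagging, covalency, contact labeling, pLDDT filtering, reports."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from carbsite.structure_io import (
    ConfigurationError,
    EmptyStructureError,
    StructureError,
    detect_covalent_attachment,
    filter_by_plddt,
    identify_carbohydrate_ligands,
    label_binding_residues,
    load_sugar_config,
    parse_structure,
    write_predictions,
)
from carbsite.synthetic import SyntheticSpec, generate_toy_protein, write_toy_pdb

from conftest import make_structure


class TestParsing:
    def test_toy_pdb_counts_and_glycine_rule(self, tmp_path):
        """A 3-residue ALA-GLY-SER + GLC file yields 3 records, 1 ligand, GLY cb==ca."""
        text = "\n".join([
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C",
            "ATOM      2  CB  ALA A   1       0.000   1.500   0.000  1.00 10.00           C",
            "ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00 10.00           C",
            "ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00 10.00           C",
            "ATOM      5  CB  SER A   3       7.600   1.500   0.000  1.00 10.00           C",
            "HETATM    6  C1  GLC A 101      10.000   3.000   0.000  1.00 20.00           C",
            "HETATM    7  O1  GLC A 101      10.000   3.000   1.400  1.00 20.00           O",
            "HETATM    8  O   HOH A 201      20.000  20.000  20.000  1.00 30.00           O",
            "END",
        ])
        p = tmp_path / "toy.pdb"
        p.write_text(text + "\n")
        s = parse_structure(p)
        assert [r.resname for r in s.residues] == ["ALA", "GLY", "SER"]
        assert len(s.ligands) == 1 and s.ligands[0].resname == "GLC"
        gly = s.residues[1]
        assert np.array_equal(gly.cb, gly.ca)
        assert [r.seq_index for r in s.residues] == [0, 1, 2]

    def test_missing_file_and_garbage(self, tmp_path):
        with pytest.raises(StructureError):
            parse_structure(tmp_path / "nope.pdb")
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(StructureError):
            parse_structure(bad, format="mmcif")

    def test_zero_residue_structure_errors(self, tmp_path):
        p = tmp_path / "het_only.pdb"
        p.write_text(
            "HETATM    1  C1  GLC A 101      10.000   3.000   0.000  1.00 20.00           C\n"
            "HETATM    2  O1  GLC A 101      10.000   3.000   1.400  1.00 20.00           O\nEND\n"
        )
        with pytest.raises(EmptyStructureError):
            parse_structure(p)

    def test_pdb_mmcif_round_trip_agreement(self, tmp_path, toy_binder):
        """The same coordinates written as PDB and mmCIF parse identically to 1e-3 Å."""
        import biotite.structure.io.pdb as bpdb
        import biotite.structure.io.pdbx as bpdbx

        pdb_path = tmp_path / "x.pdb"
        write_toy_pdb(toy_binder, pdb_path)
        arr = bpdb.get_structure(bpdb.PDBFile.read(str(pdb_path)), model=1)
        cif = bpdbx.CIFFile()
        bpdbx.set_structure(cif, arr)
        cif_path = tmp_path / "x.cif"
        cif.write(str(cif_path))

        s_pdb = parse_structure(pdb_path)
        s_cif = parse_structure(cif_path)
        assert len(s_pdb.residues) == len(s_cif.residues)
        for a, b in zip(s_pdb.residues, s_cif.residues):
            assert a.resname == b.resname and a.chain_id == b.chain_id
            assert np.allclose(a.ca, b.ca, atol=1e-3)
            assert np.allclose(a.cb, b.cb, atol=1e-3)
        assert len(s_pdb.ligands) == len(s_cif.ligands) == 1

    def test_plddt_read_from_bfactor_for_predicted(self, tmp_path):
        lp = generate_toy_protein(
            SyntheticSpec(n_proteins=1, seed=5, plddt_range=(60.0, 95.0)), 0
        )
        path = tmp_path / "pred.pdb"
        write_toy_pdb(lp, path)
        s = parse_structure(path, source="predicted")
        ref = [r.plddt for r in lp.structure.residues]
        got = [r.plddt for r in s.residues]
        assert np.allclose(got, ref, atol=0.01)
        crystal = parse_structure(path, source="crystal")
        assert all(r.plddt is None for r in crystal.residues)


class TestLigandFlags:
    def test_sugar_vocabulary_membership(self):
        s = make_structure(ligand_offset=[0, 3.0, 0], ligand_resname="GLC")
        s.ligands.append(make_structure(ligand_offset=[0, 3.0, 0], ligand_resname="ATP").ligands[0])
        identify_carbohydrate_ligands(s)
        flags = [l.is_carbohydrate for l in s.ligands]
        assert flags == [True, False]

    def test_empty_sugar_set_is_a_configuration_error(self):
        s = make_structure(ligand_offset=[0, 3.0, 0])
        with pytest.raises(ConfigurationError):
            identify_carbohydrate_ligands(s, sugar_codes=set())

    def test_user_config_roundtrip(self, tmp_path):
        cfg_path = tmp_path / "sugars.yaml"
        cfg_path.write_text("sugar_codes: [ZZZ]\ncontact_cutoff: 5.0\n")
        cfg = load_sugar_config(cfg_path)
        assert cfg["sugar_codes"] == frozenset({"ZZZ"})
        assert cfg["contact_cutoff"] == 5.0
        assert cfg["covalent_cutoff"] == 1.8  # packaged default backstop


class TestCovalency:
    @pytest.mark.parametrize("dy,expected", [(1.4, True), (3.0, False)])
    def test_bond_cutoff(self, dy, expected):
        s = make_structure(ligand_offset=[0.0, dy, 0.0])
        assert detect_covalent_attachment(s.ligands[0], s.residues) is expected

    def test_covalent_glycan_contributes_no_labels(self):
        """An N-glycan-like ligand 1.4 Å from the protein yields all-zero labels."""
        s = make_structure(n=6, ligand_offset=[0.0, 1.4, 0.0])
        identify_carbohydrate_ligands(s)
        labeled = label_binding_residues(s)
        assert labeled.residue_labels.sum() == 0
        assert labeled.protein_label == 0


class TestLabeling:
    @pytest.mark.parametrize("dy,want", [(4.0, 1), (4.3, 0)])
    def test_cutoff_inclusivity(self, dy, want):
        s = make_structure(ligand_offset=[0.0, dy, 0.0])
        identify_carbohydrate_ligands(s)
        assert label_binding_residues(s).residue_labels[0] == want

    def test_matches_brute_force_all_pairs(self):
        """Labels equal an independent O(N·M) double-loop scan on random fixtures."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            s = make_structure(n=30)
            for r in s.residues:
                jitter = rng.normal(scale=2.0, size=3)
                r.ca += jitter
                r.cb += jitter
                r.heavy_atoms = [("CA", r.ca), ("CB", r.cb)]
            lig_xyz = rng.uniform(-5, 120, size=(4, 3))
            s.ligands = [
                __import__("carbsite.structure_io", fromlist=["LigandGroup"]).LigandGroup(
                    resname="GLC", atoms=[("C", x) for x in lig_xyz]
                )
            ]
            identify_carbohydrate_ligands(s)
            got = label_binding_residues(s).residue_labels
            lig = s.ligands[0]
            if lig.is_covalent:
                expect = np.zeros(len(s.residues), dtype=int)
            else:
                expect = np.array([
                    int(
                        min(
                            float(cdist(np.array([a]), lig_xyz).min())
                            for _, a in r.heavy_atoms
                        )
                        <= 4.2
                    )
                    for r in s.residues
                ])
            assert np.array_equal(got, expect)

    def test_protein_label_iff_noncovalent_carb(self):
        near = make_structure(ligand_offset=[0.0, 4.0, 0.0])
        identify_carbohydrate_ligands(near)
        assert label_binding_residues(near).protein_label == 1
        none = make_structure()
        assert label_binding_residues(none).protein_label == 0


class TestPlddtFilter:
    def test_strict_inequality_and_reindexing(self):
        s = make_structure(n=3, source="predicted", plddt=[60.0, 75.0, 95.0])
        out = filter_by_plddt(s, 70.0)
        assert [r.plddt for r in out.residues] == [75.0, 95.0]
        assert [r.seq_index for r in out.residues] == [0, 1]
        boundary = filter_by_plddt(
            make_structure(n=2, source="predicted", plddt=[70.0, 71.0]), 70.0
        )
        assert len(boundary.residues) == 1  # 70.0 is not > 70.0

    def test_no_op_on_crystal_with_warning(self):
        s = make_structure(n=3)
        with pytest.warns(UserWarning):
            out = filter_by_plddt(s, 70.0)
        assert out is s

    def test_all_filtered_raises(self):
        s = make_structure(n=2, source="predicted", plddt=[50.0, 60.0])
        with pytest.raises(EmptyStructureError):
            filter_by_plddt(s, 70.0)

    def test_structure_gate_uses_min_retained(self):
        from carbsite.structure_io import min_retained_plddt

        s = make_structure(n=3, source="predicted", plddt=[82.0, 91.0, 85.5])
        assert min_retained_plddt(s) == 82.0  # passes the >80 augmentation gate
        low = make_structure(n=2, source="predicted", plddt=[79.0, 95.0])
        assert min_retained_plddt(low) <= 80.0

    def test_monotone_in_cutoff(self):
        s = make_structure(n=10, source="predicted",
                           plddt=list(np.linspace(50, 99, 10)))
        counts = []
        for cut in (50, 60, 70, 80, 90, 99):
            try:
                counts.append(len(filter_by_plddt(s, cut).residues))
            except EmptyStructureError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)


class TestReports:
    def test_threshold_calls_and_round_trip(self, tmp_path):
        s = make_structure(n=3)
        probs = np.array([0.95, 0.85, 0.10])
        tsv, csv_p = write_predictions(s, probs, 0.95, tmp_path / "out", threshold=0.9)
        lines = tsv.read_text().splitlines()
        calls = [int(l.split("\t")[-1]) for l in lines[1:]]
        assert calls == [1, 0, 0]  # 0.95>=0.9 -> 1; 0.85 -> 0
        got = [float(l.split("\t")[3]) for l in lines[1:]]
        assert got == [round(p, 6) for p in probs]
        again = write_predictions(s, probs, 0.95, tmp_path / "out2", threshold=0.9)
        assert again[0].read_text().split("\n", 1)[1] == tsv.read_text().split("\n", 1)[1]

    def test_rejects_out_of_range_probabilities(self, tmp_path):
        s = make_structure(n=2)
        with pytest.raises(ValueError):
            write_predictions(s, np.array([0.5, 1.5]), 0.5, tmp_path / "bad")
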