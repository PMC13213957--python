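"""Shared fixtures: tiny hand-built structures and synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from carbsite.embeddings import StubEmbedder
from carbsite.models import ModelConfig
from carbsite.structure_io import LigandGroup, ProteinStructure, ResidueRecord
from carbsite.synthetic import SyntheticSpec, generate_toy_protein, write_toy_pdb


def make_residue(i, resname="ALA", chain="A", ca=None, cb=None, plddt=None):
    ca = np.asarray(ca if ca is not None else [3.8 * i, 0.0, 0.0], dtype=float)
    if resname == "GLY":
        cb = ca.copy()
    else:
        cb = np.asarray(cb if cb is not None else ca + [0.0, 1.5, 0.0], dtype=float)
    heavy = [("CA", ca)] if resname == "GLY" else [("CA", ca), ("CB", cb)]
    return ResidueRecord(
        chain_id=chain, author_number=i + 1, seq_index=i, resname=resname,
        ca=ca, cb=cb, heavy_atoms=heavy, plddt=plddt,
    )


def make_structure(n=5, ligand_offset=None, ligand_resname="GLC", source="crystal",
                   plddt=None, sid="toy"):
    """n residues on a line; optional one-atom ligand near residue 0."""
    residues = [
        make_residue(i, plddt=None if plddt is None else plddt[i]) for i in range(n)
    ]
    ligands = []
    if ligand_offset is not None:
        pos = residues[0].cb + np.asarray(ligand_offset, dtype=float)
        ligands = [LigandGroup(resname=ligand_resname, atoms=[("C", pos), ("O", pos + [0.0, 0.0, 1.4])])]
    return ProteinStructure(id=sid, residues=residues, ligands=ligands, source=source)


@pytest.fixture(scope="session")
def toy_spec():
    return SyntheticSpec(n_proteins=12, length_range=(30, 60), seed=7,
                         binder_fraction=0.5, signal_strength=3.0)


@pytest.fixture(scope="session")
def toy_binder(toy_spec):
    """First guaranteed binder of the session corpus."""
    for i in range(toy_spec.n_proteins):
        lp = generate_toy_protein(toy_spec, i)
        if lp.protein_label == 1:
            return lp
    raise RuntimeError("no binder in toy corpus")


@pytest.fixture(scope="session")
def toy_pdb_file(tmp_path_factory, toy_binder):
    path = tmp_path_factory.mktemp("pdb") / f"{toy_binder.structure.id}.pdb"
    write_toy_pdb(toy_binder, path)
    return path


@pytest.fixture(scope="session")
def stub_embedder():
    return StubEmbedder(dim=32, seed=3, signal_strength=3.0)


@pytest.fixture(scope="session")
def tiny_config():
    """Tiny-but-complete model configuration used across model/training tests."""
    return ModelConfig(
        n_layers=4, embed_dim=16, input_dim=32, msg_hidden=32, upd_hidden=32,
        decoder_hidden=16, picap_k_schedule=(10, 20, 40, 60),
        conv_channels=(2, 2), dense_widths=(8, 8),
    )
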