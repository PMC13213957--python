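"""Desk-scale synthetic structures with planted, labeler-derived binding sites.

Proteins are ideal helices (rise 1.5 Å, radius 2.3 Å, 100° per residue) with
Cβ pseudo-atoms offset 1.5 Å radially outward.  For binders, a cluster of
carbohydrate-like ligand atoms (HET code GLC, so the default sugar
vocabulary flags it) is planted radially outside a contiguous pocket of
residues: each pocket residue's nearest ligand atom sits within the
requested contact radius, while the helix geometry keeps every other
residue beyond the 4.2 Å labeling shell.  Labels are *always* produced by
running the production contact labeler on the constructed structure — never
set directly — so fixtures and labeler cannot drift apart.

None of this is physically realistic (no rotamers, no real glycan
geometry); it exists to make every pipeline stage testable without
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as _pdb

from .data import DatasetEntry, write_manifest
from .embeddings import StubEmbedder
from .graph import EdgeFeatureConfig, ResidueGraph, build_residue_graph
from .structure_io import (
    LabeledProtein,
    LigandGroup,
    ProteinStructure,
    ResidueRecord,
    identify_carbohydrate_ligands,
    label_binding_residues,
)

__all__ = [
    "SyntheticSpec",
    "GenerationError",
    "generate_toy_protein",
    "generate_dataset",
    "make_sequence_families",
    "featurize",
    "write_toy_pdb",
]

_AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_LETTERS = "".join(_AA1TO3)

RISE = 1.5       # Å per residue along the helix axis
RADIUS = 2.3     # Å helix radius (Cα)
TURN = np.deg2rad(100.0)
CB_OFFSET = 1.5  # Å radial Cβ offset


class GenerationError(RuntimeError):
    """Geometric placement failed to satisfy the labeling guarantees."""


@dataclass(frozen=True)
class SyntheticSpec:
    """The stated world of the synthetic corpus."""

    n_proteins: int = 50
    length_range: tuple[int, int] = (30, 120)
    pocket_size: int = 5
    ligand_atoms: int = 8
    contact_radius: float = 3.5
    binder_fraction: float = 0.5
    signal_strength: float = 3.0
    seed: int = 0
    n_chains: int = 1
    plddt_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.pocket_size < 1:
            raise ValueError("pocket_size must be >= 1")
        if not self.contact_radius < 4.2:
            raise ValueError("contact_radius must stay inside the 4.2 Å shell")


def _helix_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(n)
    ang = i * TURN
    ca = np.stack([RADIUS * np.cos(ang), RADIUS * np.sin(ang), i * RISE], axis=1)
    radial = np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=1)
    cb = ca + CB_OFFSET * radial
    return ca, cb


def generate_toy_protein(spec: SyntheticSpec, index: int) -> LabeledProtein:
    """Deterministic toy protein ``index`` of the corpus described by ``spec``.

    Binder/nonbinder status is a Bernoulli(``binder_fraction``) draw from the
    (seed, index)-keyed generator; the returned labels come from the
    production labeler run on the constructed coordinates.
    """
    rng = np.random.default_rng([spec.seed, index])
    n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    letters = rng.choice(list(_LETTERS), size=n)
    is_binder = rng.random() < spec.binder_fraction
    ca, cb = _helix_coords(n)
    ang = np.arange(n) * TURN
    radial = np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=1)

    residues = []
    chain_bounds = np.array_split(np.arange(n), max(spec.n_chains, 1))
    chain_of = np.empty(n, dtype=int)
    number_of = np.empty(n, dtype=int)
    for ci, idxs in enumerate(chain_bounds):
        chain_of[idxs] = ci
        number_of[idxs] = np.arange(1, len(idxs) + 1)
    for i in range(n):
        resname = _AA1TO3[letters[i]]
        gly = resname == "GLY"
        plddt = None
        if spec.plddt_range is not None:
            lo, hi = spec.plddt_range
            plddt = float(lo + (hi - lo) * rng.random())
        residues.append(
            ResidueRecord(
                chain_id=chr(ord("A") + int(chain_of[i])),
                author_number=int(number_of[i]),
                seq_index=i,
                resname=resname,
                ca=ca[i],
                cb=ca[i].copy() if gly else cb[i],
                heavy_atoms=[("CA", ca[i])] if gly else [("CA", ca[i]), ("CB", cb[i])],
                plddt=plddt,
            )
        )

    ligands = []
    pocket = np.zeros(n, dtype=bool)
    if is_binder:
        start = int(rng.integers(0, n - spec.pocket_size + 1))
        pocket[start : start + spec.pocket_size] = True
        atoms = []
        for j in np.flatnonzero(pocket):
            d = spec.contact_radius * (0.7 + 0.3 * rng.random())
            base = cb[j] if residues[j].resname != "GLY" else ca[j]
            atoms.append(("C", base + d * radial[j]))
        extra = spec.ligand_atoms - len(atoms)
        center = int(np.flatnonzero(pocket).mean())
        for e in range(max(extra, 0)):
            far = 5.5 + 0.8 * rng.random()
            atoms.append(("O", cb[center] + far * radial[center] + np.array([0, 0, e * 0.5])))
        ligands.append(LigandGroup(resname="GLC", atoms=atoms, chain_id="X"))

    structure = ProteinStructure(
        id=f"toy{index:04d}",
        residues=residues,
        ligands=ligands,
        source="predicted" if spec.plddt_range is not None else "crystal",
    )
    identify_carbohydrate_ligands(structure)
    labeled = label_binding_residues(structure)
    if is_binder and not np.array_equal(labeled.residue_labels.astype(bool), pocket):
        raise GenerationError(
            f"toy{index}: planted pocket disagrees with the labeler "
            f"({labeled.residue_labels.sum()} labels vs pocket {pocket.sum()})"
        )
    if not is_binder and labeled.protein_label != 0:
        raise GenerationError(f"toy{index}: nonbinder acquired a label")
    return labeled


def write_toy_pdb(labeled: LabeledProtein, path: str | Path) -> Path:
    """Serialize a toy protein (with its ligand) as a PDB file."""
    s = labeled.structure
    n_atoms = sum(len(r.heavy_atoms) for r in s.residues) + sum(
        len(l.atoms) for l in s.ligands
    )
    arr = bst.AtomArray(n_atoms)
    pos = 0
    for r in s.residues:
        for name, xyz in r.heavy_atoms:
            arr.chain_id[pos] = r.chain_id
            arr.res_id[pos] = r.author_number
            arr.res_name[pos] = r.resname
            arr.atom_name[pos] = name
            arr.element[pos] = name[0]
            arr.hetero[pos] = False
            arr.coord[pos] = xyz
            pos += 1
    for lig in s.ligands:
        for ai, (elem, xyz) in enumerate(lig.atoms):
            arr.chain_id[pos] = lig.chain_id
            arr.res_id[pos] = 900
            arr.res_name[pos] = lig.resname
            arr.atom_name[pos] = f"{elem}{ai + 1}"
            arr.element[pos] = elem
            arr.hetero[pos] = True
            arr.coord[pos] = xyz
            pos += 1
    arr.set_annotation(
        "b_factor",
        np.array(
            [r.plddt if r.plddt is not None else 0.0 for r in s.residues for _ in r.heavy_atoms]
            + [0.0] * sum(len(l.atoms) for l in s.ligands)
        ),
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    f = _pdb.PDBFile()
    _pdb.set_structure(f, arr)
    f.write(str(path))
    return path


def generate_dataset(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[list[LabeledProtein], list[DatasetEntry]]:
    """Generate the full corpus; optionally write PDBs and a manifest CSV."""
    proteins = [generate_toy_protein(spec, i) for i in range(spec.n_proteins)]
    entries = []
    for lp in proteins:
        s = lp.structure
        pdb_path = ""
        if out_dir is not None:
            pdb_path = str(write_toy_pdb(lp, Path(out_dir) / f"{s.id}.pdb"))
        entries.append(
            DatasetEntry(
                id=s.id,
                sequence=s.sequence,
                binder_class="carb_binder" if lp.protein_label else "putative_nonbinder",
                crystal_path=pdb_path or None,
                has_bound_carb=bool(lp.protein_label),
                has_noncovalent_carb_ligand=bool(lp.protein_label),
                source_dataset="synthetic",
            )
        )
    if out_dir is not None:
        write_manifest(entries, Path(out_dir) / "manifest.csv")
    return proteins, entries


def make_sequence_families(
    n_families: int, copies: int, within_identity: float = 0.9, seed: int = 0,
    length: int = 50,
) -> dict[str, str]:
    """Synthetic sequence families for exercising identity clustering.

    Each family draws its letters from its own random 6-letter sub-alphabet,
    which keeps cross-family identity far below 0.3.  Copy 0 is the parent
    itself; every later copy is the parent with a ``1 - within_identity``
    fraction of positions substituted inside the sub-alphabet, so identity
    to the family parent equals the target (copy-to-copy identity is lower,
    roughly ``2*within_identity - 1``, still above a 0.6 threshold for the
    defaults).
    """
    if not 0.6 < within_identity <= 1:
        raise ValueError("within_identity must be in (0.6, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for f in range(n_families):
        sub = rng.choice(list(_LETTERS), size=6, replace=False)
        parent = rng.choice(sub, size=length)
        for c in range(copies):
            seq = parent.copy()
            n_mut = 0 if c == 0 else round((1 - within_identity) * length)
            sites = rng.choice(length, size=n_mut, replace=False)
            for s in sites:
                choices = [x for x in sub if x != seq[s]]
                seq[s] = choices[rng.integers(len(choices))]
            out[f"fam{f:02d}_c{c:02d}"] = "".join(seq)
    return out


def featurize(
    labeled: LabeledProtein | ProteinStructure,
    embedder: StubEmbedder,
    k_values: tuple[int, ...] = (16,),
    with_signal: bool = False,
    edge_config: EdgeFeatureConfig = EdgeFeatureConfig(),
) -> ResidueGraph:
    """Embed a protein and build its residue graph.

    With ``with_signal`` (training on the planted-signal world), the stub
    embedder receives the binding labels so channel 0 carries the signal;
    at prediction time labels are unknown and no signal is injected.
    """
    if isinstance(labeled, LabeledProtein):
        structure = labeled.structure
        labels = labeled.residue_labels if with_signal else None
    else:
        structure = labeled
        labels = None
    feats = embedder.embed(structure.sequence, signal_labels=labels)
    return build_residue_graph(
        structure.cb_coords(), feats, k_values=k_values, config=edge_config
    )
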