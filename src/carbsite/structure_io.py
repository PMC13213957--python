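"""Structure parsing, ligand classification, contact labeling and report output.

Proteins enter as PDB or mmCIF files.  Every standard amino-acid residue
becomes a :class:`ResidueRecord` carrying its Cα and Cβ coordinates (Cβ falls
back to Cα for glycine or when the atom is missing) and, for predicted
structures, the per-residue confidence (pLDDT) stored in the B-factor column.
HETATM residue groups become :class:`LigandGroup` objects; waters and
monoatomic ions are dropped entirely.

Binding labels follow the contact rule used throughout the package: a residue
is a binding residue iff any of its heavy atoms lies within ``contact_cutoff``
(default 4.2 Å) of any atom of a *noncovalently* bound carbohydrate ligand.
Covalent attachment (e.g. N-linked glycans) is detected by a ligand atom
closer than ``covalent_cutoff`` (default 1.8 Å) to any protein heavy atom;
such ligands never contribute labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from biotite.structure import AtomArray
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx
from scipy.spatial.distance import cdist

__all__ = [
    "ResidueRecord",
    "LigandGroup",
    "ProteinStructure",
    "LabeledProtein",
    "StructureError",
    "EmptyStructureError",
    "ConfigurationError",
    "load_sugar_config",
    "DEFAULT_SUGAR_CODES",
    "CONTACT_CUTOFF",
    "COVALENT_CUTOFF",
    "parse_structure",
    "identify_carbohydrate_ligands",
    "detect_covalent_attachment",
    "label_binding_residues",
    "filter_by_plddt",
    "write_predictions",
]


class StructureError(ValueError):
    """Problem with a structure file or its contents."""


class EmptyStructureError(StructureError):
    """A structure (or filter result) contains no standard residues."""


class ConfigurationError(ValueError):
    """Invalid configuration (e.g. an empty sugar-code vocabulary)."""


_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


def load_sugar_config(path: str | Path | None = None) -> dict:
    """Load the sugar-code vocabulary and distance cutoffs.

    Without a path, the packaged default configuration is used.  A user file
    must provide a non-empty ``sugar_codes`` list; missing cutoffs fall back
    to the packaged defaults.
    """
    if path is None:
        text = resources.files("carbsite.assets").joinpath("sugar_codes.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    codes = cfg.get("sugar_codes")
    if not codes:
        raise ConfigurationError("sugar_codes list is empty or missing")
    return {
        "sugar_codes": frozenset(str(c).upper() for c in codes),
        "contact_cutoff": float(cfg.get("contact_cutoff", 4.2)),
        "covalent_cutoff": float(cfg.get("covalent_cutoff", 1.8)),
    }


_DEFAULT_CFG = load_sugar_config()
DEFAULT_SUGAR_CODES: frozenset[str] = _DEFAULT_CFG["sugar_codes"]
CONTACT_CUTOFF: float = _DEFAULT_CFG["contact_cutoff"]
COVALENT_CUTOFF: float = _DEFAULT_CFG["covalent_cutoff"]


@dataclass
class ResidueRecord:
    """One standard amino-acid residue of a parsed structure."""

    chain_id: str
    author_number: int
    seq_index: int
    resname: str
    ca: np.ndarray
    cb: np.ndarray
    heavy_atoms: list[tuple[str, np.ndarray]]
    plddt: float | None = None

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.resname, "X")

    def heavy_coords(self) -> np.ndarray:
        return np.asarray([xyz for _, xyz in self.heavy_atoms], dtype=float)


@dataclass
class LigandGroup:
    """A HETATM residue group (waters and monoatomic ions excluded)."""

    resname: str
    atoms: list[tuple[str, np.ndarray]]
    chain_id: str = ""
    is_carbohydrate: bool = False
    is_covalent: bool | None = None

    def coords(self) -> np.ndarray:
        return np.asarray([xyz for _, xyz in self.atoms], dtype=float)


@dataclass
class ProteinStructure:
    """An ordered residue list plus its ligand groups."""

    id: str
    residues: list[ResidueRecord]
    ligands: list[LigandGroup] = field(default_factory=list)
    source: str = "crystal"  # {crystal, predicted}

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def cb_coords(self) -> np.ndarray:
        return np.asarray([r.cb for r in self.residues], dtype=float)


@dataclass
class LabeledProtein:
    """A structure with derived per-residue and protein-level binding labels."""

    structure: ProteinStructure
    residue_labels: np.ndarray
    protein_label: int

    def __post_init__(self) -> None:
        self.residue_labels = np.asarray(self.residue_labels, dtype=int)
        if len(self.residue_labels) != len(self.structure.residues):
            raise ValueError("residue_labels length mismatch")


def _atom_array_from_file(path: Path, format: str) -> AtomArray:
    if format == "pdb":
        f = _pdb.PDBFile.read(str(path))
        return _pdb.get_structure(f, model=1, altloc="first", extra_fields=["b_factor"])
    f = _pdbx.CIFFile.read(str(path))
    return _pdbx.get_structure(f, model=1, altloc="first", extra_fields=["b_factor"])


def parse_structure(
    path: str | Path,
    format: str = "auto",
    source: str = "crystal",
    structure_id: str | None = None,
) -> ProteinStructure:
    """Parse a PDB/mmCIF file into a :class:`ProteinStructure`.

    Model 1 and first-altloc atoms only.  When ``source == "predicted"`` the
    B-factor column is interpreted as pLDDT and copied onto each residue.
    Raises :class:`EmptyStructureError` if no standard residue with a Cα
    survives, and :class:`StructureError` on unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        atoms = _atom_array_from_file(path, format)
    except Exception as exc:  # biotite raises several parse-error types
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc

    is_protein = ~atoms.hetero & np.isin(atoms.res_name, sorted(_AA3))
    residues: list[ResidueRecord] = []
    prot = atoms[is_protein]
    if prot.array_length() > 0:
        # group in file order by (chain, residue number, insertion code)
        keys = list(zip(prot.chain_id, prot.res_id, prot.ins_code))
        boundaries = [0] + [i for i in range(1, len(keys)) if keys[i] != keys[i - 1]] + [len(keys)]
        seq_index = 0
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            grp = prot[a:b]
            names = list(grp.atom_name)
            if "CA" not in names:
                continue
            heavy = [
                (str(n), np.array(c, dtype=float))
                for n, c, e in zip(grp.atom_name, grp.coord, grp.element)
                if e not in ("H", "D")
            ]
            if not heavy:
                continue
            ca = np.array(grp.coord[names.index("CA")], dtype=float)
            resname = str(grp.res_name[0])
            if resname == "GLY" or "CB" not in names:
                cb = ca.copy()
            else:
                cb = np.array(grp.coord[names.index("CB")], dtype=float)
            plddt = float(grp.b_factor[names.index("CA")]) if source == "predicted" else None
            residues.append(
                ResidueRecord(
                    chain_id=str(grp.chain_id[0]),
                    author_number=int(grp.res_id[0]),
                    seq_index=seq_index,
                    resname=resname,
                    ca=ca,
                    cb=cb,
                    heavy_atoms=heavy,
                    plddt=plddt,
                )
            )
            seq_index += 1
    if not residues:
        raise EmptyStructureError(f"{path} contains no standard amino-acid residues")

    ligands: list[LigandGroup] = []
    het = atoms[atoms.hetero & ~np.isin(atoms.res_name, sorted(_WATER_NAMES))]
    if het.array_length() > 0:
        keys = list(zip(het.chain_id, het.res_id, het.res_name))
        boundaries = [0] + [i for i in range(1, len(keys)) if keys[i] != keys[i - 1]] + [len(keys)]
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            grp = het[a:b]
            if grp.array_length() < 2:
                continue  # monoatomic ions are not ligands here
            ligands.append(
                LigandGroup(
                    resname=str(grp.res_name[0]),
                    atoms=[
                        (str(e), np.array(c, dtype=float))
                        for e, c in zip(grp.element, grp.coord)
                    ],
                    chain_id=str(grp.chain_id[0]),
                )
            )
    return ProteinStructure(
        id=structure_id or path.stem, residues=residues, ligands=ligands, source=source
    )


def identify_carbohydrate_ligands(
    structure: ProteinStructure, sugar_codes: frozenset[str] | set[str] = DEFAULT_SUGAR_CODES
) -> ProteinStructure:
    """Flag every ligand group whose HET code is in the sugar vocabulary."""
    if not sugar_codes:
        raise ConfigurationError(
            "empty sugar-code set: refusing to silently flag all ligands negative"
        )
    codes = {c.upper() for c in sugar_codes}
    for lig in structure.ligands:
        lig.is_carbohydrate = lig.resname.upper() in codes
    return structure


def detect_covalent_attachment(
    ligand: LigandGroup,
    residues: list[ResidueRecord],
    bond_cutoff: float = COVALENT_CUTOFF,
) -> bool:
    """True iff any ligand atom is within ``bond_cutoff`` of a protein heavy atom."""
    if bond_cutoff <= 0:
        raise ValueError("bond_cutoff must be positive")
    lig_xyz = ligand.coords()
    for res in residues:
        if cdist(res.heavy_coords(), lig_xyz).min() <= bond_cutoff:
            return True
    return False


def label_binding_residues(
    structure: ProteinStructure,
    contact_cutoff: float = CONTACT_CUTOFF,
    covalent_cutoff: float = COVALENT_CUTOFF,
    require_carbohydrate: bool = True,
) -> LabeledProtein:
    """Derive binding labels from ligand proximity.

    Residue ``i`` gets label 1 iff the minimum heavy-atom distance from
    residue ``i`` to any atom of a noncovalent flagged ligand is at most
    ``contact_cutoff``.  With ``require_carbohydrate`` (the default), only
    ligands flagged ``is_carbohydrate`` count — this is the carbohydrate
    task; pass ``False`` for the small-molecule pretraining task where every
    noncovalent ligand contributes.  The protein label is 1 iff any
    qualifying noncovalent ligand is present at all.
    """
    for lig in structure.ligands:
        if lig.is_covalent is None:
            lig.is_covalent = detect_covalent_attachment(
                lig, structure.residues, covalent_cutoff
            )
    active = [
        lig
        for lig in structure.ligands
        if not lig.is_covalent and (lig.is_carbohydrate or not require_carbohydrate)
    ]
    labels = np.zeros(len(structure.residues), dtype=int)
    if active:
        lig_xyz = np.vstack([lig.coords() for lig in active])
        for i, res in enumerate(structure.residues):
            if cdist(res.heavy_coords(), lig_xyz).min() <= contact_cutoff:
                labels[i] = 1
    return LabeledProtein(
        structure=structure, residue_labels=labels, protein_label=int(bool(active))
    )


def filter_by_plddt(structure: ProteinStructure, min_plddt: float = 70.0) -> ProteinStructure:
    """Keep residues with pLDDT strictly above ``min_plddt`` (predicted structures).

    Order is preserved and ``seq_index`` re-densified.  Crystal structures
    are returned unchanged with a warning (pLDDT undefined).  An empty result
    raises :class:`EmptyStructureError`.
    """
    if structure.source != "predicted":
        warnings.warn(
            f"{structure.id}: pLDDT filter is a no-op on crystal structures",
            stacklevel=2,
        )
        return structure
    kept = [r for r in structure.residues if r.plddt is not None and r.plddt > min_plddt]
    if not kept:
        raise EmptyStructureError(
            f"{structure.id}: no residue has pLDDT > {min_plddt}"
        )
    kept = [replace(r, seq_index=i) for i, r in enumerate(kept)]
    return ProteinStructure(
        id=structure.id, residues=kept, ligands=structure.ligands, source=structure.source
    )


def min_retained_plddt(structure: ProteinStructure) -> float:
    """Minimum pLDDT over residues; the >80 gate for training augmentation."""
    vals = [r.plddt for r in structure.residues if r.plddt is not None]
    if not vals:
        raise ValueError(f"{structure.id}: no pLDDT values present")
    return float(min(vals))


def write_predictions(
    structure: ProteinStructure,
    residue_probs: np.ndarray,
    protein_prob: float,
    out_prefix: str | Path,
    threshold: float = 0.5,
) -> tuple[Path, Path]:
    """Write a per-residue TSV and a one-line per-protein CSV.

    Output is bit-stable for identical inputs (fixed 6-decimal formatting).
    Returns ``(tsv_path, csv_path)``.
    """
    residue_probs = np.asarray(residue_probs, dtype=float)
    if len(residue_probs) != len(structure.residues):
        raise ValueError("probability vector length mismatch")
    if residue_probs.size and (residue_probs.min() < 0 or residue_probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = out_prefix.with_suffix(".residues.tsv")
    csv = out_prefix.with_suffix(".protein.csv")
    with open(tsv, "w") as fh:
        fh.write("chain\tauthor_number\tresname\tprobability\tcall\n")
        for res, p in zip(structure.residues, residue_probs):
            fh.write(
                f"{res.chain_id}\t{res.author_number}\t{res.resname}\t{p:.6f}\t{int(p >= threshold)}\n"
            )
    with open(csv, "w") as fh:
        fh.write("id,probability,call\n")
        fh.write(f"{structure.id},{protein_prob:.6f},{int(protein_prob >= threshold)}\n")
    return tsv, csv
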