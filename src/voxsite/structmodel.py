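"""Molecular structures: loading, target cleaning, and centroids.

Wraps biotite (PDB) and RDKit (SDF/MOL2) behind one light container so the
rest of the pipeline only ever sees heavy-atom coordinates in Å plus the
metadata it needs (element, mass, hetero flag, residue/chain). No
re-orientation is performed: coordinates stay in the frame of the file,
which is also the frame docking outputs are reported in.

Protonation states are never assigned here; downstream docking inputs are
expected to be pre-protonated by the user's own preparation pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_PT = Chem.GetPeriodicTable()

#: residue names treated as water in clean_target
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


def atomic_mass(element: str) -> float:
    """Standard atomic weight in Da; raises ValueError for unknown symbols."""
    try:
        num = _PT.GetAtomicNumber(element.capitalize())
    except Exception:
        raise ValueError(f"unknown element symbol: {element!r}") from None
    if num <= 0:
        raise ValueError(f"unknown element symbol: {element!r}")
    return float(_PT.GetAtomicWeight(num))


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element symbol, position (Å), mass (Da) and file metadata."""

    element: str
    position: np.ndarray  # shape (3,), Å
    mass: float
    is_hetero: bool = False
    residue_name: str = ""
    chain_id: str = ""
    res_id: int = 0
    serial: int = 0

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D", "T")


@dataclass
class MoleculeStructure:
    """An ordered collection of atoms for one protein or ligand.

    ``bonds`` holds (i, j, order) triples over atom-list indices when the
    source format carries connectivity (SDF/MOL2); PDB structures have no
    bonds recorded.
    """

    atoms: list[AtomRecord]
    name: str = ""
    kind: str = "protein"  # protein | ligand
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError(f"structure {self.name!r} has no atoms")
        if self.kind not in ("protein", "ligand"):
            raise ValueError(f"kind must be protein|ligand, got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_subset(self) -> "MoleculeStructure":
        """Heavy atoms only, with bonds re-indexed onto the subset."""
        keep = [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]
        if not keep:
            raise ValueError(f"structure {self.name!r} has no heavy atoms")
        remap = {old: new for new, old in enumerate(keep)}
        bonds = [
            (remap[i], remap[j], o)
            for i, j, o in self.bonds
            if i in remap and j in remap
        ]
        return MoleculeStructure(
            [self.atoms[i] for i in keep], name=self.name, kind=self.kind, bonds=bonds
        )

    def translated(self, t) -> "MoleculeStructure":
        t = np.asarray(t, dtype=float)
        return MoleculeStructure(
            [replace(a, position=a.position + t) for a in self.atoms],
            name=self.name,
            kind=self.kind,
            bonds=list(self.bonds),
        )


def centroid(atoms, weighting: str = "mass") -> np.ndarray:
    """Weighted mean position of a list of atoms (Å).

    ``mass`` uses standard atomic weights (the pose/cavity "mass centre"
    used throughout the pipeline, heavy-atom convention decided by the
    caller); ``geometric`` weights every atom equally.
    """
    if isinstance(atoms, MoleculeStructure):
        atoms = atoms.atoms
    atoms = list(atoms)
    if not atoms:
        raise ValueError("centroid of an empty atom list is undefined")
    pos = np.array([a.position for a in atoms])
    if weighting == "mass":
        w = np.array([a.mass for a in atoms])
    elif weighting == "geometric":
        w = np.ones(len(atoms))
    else:
        raise ValueError(f"weighting must be mass|geometric, got {weighting!r}")
    return (pos * w[:, None]).sum(axis=0) / w.sum()


def mass_centroid_heavy(struct: MoleculeStructure) -> np.ndarray:
    """Mass centre over heavy atoms — the convention for poses, cavities
    and crystal ligands everywhere in this package."""
    return centroid(struct.heavy_atoms, weighting="mass")


# ---------------------------------------------------------------------------
# File I/O


def load_structure(path, format: str | None = None, *, kind: str | None = None,
                   name: str | None = None) -> MoleculeStructure:
    """Load a PDB, SDF or MOL2 file into a MoleculeStructure.

    Hydrogens are retained (flagged via their element) so callers choose the
    heavy-atom subset explicitly. For multi-model PDB files only MODEL 1 is
    read; alternate locations keep altloc 'A'/blank.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".pdb": "pdb", ".ent": "pdb", ".sdf": "sdf", ".sd": "sdf",
                  ".mol2": "mol2"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")
    name = name if name is not None else path.stem
    if format == "pdb":
        return _load_pdb(path, name=name, kind=kind or "protein")
    if format in ("sdf", "mol2"):
        return _load_rdkit(path, format, name=name, kind=kind or "ligand")
    raise ValueError(f"unsupported format {format!r}")


def _load_pdb(path: Path, *, name: str, kind: str) -> MoleculeStructure:
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdbio.get_structure(pdb_file, model=1, altloc="first")
    except Exception as exc:
        raise ValueError(f"failed to parse PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no atoms")
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).capitalize()
        atoms.append(
            AtomRecord(
                element=element,
                position=np.asarray(arr.coord[i], dtype=float),
                mass=atomic_mass(element),
                is_hetero=bool(arr.hetero[i]),
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]),
                res_id=int(arr.res_id[i]),
                serial=i + 1,
            )
        )
    return MoleculeStructure(atoms, name=name, kind=kind)


def _load_rdkit(path: Path, format: str, *, name: str, kind: str) -> MoleculeStructure:
    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mols = [m for m in supplier if m is not None]
        mol = mols[0] if mols else None
    else:
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    if mol is None:
        raise ValueError(f"failed to parse {format.upper()} file {path}")
    return structure_from_rdkit(mol, name=name, kind=kind)


def structure_from_rdkit(mol: Chem.Mol, *, name: str = "", kind: str = "ligand"
                         ) -> MoleculeStructure:
    """Convert an RDKit molecule (with a 3D conformer) to a MoleculeStructure,
    keeping its bond graph."""
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D coordinates")
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        p = conf.GetAtomPosition(atom.GetIdx())
        sym = atom.GetSymbol()
        atoms.append(
            AtomRecord(
                element=sym,
                position=np.array([p.x, p.y, p.z]),
                mass=atomic_mass(sym),
                is_hetero=False,
                serial=atom.GetIdx() + 1,
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(1, int(b.GetBondTypeAsDouble())))
        for b in mol.GetBonds()
    ]
    return MoleculeStructure(atoms, name=name, kind=kind, bonds=bonds)


def save_pdb(struct: MoleculeStructure, path) -> None:
    """Write a structure as a PDB file (coordinates at the format's 3-decimal
    precision)."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdbio

    n = len(struct.atoms)
    arr = bst.AtomArray(n)
    arr.coord = struct.coords.astype(np.float32)
    for i, a in enumerate(struct.atoms):
        arr.element[i] = a.element.upper()
        arr.atom_name[i] = (a.element.upper() + str(i + 1))[:4]
        arr.res_name[i] = a.residue_name or ("LIG" if struct.kind == "ligand" else "GLY")
        arr.chain_id[i] = a.chain_id or "A"
        arr.res_id[i] = a.res_id if a.res_id else (1 if struct.kind == "ligand" else i + 1)
        arr.hetero[i] = a.is_hetero or struct.kind == "ligand"
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Target cleaning


def clean_target(struct: MoleculeStructure) -> MoleculeStructure:
    """Strip waters, free ions/atoms and bound hetero ligands from a protein.

    Keeps the polymer (non-HETATM) atoms. Hetero groups are classified per
    (chain, residue id, residue name): waters by name, single-atom groups as
    free ions/atoms, and any remaining multi-atom hetero group as a bound
    ligand — all removed. The input is not modified. Idempotent.
    """
    if struct.kind != "protein":
        raise ValueError("clean_target expects a protein structure")
    kept = []
    for a in struct.atoms:
        if not a.is_hetero:
            kept.append(a)
    removed = len(struct.atoms) - len(kept)
    if not kept:
        raise ValueError(
            f"cleaning removed every atom of {struct.name!r}: not a protein structure"
        )
    if removed:
        groups = {
            (a.chain_id, a.res_id, a.residue_name)
            for a in struct.atoms
            if a.is_hetero
        }
        warnings.warn(
            f"clean_target({struct.name!r}): removed {removed} hetero atoms "
            f"in {len(groups)} groups (waters/ions/ligands)",
            stacklevel=2,
        )
    return MoleculeStructure(kept, name=struct.name, kind="protein")
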