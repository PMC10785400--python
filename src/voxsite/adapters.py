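"""Normalize docking-program and cavity-tool outputs into one interchange model.

The canonical, versioned interchange (JSON, schema ``voxsite-interchange/1``)
is the tested contract between upstream programs and the voxelizer; the
native-format parsers (Vina PDBQT, fpocket output directories, P2Rank
prediction CSVs, generic multi-entry molecule files) are best-effort
conveniences that produce the same records.

All parsers preserve input order: ``pose_id``/``cavity_id`` are the 1-based
position in the program's own ranking (for P2Rank, its ``rank`` column).
Missing scores are recorded as missing (NaN), never as zero; the voxelizer's
mean imputation resolves them later.
"""

from __future__ import annotations

import json
import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from voxsite.registry import ALL_PRODUCERS, CAVITY_TOOLS, PROGRAMS
from voxsite.structmodel import AtomRecord, MoleculeStructure, atomic_mass, centroid

log = logging.getLogger(__name__)

INTERCHANGE_SCHEMA = "voxsite-interchange/1"


@dataclass
class PoseRecord:
    """One predicted ligand pose from one docking program."""

    program: str
    pose_id: int  # 1-based rank in the program's output ordering
    score: float  # program-native units; NaN when the program emitted none
    atoms: list[AtomRecord]
    centroid: np.ndarray = None  # cached heavy-atom mass centre, Å

    def __post_init__(self):
        if self.pose_id < 1:
            raise ValueError(f"pose_id must be ≥ 1, got {self.pose_id}")
        if self.program not in PROGRAMS:
            raise ValueError(f"unknown docking program {self.program!r}")
        heavy = [a for a in self.atoms if not a.is_hydrogen]
        if self.centroid is None:
            if not heavy:
                raise ValueError("pose has no heavy atoms")
            self.centroid = centroid(heavy, weighting="mass")
        else:
            self.centroid = np.asarray(self.centroid, dtype=float)
            if heavy:
                ref = centroid(heavy, weighting="mass")
                if not np.allclose(self.centroid, ref, atol=1e-6):
                    raise ValueError(
                        f"cached centroid {self.centroid} disagrees with atoms ({ref})"
                    )

    @property
    def score_missing(self) -> bool:
        return self.score is None or (isinstance(self.score, float) and math.isnan(self.score))


@dataclass
class CavityRecord:
    """One predicted pocket from one cavity-detection tool."""

    tool: str
    cavity_id: int  # 1-based rank
    centroid: np.ndarray
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.cavity_id < 1:
            raise ValueError(f"cavity_id must be ≥ 1, got {self.cavity_id}")
        if self.tool not in CAVITY_TOOLS:
            raise ValueError(f"unknown cavity tool {self.tool!r}")
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (3,) or not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"cavity centroid must be a finite 3-vector")


@dataclass
class ProgramReport:
    """All upstream outputs for one target.

    ``failures`` lists producers (docking programs or cavity tools) that ran
    but produced no output — upstream failure rates of 0–2% per program make
    explicit failure tracking necessary so the voxelizer can mark their
    features missing rather than zero. A producer never appears both with
    records and in failures.
    """

    target_id: str
    poses: list[PoseRecord] = field(default_factory=list)
    cavities: list[CavityRecord] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)

    def __post_init__(self):
        present = {p.program for p in self.poses} | {c.tool for c in self.cavities}
        bad = present & set(self.failures)
        if bad:
            raise ValueError(f"producers listed as failed but present: {sorted(bad)}")
        unknown = set(self.failures) - set(ALL_PRODUCERS)
        if unknown:
            raise ValueError(f"unknown producers in failures: {sorted(unknown)}")

    def poses_for(self, program: str) -> list[PoseRecord]:
        return [p for p in self.poses if p.program == program]

    def cavities_for(self, tool: str) -> list[CavityRecord]:
        return [c for c in self.cavities if c.tool == tool]

    def translated(self, t) -> "ProgramReport":
        t = np.asarray(t, dtype=float)
        poses = [
            PoseRecord(
                p.program,
                p.pose_id,
                p.score,
                [
                    AtomRecord(a.element, a.position + t, a.mass, a.is_hetero,
                               a.residue_name, a.chain_id, a.res_id, a.serial)
                    for a in p.atoms
                ],
            )
            for p in self.poses
        ]
        cavities = [
            CavityRecord(c.tool, c.cavity_id, c.centroid + t, dict(c.descriptors))
            for c in self.cavities
        ]
        return ProgramReport(self.target_id, poses, cavities, list(self.failures))


# ---------------------------------------------------------------------------
# Interchange JSON


class InterchangeError(ValueError):
    """Raised when an interchange document violates the schema; the message
    names the offending field."""


def _num(x):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def write_interchange(report: ProgramReport, path) -> None:
    doc = {
        "schema": INTERCHANGE_SCHEMA,
        "target_id": report.target_id,
        "poses": [
            {
                "program": p.program,
                "pose_id": p.pose_id,
                "score": _num(p.score),
                "atoms": [
                    {"element": a.element, "position": [round(float(v), 6) for v in a.position]}
                    for a in p.atoms
                ],
            }
            for p in report.poses
        ],
        "cavities": [
            {
                "tool": c.tool,
                "cavity_id": c.cavity_id,
                "centroid": [round(float(v), 6) for v in c.centroid],
                "descriptors": {k: _num(v) for k, v in c.descriptors.items()},
            }
            for c in report.cavities
        ],
        "failures": list(report.failures),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_interchange(path) -> ProgramReport:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InterchangeError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise InterchangeError("document root must be an object")
    if doc.get("schema") != INTERCHANGE_SCHEMA:
        raise InterchangeError(
            f"field 'schema': expected {INTERCHANGE_SCHEMA!r}, got {doc.get('schema')!r}"
        )
    for key in ("target_id", "poses", "cavities", "failures"):
        if key not in doc:
            raise InterchangeError(f"missing field {key!r}")
    poses = []
    for i, p in enumerate(doc["poses"]):
        try:
            atoms = [
                AtomRecord(a["element"], np.asarray(a["position"], dtype=float),
                           atomic_mass(a["element"]))
                for a in p["atoms"]
            ]
            score = p["score"]
            poses.append(
                PoseRecord(p["program"], int(p["pose_id"]),
                           float("nan") if score is None else float(score), atoms)
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InterchangeError(f"field 'poses[{i}]': {exc}") from exc
    cavities = []
    for i, c in enumerate(doc["cavities"]):
        try:
            desc = {
                k: (float("nan") if v is None else float(v))
                for k, v in c.get("descriptors", {}).items()
            }
            cavities.append(
                CavityRecord(c["tool"], int(c["cavity_id"]),
                             np.asarray(c["centroid"], dtype=float), desc)
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InterchangeError(f"field 'cavities[{i}]': {exc}") from exc
    try:
        return ProgramReport(str(doc["target_id"]), poses, cavities, list(doc["failures"]))
    except ValueError as exc:
        raise InterchangeError(str(exc)) from exc


# ---------------------------------------------------------------------------
# fpocket output directory

_FPOCKET_KEY_MAP = {
    "number of alpha spheres": "number_of_alpha_sphere",
    "local hydrophobic density score": "local_hydrophobic_density_score",
    "druggability score": "druggability_score",
}


def _fpocket_key(raw: str) -> str:
    raw = raw.strip().lower()
    return _FPOCKET_KEY_MAP.get(raw, re.sub(r"[^a-z0-9]+", "_", raw).strip("_"))


def parse_fpocket_dir(path) -> list[CavityRecord]:
    """Parse an fpocket output directory into cavity records.

    Expects the ``*_info.txt`` summary (``Pocket N :`` headers followed by
    indented ``key : value`` descriptor lines) and per-pocket alpha-sphere
    PQR files ``pockets/pocketN_vert.pqr`` whose atoms give the pocket's
    mass centre. Descriptor lines that fail to parse are recorded as missing
    with a logged warning rather than aborting the run.
    """
    path = Path(path)
    info_files = sorted(path.glob("*_info.txt"))
    if not info_files:
        raise FileNotFoundError(f"no *_info.txt in fpocket directory {path}")
    descriptors: dict[int, dict[str, float]] = {}
    current = None
    for line in info_files[0].read_text().splitlines():
        header = re.match(r"^\s*Pocket\s+(\d+)\s*:?\s*$", line)
        if header:
            current = int(header.group(1))
            descriptors[current] = {}
            continue
        if current is None or ":" not in line or not line.strip():
            continue
        key_raw, _, value_raw = line.partition(":")
        key = _fpocket_key(key_raw)
        try:
            descriptors[current][key] = float(value_raw.strip())
        except ValueError:
            descriptors[current][key] = float("nan")
            log.warning("fpocket pocket %d: unparseable descriptor line %r", current, line)
    records = []
    for pocket_id in sorted(descriptors):
        pqr = path / "pockets" / f"pocket{pocket_id}_vert.pqr"
        if not pqr.exists():
            raise FileNotFoundError(f"missing alpha-sphere file {pqr}")
        atoms = _parse_pqr_atoms(pqr)
        if not atoms:
            raise ValueError(f"no atoms in {pqr}")
        records.append(
            CavityRecord("fpocket", pocket_id,
                         centroid(atoms, weighting="mass"), descriptors[pocket_id])
        )
    return records


def _parse_pqr_atoms(path: Path) -> list[AtomRecord]:
    atoms = []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        # PQR: record serial name resname resid x y z charge radius
        x, y, z = map(float, fields[5:8])
        element = re.sub(r"\d", "", fields[2]).capitalize() or "C"
        try:
            mass = atomic_mass(element)
        except ValueError:
            element, mass = "C", atomic_mass("C")
        atoms.append(AtomRecord(element, np.array([x, y, z]), mass))
    return atoms


# ---------------------------------------------------------------------------
# P2Rank predictions CSV


def parse_p2rank_csv(path) -> list[CavityRecord]:
    """Parse a P2Rank ``*_predictions.csv`` into cavity records ordered by the
    ``rank`` column; unknown columns are kept as extra descriptors."""
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    required = {"rank", "center_x", "center_y", "center_z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"P2Rank CSV {path} missing required columns: {sorted(missing)}")
    df = df.sort_values("rank")
    skip = required | {"name"}
    records = []
    for _, row in df.iterrows():
        desc = {}
        for col in df.columns:
            if col in skip:
                continue
            try:
                desc[col] = float(row[col])
            except (TypeError, ValueError):
                continue
        records.append(
            CavityRecord(
                "p2rank",
                int(row["rank"]),
                np.array([row["center_x"], row["center_y"], row["center_z"]], dtype=float),
                desc,
            )
        )
    return records


# ---------------------------------------------------------------------------
# AutoDock Vina PDBQT


def parse_vina_pdbqt(path) -> list[PoseRecord]:
    """Parse a multi-MODEL Vina PDBQT output into pose records.

    One record per MODEL; the score is the first number on the
    ``REMARK VINA RESULT`` line (kcal/mol), missing when absent. Hydrogens
    are excluded from the stored atoms.
    """
    poses: list[PoseRecord] = []
    model_atoms: list[AtomRecord] | None = None
    model_score = float("nan")
    for line in Path(path).read_text().splitlines():
        if line.startswith("MODEL"):
            model_atoms = []
            model_score = float("nan")
        elif line.startswith("REMARK VINA RESULT"):
            nums = re.findall(r"-?\d+\.?\d*", line)
            if nums:
                model_score = float(nums[0])
        elif line.startswith(("ATOM", "HETATM")) and model_atoms is not None:
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            elem = line[76:78].strip().capitalize() if len(line) >= 78 else ""
            if not elem:
                elem = re.sub(r"\d", "", line[12:16].strip()).capitalize()[:2] or "C"
            # PDBQT atom types: HD/HS are hydrogens, A is aromatic carbon
            if elem.upper() in ("H", "HD", "HS", "D"):
                continue
            if elem == "A":
                elem = "C"
            try:
                mass = atomic_mass(elem)
            except ValueError:
                elem, mass = "C", atomic_mass("C")
            model_atoms.append(AtomRecord(elem, np.array([x, y, z]), mass))
        elif line.startswith("ENDMDL") and model_atoms:
            poses.append(PoseRecord("vina", len(poses) + 1, model_score, model_atoms))
            model_atoms = None
    return poses


# ---------------------------------------------------------------------------
# Generic multi-entry molecule files (PLANTS / GalaxyDock3 / ZDOCK exports)


def parse_generic_poses(path, program: str, format: str,
                        scores=None) -> list[PoseRecord]:
    """Parse a multi-entry MOL2/SDF/PDB pose file for any registered program.

    ZDOCK natively emits rigid-body transformations, not coordinates, so its
    poses must be pre-extracted to one of these coordinate formats. ``scores``
    is an optional sequence keyed by entry index; entries beyond its length
    get a missing score.
    """
    from rdkit import Chem

    if program not in PROGRAMS:
        raise ValueError(f"unknown docking program {program!r}")
    path = Path(path)
    mols: list = []
    if format == "sdf":
        mols = [m for m in Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
                if m is not None]
    elif format == "mol2":
        text = path.read_text()
        blocks = re.split(r"(?=@<TRIPOS>MOLECULE)", text)
        for block in blocks:
            if not block.strip().startswith("@<TRIPOS>MOLECULE"):
                continue
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=False)
            if mol is not None:
                mols.append(mol)
    elif format == "pdb":
        text = path.read_text()
        if "MODEL" in text:
            chunks = re.findall(r"MODEL.*?ENDMDL", text, flags=re.S)
        else:
            chunks = [text]
        for chunk in chunks:
            mol = Chem.MolFromPDBBlock(chunk, removeHs=False, sanitize=False)
            if mol is not None:
                mols.append(mol)
    else:
        raise ValueError(f"format must be mol2|pdb|sdf, got {format!r}")

    poses = []
    for i, mol in enumerate(mols):
        conf = mol.GetConformer()
        atoms = []
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 1:
                continue
            p = conf.GetAtomPosition(atom.GetIdx())
            sym = atom.GetSymbol()
            atoms.append(AtomRecord(sym, np.array([p.x, p.y, p.z]), atomic_mass(sym)))
        if not atoms:
            continue
        score = float("nan")
        if scores is not None and i < len(scores) and scores[i] is not None:
            score = float(scores[i])
        poses.append(PoseRecord(program, len(poses) + 1, score, atoms))
    if scores is not None and len(scores) < len(mols):
        warnings.warn(
            f"{path.name}: {len(mols) - len(scores)} entries beyond the score "
            "table; their scores are missing", stacklevel=2,
        )
    return poses
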