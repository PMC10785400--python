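"""Synthetic blind-docking scenarios for offline training and testing.

Each target is a pseudo-protein point cloud (carbon atoms, minimum-spacing
sampling inside a sphere) with one true binding site and several decoy sites
on its surface, at least 12 Å apart so an 8 Å site hit is unambiguous. Per
docking program, each pose lands near the true site with probability
``program_accuracy`` (Gaussian scatter ``pose_spread_sigma``) and otherwise
near a random decoy; scores are drawn so true-site poses are stochastically
better (≈2 score units of separation, polarity per the program registry).
Cavity tools report the true site and decoys perturbed by
``cavity_noise_sigma``, ranking the true site first with probability
``cavity_true_rank_bias``, with plausible descriptor columns. Whole-program
failures occur at ``program_failure_rate`` (the 0–2% regime observed for
real pipelines). The crystal ligand is a small rigid template placed at the
true site.

What this emulates is the *statistical* structure blind-docking consensus
relies on — programs agreeing at the true site more often than anywhere
else — not physics: there are no conformers, rotamers or energies, and the
score scales are not those of any real program.

Everything is deterministic given (seed, target index).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from voxsite.adapters import (
    CavityRecord,
    PoseRecord,
    ProgramReport,
    write_interchange,
)
from voxsite.registry import CAVITY_TOOLS, PROGRAMS
from voxsite.structmodel import (
    AtomRecord,
    MoleculeStructure,
    atomic_mass,
    mass_centroid_heavy,
    save_pdb,
)

log = logging.getLogger(__name__)

#: default pose counts mirror the character of each program's output
#: (a shape-complementarity search emits hundreds of postures)
DEFAULT_POSES_PER_PROGRAM = {"vina": 9, "plants": 10, "galaxydock": 20, "zdock": 100}
DEFAULT_PROGRAM_ACCURACY_EASY = 0.6
DEFAULT_PROGRAM_ACCURACY_HARD = 0.3
MIN_DECOY_SEPARATION = 12.0  # Å, keeps 8 Å hits unambiguous
SCORE_SEPARATION = 2.0  # score units between true-site and decoy pose means


@dataclass
class ScenarioConfig:
    n_targets: int = 10
    protein_radius: float = 25.0
    n_decoy_sites: int = 4
    program_accuracy: dict[str, float] = field(
        default_factory=lambda: {p: DEFAULT_PROGRAM_ACCURACY_EASY for p in PROGRAMS}
    )
    pose_spread_sigma: float = 2.5
    poses_per_program: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POSES_PER_PROGRAM)
    )
    cavity_noise_sigma: float = 2.0
    cavity_true_rank_bias: float = 0.5
    #: scalar applied to every producer, or a {producer: rate} map
    program_failure_rate: float | dict[str, float] = 0.02
    n_protein_atoms: int = 220
    seed: int = 0

    def __post_init__(self):
        for name, p in list(self.program_accuracy.items()):
            if not 0 <= p <= 1:
                raise ValueError(f"program_accuracy[{name!r}] must be in [0,1]")
        if not 0 <= self.cavity_true_rank_bias <= 1:
            raise ValueError("cavity_true_rank_bias must be in [0,1]")
        rates = (self.program_failure_rate.values()
                 if isinstance(self.program_failure_rate, dict)
                 else [self.program_failure_rate])
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("program_failure_rate must be in [0,1]")
        if self.pose_spread_sigma <= 0 or self.cavity_noise_sigma <= 0:
            raise ValueError("sigmas must be > 0")

    @classmethod
    def easy(cls, **kw) -> "ScenarioConfig":
        return cls(**kw)

    @classmethod
    def hard(cls, **kw) -> "ScenarioConfig":
        kw.setdefault(
            "program_accuracy",
            {p: DEFAULT_PROGRAM_ACCURACY_HARD for p in PROGRAMS},
        )
        return cls(**kw)

    def with_accuracy(self, accuracy: float) -> "ScenarioConfig":
        cfg = ScenarioConfig(**{**self.__dict__})
        cfg.program_accuracy = {p: accuracy for p in PROGRAMS}
        return cfg


@dataclass
class ScenarioTruth:
    target_id: str
    true_site_centroid: np.ndarray
    decoy_centroids: list[np.ndarray]
    crystal_ligand: MoleculeStructure


# rigid ligand template: a para-substituted six-ring (7 heavy atoms) — has a
# non-trivial automorphism group (mirror) while staying asymmetric enough
# that its mass centre is well defined off any atom
_RING = 1.4 * np.array(
    [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
)
_TEMPLATE_POS = np.vstack([_RING, [[2.8, 0.0, 0.0]]])
_TEMPLATE_ELEMENTS = ["C"] * 6 + ["O"]
_TEMPLATE_BONDS = [(i, (i + 1) % 6, 1) for i in range(6)] + [(0, 6, 1)]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _template_ligand(center: np.ndarray, rng: np.random.Generator,
                     name: str) -> MoleculeStructure:
    rot = _random_rotation(rng)
    pos = _TEMPLATE_POS @ rot.T
    masses = np.array([atomic_mass(e) for e in _TEMPLATE_ELEMENTS])
    com = (pos * masses[:, None]).sum(axis=0) / masses.sum()
    pos = pos - com + center
    atoms = [
        AtomRecord(e, p, atomic_mass(e), residue_name="LIG")
        for e, p in zip(_TEMPLATE_ELEMENTS, pos)
    ]
    return MoleculeStructure(atoms, name=name, kind="ligand",
                             bonds=list(_TEMPLATE_BONDS))


def _point_cloud(rng: np.random.Generator, radius: float, n: int,
                 min_dist: float = 2.0) -> np.ndarray:
    """Dart-throwing minimum-spacing sample inside a ball."""
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n and attempts < 50 * n:
        attempts += 1
        p = rng.normal(size=3)
        p *= radius * rng.uniform() ** (1 / 3) / np.linalg.norm(p)
        if all(np.linalg.norm(p - q) >= min_dist for q in points[-60:]):
            points.append(p)
    return np.array(points)


def _surface_sites(rng: np.random.Generator, radius: float, n_decoys: int):
    """True site + decoys on the sphere surface, pairwise ≥ 12 Å apart."""
    sites: list[np.ndarray] = []
    while len(sites) < n_decoys + 1:
        v = rng.normal(size=3)
        v *= radius / np.linalg.norm(v)
        if all(np.linalg.norm(v - s) >= MIN_DECOY_SEPARATION for s in sites):
            sites.append(v)
    return sites[0], sites[1:]


def _pose_score(rng, program: str, at_true: bool) -> float:
    spec = PROGRAMS[program]
    if spec.lower_is_better:
        mu = -7.0 if at_true else -7.0 + SCORE_SEPARATION
    else:
        mu = 50.0 + SCORE_SEPARATION if at_true else 50.0
    return float(rng.normal(mu, 1.0))


def _target_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def generate_target(config: ScenarioConfig, index: int
                    ) -> tuple[MoleculeStructure, ScenarioTruth, ProgramReport]:
    """One synthetic target: protein, ground truth, and a full program report.

    Deterministic for fixed (config.seed, index). If the failure draw would
    silence every producer, the first docking program is forced to run so the
    report is never empty.
    """
    rng = _target_rng(config.seed, index)
    target_id = f"target_{index:04d}"

    cloud = _point_cloud(rng, config.protein_radius, config.n_protein_atoms)
    protein = MoleculeStructure(
        [AtomRecord("C", p, atomic_mass("C"), residue_name="ALA", chain_id="A",
                    res_id=i + 1, serial=i + 1) for i, p in enumerate(cloud)],
        name=target_id, kind="protein",
    )
    true_site, decoys = _surface_sites(rng, config.protein_radius,
                                       config.n_decoy_sites)
    ligand = _template_ligand(true_site, rng, f"{target_id}_ligand")
    truth = ScenarioTruth(target_id, true_site, decoys, ligand)

    rate = config.program_failure_rate
    failures = [
        name for name in (*PROGRAMS, *CAVITY_TOOLS)
        if rng.uniform() < (rate.get(name, 0.0) if isinstance(rate, dict) else rate)
    ]
    if len(failures) == len(PROGRAMS) + len(CAVITY_TOOLS):
        failures = failures[1:]  # never let every producer fail

    poses: list[PoseRecord] = []
    for program in PROGRAMS:
        if program in failures:
            continue
        accuracy = config.program_accuracy.get(program, DEFAULT_PROGRAM_ACCURACY_EASY)
        n_poses = config.poses_per_program.get(program, 10)
        for pose_id in range(1, n_poses + 1):
            at_true = rng.uniform() < accuracy
            center = true_site if at_true else decoys[rng.integers(len(decoys))]
            offset = rng.normal(0.0, config.pose_spread_sigma, size=3)
            mol = _template_ligand(np.asarray(center) + offset, rng,
                                   f"{target_id}_{program}_{pose_id}")
            poses.append(PoseRecord(program, pose_id,
                                    _pose_score(rng, program, at_true), mol.atoms))

    cavities: list[CavityRecord] = []
    site_list = [np.asarray(true_site)] + [np.asarray(d) for d in decoys]
    for tool in CAVITY_TOOLS:
        if tool in failures:
            continue
        centers = [s + rng.normal(0.0, config.cavity_noise_sigma, size=3)
                   for s in site_list]
        if rng.uniform() < config.cavity_true_rank_bias:
            order = [0] + list(1 + rng.permutation(len(decoys)))
        else:
            order = list(rng.permutation(len(site_list)))
        for rank, site_idx in enumerate(order, start=1):
            is_true = site_idx == 0
            cavities.append(CavityRecord(
                tool, rank, centers[site_idx],
                _cavity_descriptors(rng, tool, is_true),
            ))

    report = ProgramReport(target_id, poses, cavities, failures)
    return protein, truth, report


def _cavity_descriptors(rng, tool: str, is_true: bool) -> dict[str, float]:
    if tool == "fpocket":
        return {
            "number_of_alpha_sphere": float(rng.poisson(55 if is_true else 35)),
            "local_hydrophobic_density_score": float(
                rng.normal(42.0 if is_true else 30.0, 8.0)
            ),
            "druggability_score": float(np.clip(
                rng.normal(0.6 if is_true else 0.35, 0.2), 0.0, 1.0
            )),
        }
    return {
        "score": float(max(0.0, rng.normal(8.0 if is_true else 3.0, 2.0))),
        "probability": float(np.clip(
            rng.normal(0.7 if is_true else 0.35, 0.15), 0.0, 1.0
        )),
    }


# ---------------------------------------------------------------------------
# On-disk corpora


def generate_corpus(config: ScenarioConfig, out_dir, overwrite: bool = False
                    ) -> Path:
    """Write ``n_targets`` targets to disk: interchange JSON, protein and
    crystal-ligand PDB files, and a manifest CSV with the true centroids.
    Refuses a non-empty output directory unless ``overwrite`` is set."""
    if config.n_targets < 1:
        raise ValueError("n_targets must be ≥ 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for index in range(config.n_targets):
        protein, truth, report = generate_target(config, index)
        tid = truth.target_id
        write_interchange(report, out_dir / f"{tid}.json")
        save_pdb(protein, out_dir / f"{tid}_protein.pdb")
        save_pdb(truth.crystal_ligand, out_dir / f"{tid}_ligand.pdb")
        x, y, z = truth.true_site_centroid
        rows.append({
            "target_id": tid,
            "true_x": x, "true_y": y, "true_z": z,
            "n_decoys": len(truth.decoy_centroids),
            "interchange": f"{tid}.json",
            "protein": f"{tid}_protein.pdb",
            "ligand": f"{tid}_ligand.pdb",
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def corpus_checksum(out_dir) -> str:
    """Stable content digest of a corpus directory (order-independent)."""
    h = hashlib.sha256()
    for path in sorted(Path(out_dir).glob("*")):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
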