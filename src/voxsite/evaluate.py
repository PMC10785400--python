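"""Evaluation metrics for site identification and pose prediction.

Site identification is scored by the Euclidean distance between a predicted
site centroid and the mass centre of the crystallographic ligand, with the
field's standard 8 Å hit threshold. Pose prediction is scored by heavy-atom
RMSD in the receptor frame (no superposition — docking outputs already live
in the target's coordinate system) with the standard 2 Å hit threshold.

``symmetric_rmsd`` corrects for chemically equivalent atom relabelings: the
reported value is the minimum plain RMSD over all isomorphisms of the
element- and bond-order-labelled molecular graphs (e.g. the 12 automorphisms
of a benzene ring), found by VF2 search. Both thresholds are strict
(< 8 Å, < 2 Å) and configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from voxsite.sitepredict import SitePrediction
from voxsite.structmodel import MoleculeStructure, mass_centroid_heavy

log = logging.getLogger(__name__)

SITE_HIT_THRESHOLD = 8.0  # Å, centroid distance
POSE_HIT_THRESHOLD = 2.0  # Å, symmetric RMSD
AUTOMORPHISM_CAP = 10**6

#: single-bond covalent radii (Å) for distance-based bond perception
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Si": 1.11,
}
_BOND_TOL = 0.45  # Å beyond the radius sum


@dataclass
class SiteEvalResult:
    target_id: str
    predicted_centroid: np.ndarray
    true_centroid: np.ndarray
    distance: float
    hit_8A: bool


@dataclass
class PoseEvalResult:
    target_id: str
    rmsd: float
    hit_2A: bool
    n_heavy_atoms: int
    automorphism_count: int
    capped: bool = False
    bonds_perceived: bool = False


def site_distance(prediction: SitePrediction | np.ndarray,
                  crystal_ligand: MoleculeStructure,
                  target_id: str = "",
                  threshold: float = SITE_HIT_THRESHOLD) -> SiteEvalResult:
    """Distance from a predicted site centroid to the crystal ligand's mass
    centre, with the strict < 8 Å hit flag."""
    if isinstance(prediction, SitePrediction):
        pred = prediction.site_centroid
    else:
        pred = np.asarray(prediction, dtype=float)
    true = mass_centroid_heavy(crystal_ligand)
    d = float(np.linalg.norm(pred - true))
    return SiteEvalResult(target_id, pred, true, d, d < threshold)


def plain_rmsd(pred: MoleculeStructure, ref: MoleculeStructure) -> float:
    """Heavy-atom RMSD under the file's 1:1 atom correspondence, no
    superposition: sqrt(mean_i |p_i − r_i|²) summed over x, y and z."""
    p = pred.heavy_subset().coords
    r = ref.heavy_subset().coords
    if p.shape != r.shape:
        raise ValueError(
            f"heavy-atom count mismatch: predicted {len(p)} vs reference {len(r)}"
        )
    return float(np.sqrt(np.mean(np.sum((p - r) ** 2, axis=1))))


def perceive_bonds(struct: MoleculeStructure) -> list[tuple[int, int, int]]:
    """Distance-based bond perception over heavy atoms: a bond wherever the
    interatomic distance is within the covalent-radius sum + 0.45 Å. All
    perceived bonds get order 1 (geometry cannot tell orders apart)."""
    atoms = struct.atoms
    coords = struct.coords
    d = cdist(coords, coords)
    bonds = []
    for i in range(len(atoms)):
        ri = _COVALENT_RADII.get(atoms[i].element.capitalize(), 0.76)
        for j in range(i + 1, len(atoms)):
            rj = _COVALENT_RADII.get(atoms[j].element.capitalize(), 0.76)
            if d[i, j] <= ri + rj + _BOND_TOL:
                bonds.append((i, j, 1))
    return bonds


def _graph(struct: MoleculeStructure, bonds) -> nx.Graph:
    g = nx.Graph()
    for i, a in enumerate(struct.atoms):
        g.add_node(i, element=a.element.capitalize())
    for i, j, order in bonds:
        g.add_edge(int(i), int(j), order=int(order))
    return g


def molecular_automorphisms(struct: MoleculeStructure, bonds=None,
                            cap: int = AUTOMORPHISM_CAP):
    """Automorphisms of the element+bond-order labelled heavy-atom graph,
    yielded as {node → node} mappings (at most ``cap``)."""
    heavy = struct.heavy_subset()
    if bonds is None:
        bonds = heavy.bonds if heavy.bonds else perceive_bonds(heavy)
    g = _graph(heavy, bonds)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    for n, mapping in enumerate(matcher.isomorphisms_iter()):
        if n >= cap:
            return
        yield mapping


def symmetric_rmsd(pred: MoleculeStructure, ref: MoleculeStructure,
                   target_id: str = "",
                   threshold: float = POSE_HIT_THRESHOLD,
                   cap: int = AUTOMORPHISM_CAP) -> PoseEvalResult:
    """Minimum heavy-atom RMSD over all isomorphisms between the two
    molecules' labelled graphs.

    Bond connectivity comes from each structure's file connectivity when
    present; when the predicted pose carries none, the reference's bond list
    is assumed to apply under the file atom order (the docking convention),
    and when the reference carries none, bonds are perceived from geometry
    (flagged ``bonds_perceived``). If the isomorphism group exceeds ``cap``,
    the result is the best value among the first ``cap`` enumerated mappings
    and the identity correspondence — an upper bound, flagged ``capped``.

    Raises if the two graphs are not isomorphic (different molecules).
    """
    p = pred.heavy_subset()
    r = ref.heavy_subset()
    if len(p) != len(r):
        raise ValueError(
            f"heavy-atom count mismatch: predicted {len(p)} vs reference {len(r)}"
        )
    perceived = False
    bonds_r = r.bonds
    if not bonds_r:
        bonds_r = perceive_bonds(r)
        perceived = True
    bonds_p = p.bonds if p.bonds else bonds_r

    g_ref = _graph(r, bonds_r)
    g_pred = _graph(p, bonds_p)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g_ref, g_pred,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    rc = r.coords
    pc = p.coords
    best = np.inf
    count = 0
    capped = False
    for mapping in matcher.isomorphisms_iter():
        count += 1
        perm = np.array([mapping[i] for i in range(len(r.atoms))])
        val = float(np.sqrt(np.mean(np.sum((pc[perm] - rc) ** 2, axis=1))))
        if val < best:
            best = val
        if count >= cap:
            capped = True
            log.warning("%s: isomorphism count hit the cap (%d); RMSD is an "
                        "upper bound", target_id or "ligand", cap)
            break
    if count == 0:
        raise ValueError(
            "molecular graphs are not isomorphic: predicted and reference "
            "ligands are different molecules"
        )
    if capped:
        best = min(best, plain_rmsd(pred, ref))
    return PoseEvalResult(
        target_id, best, best < threshold, len(r.atoms), count,
        capped=capped, bonds_perceived=perceived,
    )


# ---------------------------------------------------------------------------
# Benchmark summaries


@dataclass
class BenchmarkSummary:
    """Per-dataset accuracy / mean / median plus an unweighted cross-dataset
    average row (each dataset counts once, regardless of size)."""

    per_dataset: dict[str, dict[str, float]] = field(default_factory=dict)
    average: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = dict(self.per_dataset)
        if self.average:
            rows["Average"] = self.average
        return pd.DataFrame(rows).T[["accuracy", "mean", "median", "n"]]


def summarize(results, dataset_labels=None) -> BenchmarkSummary:
    """Aggregate per-target results into per-dataset accuracy (fraction of
    hits), mean and median of the distance/RMSD metric, and the unweighted
    average across datasets."""
    results = list(results)
    if not results:
        raise ValueError("no results to summarize")
    if dataset_labels is None:
        dataset_labels = ["all"] * len(results)
    values = []
    hits = []
    for res in results:
        if isinstance(res, SiteEvalResult):
            values.append(res.distance)
            hits.append(res.hit_8A)
        elif isinstance(res, PoseEvalResult):
            values.append(res.rmsd)
            hits.append(res.hit_2A)
        else:
            raise TypeError(f"unsupported result type {type(res).__name__}")
    df = pd.DataFrame({"dataset": dataset_labels, "value": values, "hit": hits})
    summary = BenchmarkSummary()
    for name, grp in df.groupby("dataset", sort=True):
        summary.per_dataset[name] = {
            "accuracy": float(grp["hit"].mean()),
            "mean": float(grp["value"].mean()),
            "median": float(grp["value"].median()),
            "n": int(len(grp)),
        }
    per = list(summary.per_dataset.values())
    summary.average = {
        "accuracy": float(np.mean([d["accuracy"] for d in per])),
        "mean": float(np.mean([d["mean"] for d in per])),
        "median": float(np.mean([d["median"] for d in per])),
        "n": int(sum(d["n"] for d in per)),
    }
    return summary
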