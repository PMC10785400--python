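"""From voxel scores to a predicted binding site and a local-docking plan.

The top-scoring voxel is mapped back to the nearest cavity reported by any
cavity-detection tool (Euclidean distance voxel-centre → cavity centroid,
searched jointly over the union of tools); that cavity's centroid is the
predicted ligand binding site. A 15 Å local-docking box centred on the site
is then emitted as ready-to-run configuration stubs with the fallback order
PLANTS → Vina → GalaxyDock3 — nothing is executed here, and docking inputs
are expected pre-protonated; ``select_final_pose`` consumes whatever poses
the user's own external local-docking run produced.

Every step is deterministic: ties in the voxel ranking break by greater
total pose count then lexicographic voxel index, and ties in the nearest-
cavity search break by smaller cavity rank then tool name, so results are
invariant to input ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from voxsite.adapters import CavityRecord, PoseRecord
from voxsite.registry import PROGRAMS
from voxsite.structmodel import MoleculeStructure
from voxsite.voxelizer import FeatureTable, pose_count_col

log = logging.getLogger(__name__)

DEFAULT_BOX_EXTENT = 15.0
DEFAULT_PROGRAM_ORDER = ("plants", "vina", "galaxydock")


@dataclass
class SitePrediction:
    """One predicted binding site: the voxel that nominated it, the cavity it
    mapped to, and provenance (tool + cavity rank, or "voxel-only" when no
    cavity tool produced output)."""

    rank: int
    voxel_index: tuple[int, int, int]
    voxel_score: float
    site_centroid: np.ndarray
    cavity: CavityRecord | None = None
    provenance: str = "voxel-only"

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError(f"rank must be ≥ 1, got {self.rank}")
        if not 0.0 <= self.voxel_score <= 1.0:
            raise ValueError(f"voxel_score must be in [0,1], got {self.voxel_score}")
        self.site_centroid = np.asarray(self.site_centroid, dtype=float)

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "voxel_index": list(self.voxel_index),
            "voxel_score": self.voxel_score,
            "site_centroid": [float(v) for v in self.site_centroid],
            "provenance": self.provenance,
        }


@dataclass
class DockingBoxPlan:
    """The local-docking search box and program fallback order."""

    center: np.ndarray
    extent: float = DEFAULT_BOX_EXTENT
    program_order: tuple[str, ...] = DEFAULT_PROGRAM_ORDER
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.extent <= 0:
            raise ValueError("extent must be > 0")
        if not self.program_order:
            raise ValueError("program_order must be non-empty")
        self.center = np.asarray(self.center, dtype=float)


def rank_voxels(scores: dict[tuple[int, int, int], float],
                table: FeatureTable | None = None) -> list[tuple[int, int, int]]:
    """Voxel indices in descending score order.

    Ties break by greater total pose count (when a feature table is supplied)
    then by lexicographic voxel index, so the ranking is deterministic.
    """
    if not scores:
        raise ValueError("no scored voxels to rank")
    counts: dict[tuple[int, int, int], float] = {}
    if table is not None:
        cols = [pose_count_col(p) for p in PROGRAMS if pose_count_col(p) in table.frame]
        totals = table.frame[cols].fillna(0).sum(axis=1).to_numpy()
        for idx, tot in zip(table.voxel_indices(), totals):
            counts[idx] = float(tot)
    return sorted(scores, key=lambda i: (-scores[i], -counts.get(i, 0.0), i))


def map_to_cavity(voxel_index, voxel_center, voxel_score: float,
                  cavities: list[CavityRecord], rank: int = 1) -> SitePrediction:
    """Map a voxel to the nearest cavity over the union of all tools' lists.

    Ties break by smaller cavity rank, then tool name order; with no
    cavities at all the voxel centre itself is returned (provenance
    "voxel-only") with a warning.
    """
    center = np.asarray(voxel_center, dtype=float)
    if not cavities:
        log.warning("no cavities available; falling back to the voxel centre")
        return SitePrediction(rank, tuple(voxel_index), voxel_score, center)
    best = min(
        cavities,
        key=lambda c: (float(np.linalg.norm(c.centroid - center)), c.cavity_id, c.tool),
    )
    return SitePrediction(
        rank, tuple(voxel_index), voxel_score, best.centroid.copy(),
        cavity=best, provenance=f"{best.tool}:{best.cavity_id}",
    )


def top_k_sites(ranked_voxels, scores, grid, cavities: list[CavityRecord],
                k: int = 1) -> list[SitePrediction]:
    """First ``k`` distinct cavities encountered while walking the voxel
    ranking; each cavity is reported once. Returns fewer than ``k`` (with a
    warning) when the cavity lists are exhausted."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    out: list[SitePrediction] = []
    seen: set[tuple[str, int]] = set()
    for idx in ranked_voxels:
        if len(out) == k:
            break
        remaining = [
            c for c in cavities if (c.tool, c.cavity_id) not in seen
        ]
        pred = map_to_cavity(idx, grid.center(idx), scores[idx], remaining,
                             rank=len(out) + 1)
        if pred.cavity is None:
            if not out:
                out.append(pred)
            break
        seen.add((pred.cavity.tool, pred.cavity.cavity_id))
        out.append(pred)
    if len(out) < k:
        log.warning("only %d distinct sites available (requested %d)", len(out), k)
    return out


def make_docking_plan(site: SitePrediction, ligand: MoleculeStructure | None = None,
                      extent: float = DEFAULT_BOX_EXTENT,
                      program_order: tuple[str, ...] = DEFAULT_PROGRAM_ORDER,
                      out_dir=None) -> DockingBoxPlan:
    """Build the 15 Å local-docking box around a predicted site and, when
    ``out_dir`` is given, write ready-to-run per-program input stubs
    (Vina-dialect config text; JSON stubs otherwise) documenting the
    fallback order. Nothing is executed."""
    unknown = [p for p in program_order if p not in PROGRAMS]
    if unknown:
        raise ValueError(f"unknown programs in order: {unknown}")
    plan = DockingBoxPlan(
        center=site.site_centroid, extent=extent, program_order=tuple(program_order),
        parameters={p: {"defaults": True} for p in program_order},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cx, cy, cz = (float(v) for v in plan.center)
        if "vina" in plan.program_order:
            (out_dir / "vina.conf").write_text(
                f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
                f"size_x = {plan.extent:g}\nsize_y = {plan.extent:g}\n"
                f"size_z = {plan.extent:g}\n"
            )
        for prog in plan.program_order:
            if prog == "vina":
                continue
            (out_dir / f"{prog}.json").write_text(json.dumps({
                "program": prog,
                "center": [cx, cy, cz],
                "extent": plan.extent,
                "parameters": "defaults",
            }, indent=1))
        (out_dir / "plan.json").write_text(json.dumps({
            "center": [cx, cy, cz],
            "extent": plan.extent,
            "program_order": list(plan.program_order),
            "site_provenance": site.provenance,
            "note": "inputs are expected pre-protonated; no protonation is performed",
        }, indent=1))
    return plan


def select_final_pose(poses: list[PoseRecord],
                      program_order: tuple[str, ...] = DEFAULT_PROGRAM_ORDER
                      ) -> PoseRecord:
    """Best-scoring pose from the first program in the fallback order that
    returned any poses, respecting each program's score polarity."""
    for prog in program_order:
        candidates = [p for p in poses if p.program == prog and not p.score_missing]
        if not candidates:
            candidates = [p for p in poses if p.program == prog]
        if candidates:
            spec = PROGRAMS[prog]
            scored = [p for p in candidates if not p.score_missing]
            if scored:
                return min(
                    scored,
                    key=lambda p: p.score if spec.lower_is_better else -p.score,
                )
            return candidates[0]
    raise ValueError(f"no poses from any program in {program_order}")
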