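"""Voxelization: aggregate poses and cavities onto a 10 Å grid and featurize.

An axis-aligned cubic lattice (default edge 10 Å, chosen to sample a whole
protein without drowning the signal in near-empty cells) is drawn over the
padded bounding box of the protein. Every pose and cavity is assigned to
exactly one voxel — the box containing its mass centre, under floor indexing
with half-open intervals; points on or beyond the outer boundary clamp to
the nearest boundary voxel so the partition property survives far-flung
decoy poses.

Per-voxel features follow the field's naming convention:

* ``sampled_pose_number_<program>_at_location`` — pose count of one docking
  program in the voxel;
* ``<program>_distance`` — minimum distance (Å) from that program's pose
  mass centres in the voxel to the voxel centre;
* ``<program>_best_score`` — best native score among assigned poses,
  polarity per the program registry;
* ``<Tool>_min_pose_id`` / ``<Tool>_distance`` — best (lowest) cavity rank
  assigned to the voxel and the matching centroid distance;
* ``<Tool>_<descriptor>`` — descriptor columns copied from the assigned
  cavity with the lowest rank.

Missing values (a program that failed outright, or produced nothing in a
voxel) stay missing until mean imputation with training-set column means.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from voxsite.adapters import ProgramReport
from voxsite.registry import CAVITY_TOOLS, PROGRAMS
from voxsite.structmodel import MoleculeStructure, mass_centroid_heavy

log = logging.getLogger(__name__)

INDEX_COLS = ["ix", "iy", "iz"]
CENTER_COLS = ["cx", "cy", "cz"]
LABEL_COL = "label"
#: label values: 1 positive, 0 negative, -1 unlabeled
POSITIVE, NEGATIVE, UNLABELED = 1, 0, -1


@dataclass(frozen=True)
class VoxelGrid:
    """The cubic lattice over one protein: minimum corner, edge length (Å),
    per-axis box counts, and the padding that was added around the protein."""

    origin: tuple[float, float, float]
    resolution: float
    dims: tuple[int, int, int]
    padding: float = 0.0

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be ≥ 1 each, got {self.dims}")

    @property
    def n_voxels(self) -> int:
        return self.dims[0] * self.dims[1] * self.dims[2]

    def assign(self, point) -> tuple[int, int, int]:
        """Voxel index containing ``point`` (half-open boxes, floor indexing);
        out-of-bounds points clamp to the nearest boundary voxel."""
        p = np.asarray(point, dtype=float)
        raw = np.floor((p - np.asarray(self.origin)) / self.resolution).astype(int)
        clamped = np.clip(raw, 0, np.asarray(self.dims) - 1)
        if np.any(raw != clamped):
            over = p - (np.asarray(self.origin) + np.asarray(self.dims) * self.resolution)
            under = np.asarray(self.origin) - p
            if max(over.max(), under.max()) > 1e-6:
                log.warning("point %s outside grid, clamped to voxel %s",
                            np.round(p, 3), tuple(clamped))
        return tuple(int(v) for v in clamped)

    def center(self, index) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(index) + 0.5) * self.resolution

    def all_indices(self):
        nx, ny, nz = self.dims
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    yield (ix, iy, iz)

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "resolution": self.resolution,
            "dims": list(self.dims),
            "padding": self.padding,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(tuple(d["origin"]), d["resolution"], tuple(d["dims"]), d["padding"])


def build_grid(protein: MoleculeStructure, resolution: float = 10.0,
               padding: float = 5.0) -> VoxelGrid:
    """Axis-aligned grid over the protein's heavy atoms plus ``padding`` Å on
    every side; per axis, ``dims = ceil((extent + 2·padding)/resolution)``
    (at least one box)."""
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    heavy = protein.heavy_atoms
    if not heavy:
        raise ValueError("protein has no heavy atoms")
    coords = np.array([a.position for a in heavy])
    lo = coords.min(axis=0) - padding
    extent = coords.max(axis=0) - coords.min(axis=0) + 2 * padding
    dims = tuple(max(1, int(math.ceil(e / resolution - 1e-9))) for e in extent)
    return VoxelGrid(tuple(float(v) for v in lo), float(resolution), dims, float(padding))


# ---------------------------------------------------------------------------
# Feature naming


def pose_count_col(program: str) -> str:
    return f"sampled_pose_number_{PROGRAMS[program].display}_at_location"


def pose_distance_col(program: str) -> str:
    return f"{PROGRAMS[program].display}_distance"


def pose_score_col(program: str) -> str:
    return f"{PROGRAMS[program].display}_best_score"


def cavity_rank_col(tool: str) -> str:
    return f"{CAVITY_TOOLS[tool].display}_min_pose_id"


def cavity_distance_col(tool: str) -> str:
    return f"{CAVITY_TOOLS[tool].display}_distance"


def cavity_descriptor_col(tool: str, descriptor: str) -> str:
    return f"{CAVITY_TOOLS[tool].display}_{descriptor}"


def feature_order(descriptors_by_tool: dict[str, list[str]] | None = None) -> list[str]:
    """Canonical column ordering: per-program features in registry order,
    then per-tool rank/distance/descriptor columns."""
    descriptors_by_tool = descriptors_by_tool or {}
    cols: list[str] = []
    for prog in PROGRAMS:
        cols += [pose_count_col(prog), pose_distance_col(prog), pose_score_col(prog)]
    for tool in CAVITY_TOOLS:
        cols += [cavity_rank_col(tool), cavity_distance_col(tool)]
        cols += [cavity_descriptor_col(tool, d) for d in sorted(descriptors_by_tool.get(tool, []))]
    return cols


@dataclass
class FeatureTable:
    """One target's per-voxel feature rows.

    ``frame`` holds voxel indices, voxel centres, the named features and the
    label; ``imputed`` is a parallel boolean mask marking cells filled by
    mean imputation. Count features for a non-failing program default to 0
    (the program ran and found nothing there); features of failed programs
    are missing everywhere.
    """

    target_id: str
    grid: VoxelGrid
    frame: pd.DataFrame
    feature_names: list[str]
    imputed: pd.DataFrame | None = None
    column_means: dict[str, float] | None = None

    def __post_init__(self):
        missing = [c for c in INDEX_COLS + CENTER_COLS + [LABEL_COL] if c not in self.frame]
        if missing:
            raise ValueError(f"FeatureTable frame missing columns {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[LABEL_COL].to_numpy(dtype=int)

    def voxel_indices(self) -> list[tuple[int, int, int]]:
        return [tuple(r) for r in self.frame[INDEX_COLS].to_numpy(dtype=int)]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.target_id, self.grid, self.frame.copy(), list(self.feature_names),
            None if self.imputed is None else self.imputed.copy(),
            None if self.column_means is None else dict(self.column_means),
        )

    def save(self, csv_path, sidecar_path=None) -> None:
        """CSV of rows plus a JSON sidecar with grid metadata and imputation
        means (the on-disk interchange for feature tables)."""
        csv_path = Path(csv_path)
        self.frame.to_csv(csv_path, index=False)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".meta.json")
        sidecar.write_text(json.dumps({
            "target_id": self.target_id,
            "grid": self.grid.to_dict(),
            "feature_names": self.feature_names,
            "column_means": self.column_means,
        }, indent=1))

    @classmethod
    def load(cls, csv_path, sidecar_path=None) -> "FeatureTable":
        csv_path = Path(csv_path)
        sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".meta.json")
        meta = json.loads(sidecar.read_text())
        frame = pd.read_csv(csv_path)
        return cls(meta["target_id"], VoxelGrid.from_dict(meta["grid"]), frame,
                   meta["feature_names"], column_means=meta.get("column_means"))


# ---------------------------------------------------------------------------
# Featurization


def featurize_target(grid: VoxelGrid, report: ProgramReport) -> FeatureTable:
    """One row per grid voxel with the named consensus features.

    Every pose/cavity lands in exactly one voxel (clamped assignment), so the
    per-program counts sum to the program's pose count. Distances are the
    minimum over assigned records; best scores respect each program's
    polarity; a cavity tool's descriptor columns are copied from its
    lowest-ranked cavity in the voxel.
    """
    descriptors_by_tool: dict[str, set] = {t: set() for t in CAVITY_TOOLS}
    for c in report.cavities:
        descriptors_by_tool[c.tool].update(c.descriptors)
    feat_names = feature_order({t: sorted(s) for t, s in descriptors_by_tool.items()})

    index_list = list(grid.all_indices())
    row_of = {idx: i for i, idx in enumerate(index_list)}
    n = len(index_list)
    data = {c: np.full(n, np.nan) for c in feat_names}
    failed = set(report.failures)

    for prog in PROGRAMS:
        if prog in failed:
            continue
        data[pose_count_col(prog)][:] = 0.0
        poses = report.poses_for(prog)
        spec = PROGRAMS[prog]
        for pose in poses:
            idx = grid.assign(pose.centroid)
            i = row_of[idx]
            data[pose_count_col(prog)][i] += 1
            d = float(np.linalg.norm(pose.centroid - grid.center(idx)))
            cur = data[pose_distance_col(prog)][i]
            if np.isnan(cur) or d < cur:
                data[pose_distance_col(prog)][i] = d
            if not pose.score_missing:
                cur_s = data[pose_score_col(prog)][i]
                if np.isnan(cur_s) or spec.better(pose.score, cur_s):
                    data[pose_score_col(prog)][i] = pose.score

    for tool in CAVITY_TOOLS:
        if tool in failed:
            continue
        best_cavity: dict[int, object] = {}
        for cav in report.cavities_for(tool):
            idx = grid.assign(cav.centroid)
            i = row_of[idx]
            d = float(np.linalg.norm(cav.centroid - grid.center(idx)))
            cur = data[cavity_distance_col(tool)][i]
            if np.isnan(cur) or d < cur:
                data[cavity_distance_col(tool)][i] = d
            cur_rank = data[cavity_rank_col(tool)][i]
            if np.isnan(cur_rank) or cav.cavity_id < cur_rank:
                data[cavity_rank_col(tool)][i] = cav.cavity_id
                best_cavity[i] = cav
        for i, cav in best_cavity.items():
            for k, v in cav.descriptors.items():
                data[cavity_descriptor_col(tool, k)][i] = v

    frame = pd.DataFrame({
        "ix": [i[0] for i in index_list],
        "iy": [i[1] for i in index_list],
        "iz": [i[2] for i in index_list],
    })
    centers = np.array([grid.center(i) for i in index_list])
    frame[CENTER_COLS] = centers
    for c in feat_names:
        frame[c] = data[c]
    frame[LABEL_COL] = UNLABELED
    return FeatureTable(report.target_id, grid, frame, feat_names)


def filter_empty(table: FeatureTable) -> FeatureTable:
    """Drop voxels no program or tool touched: every pose count 0 (or missing)
    and no cavity assigned. Idempotent; raises if nothing survives."""
    count_cols = [pose_count_col(p) for p in PROGRAMS]
    rank_cols = [cavity_rank_col(t) for t in CAVITY_TOOLS]
    counts = table.frame[count_cols].fillna(0)
    has_pose = (counts > 0).any(axis=1)
    has_cavity = table.frame[rank_cols].notna().any(axis=1)
    keep = has_pose | has_cavity
    if not keep.any():
        raise ValueError(
            f"target {table.target_id!r}: every voxel is empty — no program produced output"
        )
    out = table.copy()
    out.frame = out.frame.loc[keep].reset_index(drop=True)
    if out.imputed is not None:
        out.imputed = out.imputed.loc[keep].reset_index(drop=True)
    return out


def label_rows(table: FeatureTable, crystal_ligand: MoleculeStructure) -> FeatureTable:
    """Mark the voxel containing the crystal ligand's mass centre positive and
    every other retained voxel negative.

    If the positive voxel was filtered out as empty it is re-inserted with
    missing features (later mean-imputed) so each labelled target keeps
    exactly one positive row.
    """
    true_idx = table.grid.assign(mass_centroid_heavy(crystal_ligand))
    out = table.copy()
    out.frame[LABEL_COL] = NEGATIVE
    mask = (
        (out.frame["ix"] == true_idx[0])
        & (out.frame["iy"] == true_idx[1])
        & (out.frame["iz"] == true_idx[2])
    )
    if mask.any():
        out.frame.loc[mask, LABEL_COL] = POSITIVE
    else:
        center = table.grid.center(true_idx)
        row = {c: np.nan for c in out.feature_names}
        row.update({"ix": true_idx[0], "iy": true_idx[1], "iz": true_idx[2],
                    "cx": center[0], "cy": center[1], "cz": center[2],
                    LABEL_COL: POSITIVE})
        out.frame = pd.concat([out.frame, pd.DataFrame([row])], ignore_index=True)
        if out.imputed is not None:
            out.imputed = None  # stale after insertion; re-impute
    return out


# ---------------------------------------------------------------------------
# Alignment and imputation


def align_tables(tables: list[FeatureTable]) -> list[FeatureTable]:
    """Reindex every table onto the union of feature columns (canonical
    order); columns a target never saw become missing, for imputation."""
    union_desc: dict[str, set] = {t: set() for t in CAVITY_TOOLS}
    base = feature_order()
    for t in tables:
        for c in t.feature_names:
            if c in base:
                continue
            for tool, spec in CAVITY_TOOLS.items():
                prefix = spec.display + "_"
                if c.startswith(prefix):
                    for known in (cavity_rank_col(tool), cavity_distance_col(tool)):
                        if c == known:
                            break
                    else:
                        union_desc[tool].add(c[len(prefix):])
    order = feature_order({t: sorted(s) for t, s in union_desc.items()})
    out = []
    for t in tables:
        nt = t.copy()
        for c in order:
            if c not in nt.frame:
                nt.frame[c] = np.nan
        nt.frame = nt.frame[INDEX_COLS + CENTER_COLS + order + [LABEL_COL]]
        nt.feature_names = list(order)
        out.append(nt)
    return out


def fit_impute(tables: list[FeatureTable]) -> dict[str, float]:
    """Column means over all rows of the training tables, skipping missing
    cells; a column with no observed value gets mean 0 (flagged in the log)."""
    if not tables:
        raise ValueError("fit_impute needs at least one table")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise ValueError("tables have differing feature sets; run align_tables first")
    stacked = pd.concat([t.frame[names] for t in tables], ignore_index=True)
    means = {}
    for c in names:
        m = stacked[c].mean()
        if pd.isna(m):
            log.warning("feature %r has no observed values; imputation mean set to 0", c)
            m = 0.0
        means[c] = float(m)
    return means


def apply_impute(table: FeatureTable, column_means: dict[str, float]) -> FeatureTable:
    """Replace every missing feature cell with the training-set column mean;
    the ``imputed`` mask records which cells were filled. Idempotent."""
    out = table.copy()
    missing = [c for c in out.feature_names if c not in column_means]
    if missing:
        raise ValueError(f"no imputation mean for columns {missing}")
    mask = out.frame[out.feature_names].isna()
    for c in out.feature_names:
        out.frame[c] = out.frame[c].fillna(column_means[c])
    out.imputed = mask
    out.column_means = dict(column_means)
    return out
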