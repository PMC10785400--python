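"""Emit a 15 Å local-docking plan and pick the final pose from its results.

After site prediction the pipeline does not run any docking program itself:
it writes ready-to-run configuration stubs (15 Å box centred on the site,
fallback order PLANTS → Vina → GalaxyDock3). When the user's external local
docking has produced poses, `select_final_pose` takes the lowest-energy pose
from the first program that succeeded.
"""

import tempfile
from pathlib import Path

import numpy as np

from voxsite.adapters import CavityRecord, PoseRecord
from voxsite.sitepredict import make_docking_plan, map_to_cavity, select_final_pose
from voxsite.structmodel import AtomRecord, atomic_mass

site = map_to_cavity(
    voxel_index=(2, 1, 1), voxel_center=(25.0, 15.0, 15.0), voxel_score=0.93,
    cavities=[CavityRecord("fpocket", 1, [24.1, 15.8, 14.2])],
)

out_dir = Path(tempfile.mkdtemp())
plan = make_docking_plan(site, out_dir=out_dir)
print(f"box centre {np.round(plan.center, 1)}, extent {plan.extent} Å, "
      f"fallback order {plan.program_order}")
print("--- vina.conf ---")
print((out_dir / "vina.conf").read_text())


def pose(program, pose_id, score):
    atoms = [AtomRecord("C", np.array([24.0, 15.0, 14.0]), atomic_mass("C"))]
    return PoseRecord(program, pose_id, score, atoms)


# a simulated external run: PLANTS produced three scored poses
poses = [pose("plants", 1, -80.0), pose("plants", 2, -95.0), pose("plants", 3, -60.0)]
best = select_final_pose(poses)
print(f"final pose: {best.program} #{best.pose_id} at score {best.score} "
      "(lowest energy of the first non-failing program)")
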