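import math

import numpy as np
import pytest

from voxsite.adapters import (
    CavityRecord,
    InterchangeError,
    PoseRecord,
    ProgramReport,
    parse_fpocket_dir,
    parse_generic_poses,
    parse_p2rank_csv,
    parse_vina_pdbqt,
    read_interchange,
    write_interchange,
)
from voxsite.registry import ALL_PRODUCERS
from voxsite.structmodel import centroid

from conftest import make_atom


def pose(program="vina", pose_id=1, score=-7.5, at=(0.0, 0.0, 0.0)):
    """Three equal-mass atoms whose mass centre is exactly ``at``."""
    at = np.asarray(at, float)
    offsets = [(-0.75, -0.5, 0.0), (0.75, -0.5, 0.0), (0.0, 1.0, 0.0)]
    atoms = [make_atom("C", at + d) for d in offsets]
    return PoseRecord(program, pose_id, score, atoms)


def random_report(rng, target_id="t"):
    poses = []
    for program in ("vina", "plants", "zdock"):
        for i in range(rng.integers(0, 4)):
            score = float("nan") if rng.uniform() < 0.2 else float(rng.normal())
            poses.append(pose(program, i + 1, score, rng.normal(size=3) * 10))
    cavities = [
        CavityRecord("fpocket", i + 1, rng.normal(size=3) * 10,
                     {"druggability_score": float(rng.uniform())})
        for i in range(rng.integers(0, 3))
    ]
    failures = ["galaxydock"] if rng.uniform() < 0.5 else []
    return ProgramReport(target_id, poses, cavities, failures)


class TestRecords:
    def test_pose_centroid_cached_matches_recomputation(self):
        p = pose(at=(3, 4, 5))
        heavy = [a for a in p.atoms if not a.is_hydrogen]
        np.testing.assert_allclose(p.centroid, centroid(heavy, "mass"), atol=1e-9)

    def test_wrong_cached_centroid_rejected(self):
        atoms = [make_atom("C", (0, 0, 0))]
        with pytest.raises(ValueError):
            PoseRecord("vina", 1, -5.0, atoms, centroid=np.array([9.0, 9.0, 9.0]))

    def test_ids_start_at_one(self):
        with pytest.raises(ValueError):
            pose(pose_id=0)
        with pytest.raises(ValueError):
            CavityRecord("fpocket", 0, np.zeros(3))

    def test_failure_conflict_rejected(self):
        with pytest.raises(ValueError):
            ProgramReport("t", [pose("vina")], [], failures=["vina"])


class TestInterchange:
    def test_round_trip_one_pose_one_cavity(self, tmp_path):
        rep = ProgramReport(
            "t1", [pose()],
            [CavityRecord("p2rank", 1, [1.0, 2.0, 3.0], {"score": 4.5})],
        )
        f = tmp_path / "r.json"
        write_interchange(rep, f)
        back = read_interchange(f)
        assert back.target_id == "t1"
        np.testing.assert_allclose(back.poses[0].centroid, rep.poses[0].centroid)
        assert back.cavities[0].descriptors == {"score": 4.5}
        # byte-stable representation: write∘read∘write is identical
        f2 = tmp_path / "r2.json"
        write_interchange(back, f2)
        assert f.read_text() == f2.read_text()

    def test_empty_report_all_failed(self, tmp_path):
        rep = ProgramReport("t", [], [], failures=list(ALL_PRODUCERS))
        f = tmp_path / "e.json"
        write_interchange(rep, f)
        back = read_interchange(f)
        assert back.poses == [] and back.cavities == []
        assert len(back.failures) == 6

    def test_hundred_zdock_poses_preserve_order(self, tmp_path):
        rep = ProgramReport(
            "t", [pose("zdock", i + 1, float(i), (i, 0, 0)) for i in range(100)], []
        )
        f = tmp_path / "z.json"
        write_interchange(rep, f)
        assert [p.pose_id for p in read_interchange(f).poses] == list(range(1, 101))

    def test_round_trip_property_randomized(self, tmp_path):
        rng = np.random.default_rng(11)
        for k in range(10):
            rep = random_report(rng, f"t{k}")
            f = tmp_path / f"{k}.json"
            write_interchange(rep, f)
            back = read_interchange(f)
            assert len(back.poses) == len(rep.poses)
            assert back.failures == rep.failures
            for a, b in zip(back.poses, rep.poses):
                assert (a.program, a.pose_id) == (b.program, b.pose_id)
                assert a.score_missing == b.score_missing
                np.testing.assert_allclose(a.centroid, b.centroid, atol=1e-5)

    def test_schema_violation_names_field(self, tmp_path):
        f = tmp_path / "bad.json"
        f.write_text('{"schema": "voxsite-interchange/1", "target_id": "x"}')
        with pytest.raises(InterchangeError, match="poses"):
            read_interchange(f)

    def test_wrong_schema_version_rejected(self, tmp_path):
        f = tmp_path / "v.json"
        f.write_text('{"schema": "other/9", "target_id": "x", "poses": [],'
                     ' "cavities": [], "failures": []}')
        with pytest.raises(InterchangeError, match="schema"):
            read_interchange(f)


FPOCKET_INFO = """Pocket 1 :
\tScore : \t0.4123
\tDruggability Score : \t0.9213
\tNumber of Alpha Spheres : \t41
\tLocal hydrophobic density Score : \t45.12
Pocket 2 :
\tScore : \t0.2011
\tDruggability Score : \t0.1077
\tNumber of Alpha Spheres : \t17
\tLocal hydrophobic density Score : \tnot-a-number
"""


def write_fpocket_fixture(root):
    (root / "pockets").mkdir(parents=True)
    (root / "prot_info.txt").write_text(FPOCKET_INFO)
    for pid, base in [(1, 0.0), (2, 10.0)]:
        lines = [
            f"ATOM  {i+1:>5} APOL STP     1    {base + i:8.3f}{0.0:8.3f}{0.0:8.3f}"
            f"{0.0:8.2f}{1.8:8.2f}"
            for i in range(3)
        ]
        (root / "pockets" / f"pocket{pid}_vert.pqr").write_text("\n".join(lines) + "\n")


class TestFpocket:
    def test_two_pockets_parsed(self, tmp_path):
        write_fpocket_fixture(tmp_path)
        recs = parse_fpocket_dir(tmp_path)
        assert [r.cavity_id for r in recs] == [1, 2]
        assert all(r.tool == "fpocket" for r in recs)

    def test_alpha_sphere_descriptor_value(self, tmp_path):
        write_fpocket_fixture(tmp_path)
        recs = parse_fpocket_dir(tmp_path)
        assert recs[0].descriptors["number_of_alpha_sphere"] == 41
        assert recs[0].descriptors["druggability_score"] == pytest.approx(0.9213)

    def test_unparseable_descriptor_marked_missing(self, tmp_path):
        write_fpocket_fixture(tmp_path)
        recs = parse_fpocket_dir(tmp_path)
        assert math.isnan(recs[1].descriptors["local_hydrophobic_density_score"])

    def test_centroid_from_pqr_atoms(self, tmp_path):
        write_fpocket_fixture(tmp_path)
        recs = parse_fpocket_dir(tmp_path)
        np.testing.assert_allclose(recs[0].centroid, [1.0, 0.0, 0.0], atol=1e-6)

    def test_missing_info_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_fpocket_dir(tmp_path)


P2RANK_CSV = """name,rank,score,probability,center_x,center_y,center_z
pocket1,1,9.8,0.91,1.0,2.0,3.0
pocket2,2,4.1,0.44,-4.0,0.0,8.5
pocket3,3,1.2,0.10,7.0,7.0,7.0
"""


class TestP2Rank:
    def test_three_rows(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text(P2RANK_CSV)
        recs = parse_p2rank_csv(f)
        assert [r.cavity_id for r in recs] == [1, 2, 3]
        np.testing.assert_allclose(recs[1].centroid, [-4.0, 0.0, 8.5])
        assert recs[0].descriptors["probability"] == pytest.approx(0.91)

    def test_extra_columns_become_descriptors(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text(P2RANK_CSV.replace("center_z\n", "center_z,sas_points\n")
                     .replace("3.0\n", "3.0,55\n", 1)
                     .replace("8.5\n", "8.5,30\n", 1)
                     .replace("7.0\n", "7.0,12\n", 1))
        recs = parse_p2rank_csv(f)
        assert recs[0].descriptors["sas_points"] == 55

    def test_header_only_is_empty(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text(P2RANK_CSV.splitlines()[0] + "\n")
        assert parse_p2rank_csv(f) == []

    def test_missing_column_raises(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("name,rank,center_x,center_y\npocket1,1,0,0\n")
        with pytest.raises(ValueError, match="center_z"):
            parse_p2rank_csv(f)


VINA_PDBQT = """MODEL 1
REMARK VINA RESULT:      -7.5      0.000      0.000
ATOM      1  C   LIG A   1       0.000   0.000   0.000  0.00  0.00    +0.00 C
ATOM      2  O   LIG A   1       1.400   0.000   0.000  0.00  0.00    +0.00 OA
ATOM      3  H   LIG A   1       2.000   0.700   0.000  0.00  0.00    +0.00 HD
ENDMDL
MODEL 2
REMARK VINA RESULT:      -6.9      1.200      2.100
ATOM      1  C   LIG A   1       5.000   0.000   0.000  0.00  0.00    +0.00 C
ATOM      2  O   LIG A   1       6.400   0.000   0.000  0.00  0.00    +0.00 OA
ENDMDL
"""


class TestVinaPdbqt:
    def test_two_models_scores_and_ids(self, tmp_path):
        f = tmp_path / "out.pdbqt"
        f.write_text(VINA_PDBQT)
        poses = parse_vina_pdbqt(f)
        assert [p.pose_id for p in poses] == [1, 2]
        assert [p.score for p in poses] == [-7.5, -6.9]

    def test_hydrogens_excluded(self, tmp_path):
        f = tmp_path / "out.pdbqt"
        f.write_text(VINA_PDBQT)
        poses = parse_vina_pdbqt(f)
        assert len(poses[0].atoms) == 2  # H dropped

    def test_missing_remark_is_missing_score(self, tmp_path):
        f = tmp_path / "out.pdbqt"
        f.write_text(VINA_PDBQT.replace(
            "REMARK VINA RESULT:      -7.5      0.000      0.000\n", ""))
        poses = parse_vina_pdbqt(f)
        assert poses[0].score_missing and not poses[1].score_missing

    def test_no_models_is_empty(self, tmp_path):
        f = tmp_path / "empty.pdbqt"
        f.write_text("REMARK nothing here\n")
        assert parse_vina_pdbqt(f) == []


SINGLE_SDF = """mol
  test

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    1.5000    0.0000    0.0000 C   0  0
    2.1000    1.3000    0.0000 O   0  0
  1  2  1  0
  2  3  1  0
M  END
$$$$
"""


class TestGenericPoses:
    def test_single_sdf_entry(self, tmp_path):
        f = tmp_path / "poses.sdf"
        f.write_text(SINGLE_SDF)
        poses = parse_generic_poses(f, "galaxydock", "sdf", scores=[12.5])
        assert len(poses) == 1
        assert poses[0].program == "galaxydock"
        assert poses[0].score == 12.5

    def test_three_entries_in_order(self, tmp_path):
        f = tmp_path / "poses.sdf"
        f.write_text(SINGLE_SDF * 3)
        poses = parse_generic_poses(f, "plants", "sdf")
        assert [p.pose_id for p in poses] == [1, 2, 3]

    def test_short_score_table_leaves_missing(self, tmp_path):
        f = tmp_path / "poses.sdf"
        f.write_text(SINGLE_SDF * 3)
        with pytest.warns(UserWarning):
            poses = parse_generic_poses(f, "zdock", "sdf", scores=[1.0])
        assert not poses[0].score_missing
        assert poses[1].score_missing and poses[2].score_missing

    def test_unknown_program_rejected(self, tmp_path):
        f = tmp_path / "poses.sdf"
        f.write_text(SINGLE_SDF)
        with pytest.raises(ValueError):
            parse_generic_poses(f, "mystery", "sdf")
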