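import numpy as np
import pytest

from voxsite.pipeline import CorpusTarget
from voxsite.structmodel import AtomRecord, MoleculeStructure, atomic_mass
from voxsite.synthetic import ScenarioConfig, generate_target


def make_atom(element="C", pos=(0.0, 0.0, 0.0), **kw):
    return AtomRecord(element, np.asarray(pos, float), atomic_mass(element), **kw)


def make_structure(positions, elements=None, kind="ligand", bonds=None, name="mol"):
    positions = np.asarray(positions, float)
    elements = elements or ["C"] * len(positions)
    atoms = [make_atom(e, p) for e, p in zip(elements, positions)]
    return MoleculeStructure(atoms, name=name, kind=kind, bonds=bonds or [])


@pytest.fixture
def tiny_pdb(tmp_path):
    text = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       2.100   1.400   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path


def in_memory_targets(n, seed=0, accuracy=None, **cfg_kw):
    """Generate n synthetic targets as CorpusTarget objects without disk I/O."""
    kw = dict(cfg_kw)
    if accuracy is not None:
        from voxsite.registry import PROGRAMS

        kw["program_accuracy"] = {p: accuracy for p in PROGRAMS}
    cfg = ScenarioConfig(n_targets=n, seed=seed, **kw)
    out = []
    for i in range(n):
        protein, truth, report = generate_target(cfg, i)
        out.append(CorpusTarget(truth.target_id, protein, report,
                                truth.crystal_ligand, truth.true_site_centroid))
    return out


@pytest.fixture(scope="session")
def small_corpus():
    """12 easy synthetic targets, shared across fast model tests."""
    return in_memory_targets(12, seed=7)
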