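import itertools

import numpy as np
import pytest

from voxsite.evaluate import (
    BenchmarkSummary,
    molecular_automorphisms,
    plain_rmsd,
    site_distance,
    summarize,
    symmetric_rmsd,
)
from voxsite.structmodel import MoleculeStructure

from conftest import make_structure


def hexagon(radius=1.4, z=0.0):
    return radius * np.array(
        [[np.cos(a), np.sin(a), 0.0] for a in
         np.linspace(0, 2 * np.pi, 6, endpoint=False)]
    ) + np.array([0.0, 0.0, z])


RING_BONDS = [(i, (i + 1) % 6, 1) for i in range(6)]


def benzene(coords=None):
    return make_structure(coords if coords is not None else hexagon(),
                          ["C"] * 6, bonds=list(RING_BONDS))


def brute_force_symmetric_rmsd(pred, ref):
    """Oracle: minimum RMSD over ALL element- and bond-preserving atom
    permutations, by exhaustive enumeration (independent of the VF2 path).

    Enumerates permutations within each element class (the only candidates
    that can preserve element labels) and filters on exact bond-multiset
    equality.
    """
    p = pred.heavy_subset()
    r = ref.heavy_subset()
    elements_r = [a.element for a in r.atoms]
    elements_p = [a.element for a in p.atoms]
    ref_bonds = {frozenset((i, j)): o for i, j, o in (r.bonds or [])}
    pred_bonds = {frozenset((i, j)): o for i, j, o in (p.bonds or r.bonds or [])}
    n = len(r.atoms)

    classes = {}
    for i, e in enumerate(elements_r):
        classes.setdefault(e, ([], []))[0].append(i)
    for i, e in enumerate(elements_p):
        if e not in classes:
            return np.inf
        classes[e][1].append(i)
    class_list = list(classes.values())
    if any(len(a) != len(b) for a, b in class_list):
        return np.inf

    best = np.inf
    pc, rc = p.coords, r.coords
    pools = [itertools.permutations(targets) for _, targets in class_list]
    for combo in itertools.product(*pools):
        perm = [0] * n
        for (sources, _), assignment in zip(class_list, combo):
            for s, t in zip(sources, assignment):
                perm[s] = t
        mapped = {frozenset((perm[i], perm[j])): o
                  for (i, j), o in ((tuple(k), o) for k, o in ref_bonds.items())}
        if mapped != pred_bonds:
            continue
        val = np.sqrt(np.mean(np.sum((pc[perm] - rc) ** 2, axis=1)))
        best = min(best, val)
    return float(best)


class TestSiteDistance:
    def test_exact_prediction_hits(self):
        ligand = make_structure([(5, 5, 5), (7, 5, 5)])
        res = site_distance(np.array([6.0, 5.0, 5.0]), ligand)
        assert res.distance == pytest.approx(0.0) and res.hit_8A

    def test_threshold_is_strict_at_8A(self):
        ligand = make_structure([(0, 0, 0)])
        assert site_distance(np.array([7.9, 0, 0]), ligand).hit_8A
        assert not site_distance(np.array([8.1, 0, 0]), ligand).hit_8A
        assert not site_distance(np.array([8.0, 0, 0]), ligand).hit_8A

    def test_translation_invariance(self):
        ligand = make_structure([(1, 2, 3), (3, 2, 1)])
        t = np.array([10.0, -4.0, 2.0])
        d0 = site_distance(np.array([5.0, 5.0, 5.0]), ligand).distance
        d1 = site_distance(np.array([5.0, 5.0, 5.0]) + t, ligand.translated(t)).distance
        assert d0 == pytest.approx(d1)


class TestPlainRmsd:
    def test_identical_zero(self):
        m = benzene()
        assert plain_rmsd(m, m) == 0.0

    def test_uniform_displacement(self):
        m = benzene()
        shifted = m.translated([2.0, 0.0, 0.0])
        assert plain_rmsd(shifted, m) == pytest.approx(2.0)

    def test_two_atom_closed_form(self):
        ref = make_structure([(0, 0, 0), (0, 0, 1)])
        pred = make_structure([(0, 0, 0), (2, 0, 1)])
        assert plain_rmsd(pred, ref) == pytest.approx(np.sqrt(2))

    def test_count_mismatch_raises(self):
        with pytest.raises(ValueError):
            plain_rmsd(make_structure([(0, 0, 0)]), benzene())


class TestSymmetricRmsd:
    def test_rotated_benzene_numbering_is_zero(self):
        ref = benzene()
        rolled = np.roll(hexagon(), 1, axis=0)  # same geometry, relabelled
        pred = benzene(rolled)
        assert plain_rmsd(pred, ref) > 1.0
        res = symmetric_rmsd(pred, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.automorphism_count == 12  # dihedral group of the hexagon

    def test_asymmetric_molecule_equals_plain(self):
        coords = [(0, 0, 0), (1.5, 0, 0), (2.2, 1.2, 0)]
        ref = make_structure(coords, ["C", "N", "O"],
                             bonds=[(0, 1, 1), (1, 2, 1)])
        pred = make_structure(np.asarray(coords) + [0.3, 0.1, -0.2],
                              ["C", "N", "O"], bonds=[(0, 1, 1), (1, 2, 1)])
        res = symmetric_rmsd(pred, ref)
        assert res.automorphism_count == 1
        assert res.rmsd == pytest.approx(plain_rmsd(pred, ref))

    def test_identity_is_zero(self):
        m = benzene()
        assert symmetric_rmsd(m, m).rmsd == 0.0

    def test_threshold_strict_at_2A(self):
        ref = make_structure([(0, 0, 0)], ["C"])
        assert symmetric_rmsd(make_structure([(1.9, 0, 0)], ["C"]), ref).hit_2A
        assert not symmetric_rmsd(make_structure([(2.1, 0, 0)], ["C"]), ref).hit_2A

    def test_never_exceeds_plain(self):
        rng = np.random.default_rng(2)
        ref = benzene()
        for _ in range(5):
            pred = benzene(hexagon() + rng.normal(0, 0.5, size=(6, 3)))
            res = symmetric_rmsd(pred, ref)
            assert res.rmsd <= plain_rmsd(pred, ref) + 1e-12

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        ref = benzene()
        for _ in range(4):
            pred = benzene(np.roll(hexagon(), rng.integers(6), axis=0)
                           + rng.normal(0, 0.4, size=(6, 3)))
            got = symmetric_rmsd(pred, ref).rmsd
            want = brute_force_symmetric_rmsd(pred, ref)
            assert got == pytest.approx(want, abs=1e-9)

    def test_rigid_motion_of_both_invariant(self):
        rng = np.random.default_rng(4)
        ref = benzene()
        pred = benzene(hexagon() + rng.normal(0, 0.3, size=(6, 3)))
        base = symmetric_rmsd(pred, ref).rmsd
        t = np.array([3.0, -1.0, 5.0])
        assert symmetric_rmsd(pred.translated(t), ref.translated(t)).rmsd == \
            pytest.approx(base, abs=1e-9)

    def test_motion_of_one_alone_changes_rmsd(self):
        # no superposition: moving only the prediction must move the metric
        m = benzene()
        assert symmetric_rmsd(m.translated([5.0, 0, 0]), m).rmsd == pytest.approx(5.0)

    def test_different_molecules_raise(self):
        ref = make_structure([(0, 0, 0), (1.5, 0, 0)], ["C", "O"], bonds=[(0, 1, 1)])
        pred = make_structure([(0, 0, 0), (1.5, 0, 0)], ["C", "N"], bonds=[(0, 1, 1)])
        with pytest.raises(ValueError):
            symmetric_rmsd(pred, ref)

    def test_perceived_bonds_flagged(self):
        ref = make_structure([(0, 0, 0), (1.5, 0, 0)], ["C", "C"])
        pred = make_structure([(0.1, 0, 0), (1.6, 0, 0)], ["C", "C"])
        res = symmetric_rmsd(pred, ref)
        assert res.bonds_perceived

    def test_cap_yields_flagged_upper_bound(self):
        ref = benzene()
        pred = benzene(np.roll(hexagon(), 2, axis=0))
        res = symmetric_rmsd(pred, ref, cap=3)
        assert res.capped
        assert res.rmsd <= plain_rmsd(pred, ref) + 1e-12


class TestAutomorphisms:
    def test_benzene_group_order(self):
        assert sum(1 for _ in molecular_automorphisms(benzene())) == 12

    def test_agrees_with_rdkit_automorphism_enumeration(self):
        """Independent route: RDKit's self substructure matches enumerate the
        same automorphism group and the same minimum RMSD."""
        from rdkit import Chem

        rng = np.random.default_rng(5)
        ref = benzene()
        pred = benzene(np.roll(hexagon(), 2, axis=0) + rng.normal(0, 0.3, (6, 3)))

        mol = Chem.RWMol()
        for _ in range(6):
            mol.AddAtom(Chem.Atom(6))
        for i, j, _ in RING_BONDS:
            mol.AddBond(i, j, Chem.BondType.SINGLE)
        matches = mol.GetMol().GetSubstructMatches(
            mol.GetMol(), uniquify=False, maxMatches=10_000)
        assert len(matches) == 12

        pc, rc = pred.coords, ref.coords
        rdkit_min = min(
            float(np.sqrt(np.mean(np.sum((pc[list(perm)] - rc) ** 2, axis=1))))
            for perm in matches
        )
        assert symmetric_rmsd(pred, ref).rmsd == pytest.approx(rdkit_min, abs=1e-9)

    def test_chain_with_distinct_elements_trivial(self):
        m = make_structure([(0, 0, 0), (1.5, 0, 0), (3.0, 0, 0)], ["C", "N", "O"],
                           bonds=[(0, 1, 1), (1, 2, 1)])
        assert sum(1 for _ in molecular_automorphisms(m)) == 1


class TestSummarize:
    def _site_results(self, distances):
        ligand = make_structure([(0, 0, 0)])
        return [site_distance(np.array([d, 0.0, 0.0]), ligand, target_id=str(i))
                for i, d in enumerate(distances)]

    def test_accuracy_mean_median(self):
        s = summarize(self._site_results([1.0, 9.0]))
        assert s.per_dataset["all"] == {"accuracy": 0.5, "mean": 5.0,
                                        "median": 5.0, "n": 2}

    def test_all_hits(self):
        s = summarize(self._site_results([1.0, 2.0, 3.0]))
        assert s.per_dataset["all"]["accuracy"] == 1.0

    def test_cross_dataset_average_unweighted(self):
        results = self._site_results([1.0] * 2 + [1.0] * 8)
        # dataset A: 2 results acc 0.4 impossible with 2; instead craft hits:
        results = self._site_results([1.0, 9.0, 9.0, 9.0, 9.0] + [1.0, 1.0, 1.0, 9.0, 9.0])
        labels = ["A"] * 5 + ["B"] * 5
        s = summarize(results, labels)
        assert s.per_dataset["A"]["accuracy"] == pytest.approx(0.2)
        assert s.per_dataset["B"]["accuracy"] == pytest.approx(0.6)
        assert s.average["accuracy"] == pytest.approx(0.4)

    def test_accuracy_monotone_in_threshold(self):
        ligand = make_structure([(0, 0, 0)])
        distances = [1.0, 3.0, 5.0, 7.0, 9.0, 11.0]
        accs = []
        for threshold in (10.0, 8.0, 4.0, 2.0):
            res = [site_distance(np.array([d, 0, 0]), ligand, threshold=threshold)
                   for d in distances]
            accs.append(np.mean([r.hit_8A for r in res]))
        assert all(a >= b for a, b in zip(accs, accs[1:]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize([])
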