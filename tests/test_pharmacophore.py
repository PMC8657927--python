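import itertools

import numpy as np
import pytest

from grindqsar.compounds import Molecule3D
from grindqsar.pharmacophore import (
    FeaturePoint,
    PharmacophoreFeature,
    PharmacophoreModel,
    builtin_models,
    match,
    model_json,
    perceive_features,
    screen,
)
from grindqsar.syndata import motif_coordinates
from conftest import random_rotation


@pytest.fixture(scope="module")
def model1():
    return builtin_models()["model_1"]


class TestBuiltinModels:
    def test_ten_models_with_valid_matrices(self):
        models = builtin_models()
        assert len(models) == 10
        for m in models.values():
            D = m.distances
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0)
            assert m.tolerance == 1.5

    def test_model1_matrix_entries(self, model1):
        ids = [f.feature_id for f in model1.features]
        assert ids == ["Hyd", "HBA1", "HBA2", "HBD1", "HBD2"]
        D = model1.distances
        assert D[1, 2] == 2.61  # acceptor pair
        assert D[0, 2] == 4.79 and D[0, 3] == 5.56
        assert D[0, 4] == 7.68 and D[3, 4] == 6.97
        # C(5,2) = 10 distinct pairwise distances
        iu = np.triu_indices(5, 1)
        assert len(D[iu]) == 10

    def test_model1_radii(self, model1):
        radii = {f.feature_id: f.radius for f in model1.features}
        assert radii == {"Hyd": 0.75, "HBA1": 1.0, "HBA2": 0.5,
                         "HBD1": 0.75, "HBD2": 0.75}

    def test_json_roundtrip(self, model1):
        js = model_json(model1)
        m2 = PharmacophoreModel(
            name=js["name"],
            features=[PharmacophoreFeature(f["id"], f["kind"], f["radius"])
                      for f in js["features"]],
            distances=np.array(js["distances"]), tolerance=js["tolerance"])
        assert np.allclose(m2.distances, model1.distances)

    def test_invalid_matrices_rejected(self):
        feats = [PharmacophoreFeature("a", "hba", 1.0),
                 PharmacophoreFeature("b", "hbd", 1.0)]
        with pytest.raises(ValueError):
            PharmacophoreModel("bad", feats, np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValueError):
            PharmacophoreModel("bad", feats, np.array([[1.0, 2], [2, 0]]))


class TestPerceiveFeatures:
    def test_flags_take_precedence(self):
        mol = Molecule3D("f", ["C", "O"], np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                         np.zeros(2),
                         flags=[frozenset({"hydrophobic"}), frozenset({"hba"})])
        pts = perceive_features(mol)
        kinds = sorted(p.kind for p in pts)
        assert kinds == ["hba", "hydrophobic"]

    def test_carbonyl_and_hydroxyl_perception(self, toy_molecule):
        pts = perceive_features(toy_molecule)
        by_kind = {}
        for p in pts:
            by_kind.setdefault(p.kind, []).append(p)
        # carbonyl O (no H) -> acceptor only; hydroxyl O -> donor + acceptor
        hbd_atoms = {p.atom_indices[0] for p in by_kind["hbd"]}
        hba_atoms = {p.atom_indices[0] for p in by_kind["hba"]}
        assert hbd_atoms == {3}
        assert {1, 3} <= hba_atoms

    def test_ring_centroid_hydrophobic(self):
        ang = np.linspace(0, 2 * np.pi, 7)[:6]
        coords = np.column_stack([1.4 * np.cos(ang), 1.4 * np.sin(ang),
                                  np.zeros(6)])
        bonds = [(i, (i + 1) % 6, 1) for i in range(6)]
        mol = Molecule3D("ring", ["C"] * 6, coords, np.zeros(6), bonds=bonds)
        pts = perceive_features(mol)
        hyd = [p for p in pts if p.kind == "hydrophobic"]
        assert len(hyd) == 1
        assert np.linalg.norm(np.array(hyd[0].position)) < 1e-9

    def test_no_bonds_no_flags_is_error(self):
        mol = Molecule3D("x", ["C"], np.zeros((1, 3)), np.zeros(1))
        with pytest.raises(ValueError):
            perceive_features(mol)


def planted_features(jitter=0.0, seed=0):
    """Feature points at the exact built-in model-1 geometry."""
    X = motif_coordinates()
    if jitter:
        X = X + np.random.default_rng(seed).normal(0, jitter, X.shape)
    kinds = ["hydrophobic", "hba", "hba", "hbd", "hbd"]
    return [FeaturePoint(k, tuple(x), (i,)) for i, (k, x) in enumerate(zip(kinds, X))]


class TestMatch:
    def test_exact_geometry_matches_with_top_score(self, model1):
        res = match(planted_features(), model1)
        assert res.matched
        assert res.fit_score > 0.99
        assert res.max_deviation < 0.05  # printed matrix embeds to ~4e-3

    def test_tolerance_breach_rejected(self, model1):
        feats = planted_features()
        # push one donor 2.5 A outward: deviation > 1.5 A tolerance
        bad = np.array(feats[4].position)
        bad = bad / np.linalg.norm(bad) * (np.linalg.norm(bad) + 2.5)
        feats[4] = FeaturePoint("hbd", tuple(bad), (4,))
        assert not match(feats, model1).matched

    def test_rigid_motion_invariance(self, model1):
        feats = planted_features(jitter=0.2, seed=1)
        R = random_rotation(4)
        t = np.array([3.0, -1.0, 8.0])
        moved = [FeaturePoint(f.kind, tuple(R @ np.array(f.position) + t),
                              f.atom_indices) for f in feats]
        r0, r1 = match(feats, model1), match(moved, model1)
        assert r0.matched == r1.matched
        assert r0.fit_score == pytest.approx(r1.fit_score, abs=1e-9)

    def test_monotone_in_tolerance(self, model1):
        feats = planted_features(jitter=0.5, seed=2)
        loose = PharmacophoreModel("loose", model1.features,
                                   model1.distances, tolerance=3.0)
        if match(feats, model1).matched:
            assert match(feats, loose).matched

    def test_matches_bruteforce_assignment_enumeration(self):
        """4-feature model vs exhaustive assignment search."""
        rng = np.random.default_rng(6)
        feats_model = [PharmacophoreFeature("h", "hydrophobic", 0.75),
                       PharmacophoreFeature("a", "hba", 1.0),
                       PharmacophoreFeature("d1", "hbd", 0.75),
                       PharmacophoreFeature("d2", "hbd", 0.75)]
        for trial in range(25):
            pts = rng.uniform(-4, 4, size=(4, 3))
            D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            model = PharmacophoreModel("t", feats_model, D, tolerance=1.0)
            mol_pts = [
                FeaturePoint(k, tuple(rng.uniform(-4, 4, 3)), (i,))
                for i, k in enumerate(["hydrophobic", "hba", "hba",
                                       "hbd", "hbd", "hbd"])
            ]
            got = match(mol_pts, model)
            # oracle: enumerate all kind-compatible injective assignments
            expected = False
            cands = [[f for f in mol_pts if f.kind == mf.kind]
                     for mf in feats_model]
            for combo in itertools.product(*cands):
                if len({id(c) for c in combo}) < 4:
                    continue
                ok = all(
                    abs(np.linalg.norm(np.array(combo[i].position)
                                       - np.array(combo[j].position)) - D[i, j])
                    <= 1.0
                    for i in range(4) for j in range(i + 1, 4))
                if ok:
                    expected = True
                    break
            assert got.matched == expected

    def test_feature_kind_strictness(self, model1):
        feats = planted_features()
        # re-kind an acceptor as donor: no complete assignment remains
        feats[2] = FeaturePoint("hbd", feats[2].position, (2,))
        assert not match(feats, model1).matched

    def test_complexity_guard(self):
        feats = [PharmacophoreFeature(f"f{i}", "hba", 1.0) for i in range(9)]
        model = PharmacophoreModel("big", feats, np.zeros((9, 9)))
        with pytest.raises(ValueError, match="features"):
            match([], model)


class TestScreen:
    def _mol_with_features(self, cid, feats):
        elements = ["C"] * len(feats)
        coords = np.array([f.position for f in feats])
        flags = [frozenset({f.kind}) for f in feats]
        return Molecule3D(cid, elements, coords, np.zeros(len(feats)),
                          flags=flags)

    def test_perfectly_separable_dataset(self, model1):
        dataset = []
        for i in range(6):
            feats = planted_features(jitter=0.05, seed=i)
            dataset.append((f"act{i}", [self._mol_with_features(f"act{i}", feats)],
                            True))
        far = [FeaturePoint("hydrophobic", (0, 0, 0), (0,)),
               FeaturePoint("hba", (12, 0, 0), (1,)),
               FeaturePoint("hba", (0, 12, 0), (2,)),
               FeaturePoint("hbd", (0, 0, 12), (3,)),
               FeaturePoint("hbd", (12, 12, 0), (4,))]
        for i in range(6):
            dataset.append((f"ina{i}", [self._mol_with_features(f"ina{i}", far)],
                            False))
        res = screen(dataset, model1)
        assert res.mcc == 1.0 and res.tpr == 1.0 and res.tnr == 1.0

    def test_any_conformer_matching_makes_a_hit(self, model1):
        good = self._mol_with_features("c", planted_features())
        bad = self._mol_with_features("c", [
            FeaturePoint("hydrophobic", (0, 0, 0), (0,)),
            FeaturePoint("hba", (20, 0, 0), (1,)),
            FeaturePoint("hba", (0, 20, 0), (2,)),
            FeaturePoint("hbd", (0, 0, 20), (3,)),
            FeaturePoint("hbd", (20, 20, 0), (4,))])
        r1 = screen([("c", [bad, good], True)], model1)
        r2 = screen([("c", [good, bad], True)], model1)
        assert r1.hits["c"] and r2.hits["c"]

    def test_empty_dataset_rejected(self, model1):
        with pytest.raises(ValueError):
            screen([], model1)
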