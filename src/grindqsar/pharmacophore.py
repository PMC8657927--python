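"""Distance-geometry pharmacophore models, feature perception and screening.

A pharmacophore is an ordered list of interaction features (hydrophobic,
hydrogen-bond acceptor, hydrogen-bond donor) with a symmetric pairwise
distance matrix (Å) and a global distance tolerance. A conformer matches a
model when an injective, kind-preserving assignment of model features to
molecule feature points exists whose pairwise distances all agree with the
model within the tolerance. Matching is pure distance geometry — invariant
to rigid motion of the conformer — and deliberately ignores feature
direction vectors and exclusion volumes (a schema flag is reserved for the
latter). Ten built-in models derived from a ryanodine template ship with
the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np

from .compounds import Molecule3D
from .validate import ConfusionCounts, confusion_metrics

__all__ = [
    "PharmacophoreFeature",
    "PharmacophoreModel",
    "FeaturePoint",
    "MatchResult",
    "ScreenResult",
    "perceive_features",
    "match",
    "screen",
    "builtin_models",
]

FEATURE_KINDS = ("hydrophobic", "hba", "hbd")
MAX_MODEL_FEATURES = 8  # assignment search guard


@dataclass(frozen=True)
class PharmacophoreFeature:
    feature_id: str
    kind: str
    radius: float

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"kind must be one of {FEATURE_KINDS}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class PharmacophoreModel:
    name: str
    features: list
    distances: np.ndarray
    tolerance: float = 1.5
    use_exclusion_volumes: bool = False  # reserved; not applied in matching

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float)
        k = len(self.features)
        if self.distances.shape != (k, k):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.distances), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")
        D = self.distances
        for i in range(k):
            for j in range(i + 1, k):
                for m in range(k):
                    if m in (i, j):
                        continue
                    if D[i, j] > D[i, m] + D[m, j] + self.tolerance:
                        warnings.warn(
                            f"{self.name}: triangle inequality violated beyond "
                            f"tolerance for features ({i},{j},{m})",
                            UserWarning,
                        )


@dataclass(frozen=True)
class FeaturePoint:
    kind: str
    position: tuple
    atom_indices: tuple


@dataclass
class MatchResult:
    matched: bool
    assignment: dict  # model feature_id -> FeaturePoint
    fit_score: float
    max_deviation: float


def _adjacency(mol: Molecule3D):
    neigh = [[] for _ in range(mol.n_atoms)]
    for b in mol.bonds:
        neigh[b[0]].append(b[1])
        neigh[b[1]].append(b[0])
    return neigh


def perceive_features(mol: Molecule3D) -> list:
    """Feature points of a conformer.

    Pre-labelled atom flags take precedence and are returned verbatim (one
    feature point per flagged atom per kind). Otherwise features are
    perceived from elements and bonds: donors are O/N bearing a hydrogen;
    acceptors are oxygens (carbonyl/ether/hydroxyl) and nitrogens that are
    not fully substituted; hydrophobic points are the centroid of each
    ring system and of each aliphatic carbon cluster (>= 2 C) without
    attached heteroatoms.
    """
    if any(mol.flags[i] for i in range(mol.n_atoms)):
        points = []
        for i, fl in enumerate(mol.flags):
            for kind in FEATURE_KINDS:
                if kind in fl:
                    points.append(FeaturePoint(kind, tuple(mol.coords[i]), (i,)))
        return points
    if not mol.bonds:
        raise ValueError("cannot perceive features without bonds or flags")

    import networkx as nx

    neigh = _adjacency(mol)
    el = mol.elements
    points = []
    for i in range(mol.n_atoms):
        if el[i] in ("O", "N"):
            has_h = any(el[j] == "H" for j in neigh[i])
            heavy_deg = sum(1 for j in neigh[i] if el[j] != "H")
            if has_h:
                points.append(FeaturePoint("hbd", tuple(mol.coords[i]), (i,)))
            if el[i] == "O" or (el[i] == "N" and heavy_deg < 3):
                points.append(FeaturePoint("hba", tuple(mol.coords[i]), (i,)))

    g = nx.Graph()
    g.add_nodes_from(range(mol.n_atoms))
    g.add_edges_from((b[0], b[1]) for b in mol.bonds)
    ring_atoms = set()
    for cycle in nx.cycle_basis(g):
        ring_atoms.update(cycle)
    ring_sub = g.subgraph(ring_atoms)
    for comp in nx.connected_components(ring_sub):
        idx = sorted(comp)
        centroid = mol.coords[idx].mean(axis=0)
        points.append(FeaturePoint("hydrophobic", tuple(centroid), tuple(idx)))
    # aliphatic carbon clusters outside rings, no heteroatom neighbours
    plain_c = [
        i for i in range(mol.n_atoms)
        if el[i] == "C" and i not in ring_atoms
        and all(el[j] in ("C", "H") for j in neigh[i])
    ]
    for comp in nx.connected_components(g.subgraph(plain_c)):
        if len(comp) >= 2:
            idx = sorted(comp)
            centroid = mol.coords[idx].mean(axis=0)
            points.append(FeaturePoint("hydrophobic", tuple(centroid), tuple(idx)))
    return points


def match(features, model: PharmacophoreModel) -> MatchResult:
    """Match molecule feature points against a model.

    Backtracking over kind-preserving injective assignments with pairwise
    pruning: a candidate placement (model feature i -> point a) is kept
    only while |d(a, b) - D_model(i, j)| <= tolerance against every
    already-placed feature j -> b. The first admissible complete
    assignment (deterministic feature and candidate order) is returned
    with fit_score = 1 - RMS(deviations) / tolerance.
    """
    k = len(model.features)
    if k > MAX_MODEL_FEATURES:
        raise ValueError(f"models with more than {MAX_MODEL_FEATURES} features "
                         "are not supported")
    cands = [
        [fp for fp in features if fp.kind == f.kind] for f in model.features
    ]
    if any(len(c) == 0 for c in cands):
        return MatchResult(False, {}, 0.0, float("inf"))
    tol = model.tolerance
    D = model.distances
    placed: list = [None] * k

    def backtrack(i: int):
        if i == k:
            return True
        for fp in cands[i]:
            if any(p is fp for p in placed[:i]):
                continue
            ok = True
            for j in range(i):
                d = np.linalg.norm(np.array(fp.position) - np.array(placed[j].position))
                if abs(d - D[i, j]) > tol:
                    ok = False
                    break
            if ok:
                placed[i] = fp
                if backtrack(i + 1):
                    return True
                placed[i] = None
        return False

    if not backtrack(0):
        return MatchResult(False, {}, 0.0, float("inf"))
    devs = []
    for i in range(k):
        for j in range(i + 1, k):
            d = np.linalg.norm(
                np.array(placed[i].position) - np.array(placed[j].position))
            devs.append(abs(d - D[i, j]))
    devs = np.array(devs) if devs else np.zeros(1)
    rms = float(np.sqrt((devs**2).mean()))
    return MatchResult(
        matched=True,
        assignment={model.features[i].feature_id: placed[i] for i in range(k)},
        fit_score=max(0.0, 1.0 - rms / tol),
        max_deviation=float(devs.max()),
    )


@dataclass
class ScreenResult:
    hits: dict  # compound_id -> bool
    best_scores: dict  # compound_id -> best fit score over conformers
    counts: ConfusionCounts
    mcc: float | None
    tpr: float | None
    tnr: float | None


def screen(dataset, model: PharmacophoreModel) -> ScreenResult:
    """Screen a dataset of conformer ensembles against a model.

    ``dataset`` is an iterable of ``(compound_id, conformers, is_active)``
    where conformers are Molecule3D objects (or pre-perceived feature
    lists). A compound is a hit when any conformer matches — the search
    stops at the first matching conformation. Hits against activity labels
    give the confusion matrix and MCC / sensitivity / specificity.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty dataset")
    hits, best = {}, {}
    tp = tn = fp = fn = 0
    for compound_id, conformers, is_active in dataset:
        hit = False
        score = 0.0
        for conf in conformers:
            feats = conf if isinstance(conf, list) else perceive_features(conf)
            res = match(feats, model)
            if res.matched:
                hit = True
                score = res.fit_score
                break  # stop after first matching conformation
        hits[compound_id] = hit
        best[compound_id] = score
        if is_active and hit:
            tp += 1
        elif is_active:
            fn += 1
        elif hit:
            fp += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    mcc, tpr, tnr = confusion_metrics(counts)
    return ScreenResult(hits=hits, best_scores=best, counts=counts,
                        mcc=mcc, tpr=tpr, tnr=tnr)


def _load_builtin() -> dict:
    with resources.files("grindqsar.data").joinpath(
            "pharmacophore_models.json").open() as fh:
        return json.load(fh)


def builtin_models() -> dict:
    """The ten ryanodine-template distance-geometry models, keyed by name.

    Model 1 (one hydrophobic, two acceptor, two donor features; global
    tolerance 1.5 Å) is the selected screening model.
    """
    raw = _load_builtin()
    default_r = raw["default_radius"]
    out = {}
    for m in raw["models"]:
        feats = [
            PharmacophoreFeature(
                f["id"], f["kind"], f.get("radius", default_r[f["kind"]]))
            for f in m["features"]
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # some printed matrices bend triangles
            model = PharmacophoreModel(
                name=m["name"], features=feats,
                distances=np.array(m["distances"], float),
                tolerance=raw["tolerance"],
            )
        out[m["name"]] = model
    return out


def model_json(model: PharmacophoreModel) -> dict:
    return {
        "name": model.name,
        "features": [
            {"id": f.feature_id, "kind": f.kind, "radius": f.radius}
            for f in model.features
        ],
        "distances": model.distances.tolist(),
        "tolerance": model.tolerance,
    }
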