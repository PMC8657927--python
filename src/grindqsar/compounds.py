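"""Activity-table handling, curation and dataset splitting.

Activities are half-maximal inhibitory concentrations (IC50, µM). All
potency arithmetic is done on the molar scale: pIC50 = -log10(IC50 [M]),
and lipophilic efficiency LipE = pIC50 - clogP. clogP is always an input
column, never computed here. Compounds are flagged active when their IC50
does not exceed a configurable threshold (default 160 µM).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ActivityRecord",
    "Molecule3D",
    "DatasetSplit",
    "CurationReport",
    "ACTIVE_THRESHOLD_UM",
    "compute_pic50",
    "compute_lipe",
    "make_record",
    "curate",
    "select_template",
    "diverse_split",
    "molecular_weight",
    "connectivity_key",
]

ACTIVE_THRESHOLD_UM = 160.0

CLASS_LABELS = ("A", "B", "C", "M", "other")

# Monoisotopic-free average masses for the elements the generator and the
# pharmacophore toy fragments use; anything else falls back to RDKit's table.
_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "F": 18.998, "Cl": 35.45, "Br": 79.904,
}


def compute_pic50(ic50_um: float) -> float:
    """Molar pIC50 from an IC50 in µM.

    pIC50 = -log10(IC50 * 1e-6). Raises ValueError for non-positive or
    non-finite input.
    """
    if not math.isfinite(ic50_um) or ic50_um <= 0:
        raise ValueError(f"IC50 must be a positive finite value in µM, got {ic50_um!r}")
    return -math.log10(ic50_um * 1e-6)


def compute_lipe(pic50: float, clogp: float) -> float:
    """Lipophilic efficiency LipE = pIC50 - clogP (both unitless)."""
    if not (math.isfinite(pic50) and math.isfinite(clogp)):
        raise ValueError("pIC50 and clogP must be finite")
    return pic50 - clogp


@dataclass(frozen=True)
class ActivityRecord:
    """One compound's activity row.

    ``pic50`` and ``lipe`` are derived from ``ic50`` (µM) and ``clogp``;
    use :func:`make_record` to build a consistent record.
    """

    compound_id: str
    class_label: str
    ic50: float
    clogp: float
    pic50: float
    lipe: float
    is_active: bool

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if abs(self.pic50 - compute_pic50(self.ic50)) > 1e-9:
            raise ValueError("pic50 inconsistent with ic50 (molar scale)")
        if abs(self.lipe - (self.pic50 - self.clogp)) > 1e-9:
            raise ValueError("lipe inconsistent with pic50 - clogp")


def make_record(
    compound_id: str,
    class_label: str,
    ic50_um: float,
    clogp: float,
    active_threshold_um: float = ACTIVE_THRESHOLD_UM,
) -> ActivityRecord:
    pic50 = compute_pic50(ic50_um)
    return ActivityRecord(
        compound_id=compound_id,
        class_label=class_label,
        ic50=ic50_um,
        clogp=clogp,
        pic50=pic50,
        lipe=compute_lipe(pic50, clogp),
        is_active=ic50_um <= active_threshold_um,
    )


@dataclass
class Molecule3D:
    """A single-conformer 3D structure: typed atoms with coordinates,
    partial charges (e) and optional pharmacophoric feature flags.

    Pseudo-compounds from the synthetic generator use the same container;
    downstream operators only consume geometry, element types, charges and
    flags, so chemical validity is not required.
    """

    compound_id: str
    elements: list
    coords: np.ndarray
    charges: np.ndarray
    flags: list = field(default_factory=list)
    bonds: list = field(default_factory=list)  # (i, j, order)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        n = len(self.elements)
        if n < 1:
            raise ValueError("molecule must have at least one atom")
        if self.coords.shape[0] != n or self.charges.shape[0] != n:
            raise ValueError("elements/coords/charges length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.flags:
            self.flags = [frozenset() for _ in range(n)]
        self.flags = [frozenset(f) for f in self.flags]
        if len(self.flags) != n:
            raise ValueError("flags length mismatch")
        for b in self.bonds:
            i, j = b[0], b[1]
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond index out of range: {b}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Molecule3D":
        """Rigidly moved copy (rotation applied about the origin first)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        return replace(self, coords=xyz.copy())


def molecular_weight(mol: Molecule3D) -> float:
    """Sum of average atomic masses, Da."""
    total = 0.0
    for el in mol.elements:
        m = _ATOMIC_MASS.get(el)
        if m is None:
            from rdkit.Chem import GetPeriodicTable

            m = GetPeriodicTable().GetMostCommonIsotopeMass(el)
        total += m
    return total


def connectivity_key(mol: Molecule3D) -> str:
    """Canonical connectivity string used for duplicate removal.

    RDKit canonical SMILES when the structure sanitizes (stereo-aware when
    stereo is present); otherwise a deterministic Weisfeiler–Lehman-style
    hash over (element, bond-order) neighbourhoods, which also covers the
    generator's pseudo-compounds.
    """
    try:
        from rdkit import Chem

        from .io import to_rdkit

        rd = to_rdkit(mol)
        Chem.SanitizeMol(rd)
        return Chem.MolToSmiles(rd)
    except Exception:
        pass
    n = mol.n_atoms
    neigh = [[] for _ in range(n)]
    for b in mol.bonds:
        i, j = b[0], b[1]
        order = b[2] if len(b) > 2 else 1
        neigh[i].append((j, order))
        neigh[j].append((i, order))
    labels = [str(el) for el in mol.elements]
    for _ in range(max(1, n)):
        new = []
        for i in range(n):
            env = sorted(f"{order}:{labels[j]}" for j, order in neigh[i])
            new.append(hashlib.sha1((labels[i] + "|" + ",".join(env)).encode()).hexdigest()[:12])
        if new == labels:
            break
        labels = new
    return "WL:" + hashlib.sha1(",".join(sorted(labels)).encode()).hexdigest()


@dataclass
class CurationReport:
    n_input: int = 0
    n_kept: int = 0
    removed_fragment: int = 0
    removed_duplicate: int = 0
    missing_structure: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "fragment": self.removed_fragment,
            "duplicate": self.removed_duplicate,
            "missing_structure": list(self.missing_structure),
        }


def curate(records, molecules, mw_min: float = 200.0):
    """Remove fragments (MW < ``mw_min`` Da) and duplicate structures.

    Duplicates are detected by canonical connectivity key, keeping the
    first occurrence. Records without a structure are reported but kept
    out of the curated set (not fatal). Returns
    ``(records, molecules, CurationReport)``; idempotent.
    """
    by_id = {m.compound_id: m for m in molecules}
    report = CurationReport(n_input=len(records))
    seen_keys = set()
    kept_records, kept_mols = [], []
    for rec in records:
        mol = by_id.get(rec.compound_id)
        if mol is None:
            report.missing_structure.append(rec.compound_id)
            continue
        if molecular_weight(mol) < mw_min:
            report.removed_fragment += 1
            continue
        key = connectivity_key(mol)
        if key in seen_keys:
            report.removed_duplicate += 1
            continue
        seen_keys.add(key)
        kept_records.append(rec)
        kept_mols.append(mol)
    report.n_kept = len(kept_records)
    return kept_records, kept_mols, report


def select_template(
    records,
    clogp_range: tuple = (2.0, 3.0),
    lipe_min: float = 5.0,
):
    """Pick the pharmacophore template compound.

    Among records with clogP inside ``clogp_range``, return the id of the
    one with maximal LipE. If no in-range record reaches ``lipe_min`` the
    criterion is relaxed: the best in-range LipE wins anyway and the
    relaxation is flagged (second return value). Ties break by lower IC50,
    then lexicographic id.

    Returns ``(compound_id, relaxed)``.
    """
    if not records:
        raise ValueError("no records")
    lo, hi = clogp_range
    in_range = [r for r in records if lo <= r.clogp <= hi]
    if not in_range:
        raise ValueError(
            f"no record with clogP in [{lo}, {hi}]; template criterion cannot be met"
        )
    best = min(in_range, key=lambda r: (-r.lipe, r.ic50, r.compound_id))
    relaxed = best.lipe < lipe_min
    return best.compound_id, relaxed


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple
    test_ids: tuple
    fraction_train: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train/test overlap")
        n = len(self.train_ids) + len(self.test_ids)
        if abs(len(self.train_ids) - self.fraction_train * n) > 1.0 + 1e-9:
            raise ValueError("train size inconsistent with fraction_train")


def diverse_split(descriptors, ids=None, fraction_train: float = 0.8,
                  seed: int = 0) -> DatasetSplit:
    """Diverse (MaxMin) training-subset selection.

    Descriptors are standardized internally (zero-variance columns left
    centered). The seed picks the starting compound; thereafter the
    compound maximizing its minimum Euclidean distance to the already
    selected set is added until ceil(fraction_train * n) compounds are
    selected. Ties break on the lowest input index — deterministic for a
    fixed seed.
    """
    X = np.asarray(descriptors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5:
        raise ValueError("need a 2D descriptor table with at least 5 compounds")
    if not 0.0 < fraction_train < 1.0:
        raise ValueError("fraction_train must be in (0, 1)")
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    ids = list(ids)
    if len(ids) != n:
        raise ValueError("ids length mismatch")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    D = cdist(Z, Z)

    n_train = math.ceil(fraction_train * n)
    rng = np.random.default_rng(seed)
    start = int(rng.integers(n))
    selected = [start]
    remaining = [i for i in range(n) if i != start]
    while len(selected) < n_train:
        dmin = D[np.ix_(remaining, selected)].min(axis=1)
        best = int(np.argmax(dmin))  # np.argmax keeps the first (lowest-index) tie
        selected.append(remaining.pop(best))
    train = sorted(selected)
    test = sorted(set(range(n)) - set(train))
    return DatasetSplit(
        train_ids=tuple(ids[i] for i in train),
        test_ids=tuple(ids[i] for i in test),
        fraction_train=fraction_train,
    )
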