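"""File I/O: SDF V2000 structures, activity CSV tables, field exports.

Structures travel as plain V2000 SDF written/read through RDKit. Partial
charges and pharmacophoric feature flags have no V2000 column, so they
round-trip through SD data fields (``partial_charges``, ``feature_flags``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .compounds import ActivityRecord, Molecule3D, make_record

RDLogger.DisableLog("rdApp.*")

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def to_rdkit(mol: Molecule3D) -> Chem.Mol:
    """Molecule3D -> RDKit Mol (unsanitized) with one conformer."""
    rw = Chem.RWMol()
    for el in mol.elements:
        a = Chem.Atom(el)
        a.SetNoImplicit(True)
        rw.AddAtom(a)
    for b in mol.bonds:
        i, j = int(b[0]), int(b[1])
        order = int(b[2]) if len(b) > 2 else 1
        rw.AddBond(i, j, _BOND_TYPES.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(mol.n_atoms)
    for i, xyz in enumerate(mol.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    m = rw.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", mol.compound_id)
    m.SetProp("partial_charges", " ".join(f"{q:.8f}" for q in mol.charges))
    m.SetProp(
        "feature_flags",
        ";".join("|".join(sorted(f)) if f else "-" for f in mol.flags),
    )
    m.UpdatePropertyCache(strict=False)
    return m


def from_rdkit(rd: Chem.Mol) -> Molecule3D:
    conf = rd.GetConformer()
    n = rd.GetNumAtoms()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)], float)
    elements = [a.GetSymbol() for a in rd.GetAtoms()]
    if rd.HasProp("partial_charges"):
        charges = np.array([float(v) for v in rd.GetProp("partial_charges").split()])
    else:
        charges = np.zeros(n)
    if rd.HasProp("feature_flags"):
        raw = rd.GetProp("feature_flags").split(";")
        flags = [frozenset() if t == "-" else frozenset(t.split("|")) for t in raw]
    else:
        flags = [frozenset() for _ in range(n)]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()))
        for b in rd.GetBonds()
    ]
    name = rd.GetProp("_Name") if rd.HasProp("_Name") else ""
    return Molecule3D(
        compound_id=name, elements=elements, coords=coords, charges=charges,
        flags=flags, bonds=bonds,
    )


def write_sdf(molecules, path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for mol in molecules:
        writer.write(to_rdkit(mol))
    writer.close()


def read_sdf(path) -> list:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for rd in supplier:
        if rd is not None:
            out.append(from_rdkit(rd))
    return out


ACTIVITY_COLUMNS = ["compound_id", "class", "ic50_um", "clogp"]


def write_activity_csv(records, path) -> None:
    """Activity table with the derived pic50/lipe/is_active columns."""
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "class": [r.class_label for r in records],
            "ic50_um": [r.ic50 for r in records],
            "clogp": [r.clogp for r in records],
            "pic50": [r.pic50 for r in records],
            "lipe": [r.lipe for r in records],
            "is_active": [r.is_active for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_activity_csv(path, active_threshold_um: float = 160.0) -> list:
    df = pd.read_csv(path)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity CSV missing columns: {missing}")
    return [
        make_record(
            str(row["compound_id"]), str(row["class"]), float(row["ic50_um"]),
            float(row["clogp"]), active_threshold_um=active_threshold_um,
        )
        for _, row in df.iterrows()
    ]


def write_field_csv(field, path) -> None:
    """Flat per-point export: i,j,k,x,y,z,E_lj,E_el,E_hb,E."""
    g = field.grid
    nx, ny, nz = g.dims
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pts = field.grid.points()
    df = pd.DataFrame(
        {
            "i": ii.ravel(), "j": jj.ravel(), "k": kk.ravel(),
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
            "E_lj": field.e_lj.ravel(), "E_el": field.e_el.ravel(),
            "E_hb": field.e_hb.ravel(), "E": field.energy.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def write_field_dx(field, path) -> None:
    """OpenDX-style regular-grid text export of the total energy."""
    g = field.grid
    nx, ny, nz = g.dims
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {g.origin[0]:.6f} {g.origin[1]:.6f} {g.origin[2]:.6f}",
        f"delta {g.spacing:.6f} 0 0",
        f"delta 0 {g.spacing:.6f} 0",
        f"delta 0 0 {g.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    vals = field.energy.ravel()
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    Path(path).write_text("\n".join(lines) + "\n")


def save_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
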