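"""Molecular interaction fields (MIFs) on a regular grid.

Four probes are evaluated around each molecule: DRY (hydrophobic), O (sp2
carbonyl oxygen, hydrogen-bond acceptor), N1 (amide nitrogen, hydrogen-bond
donor) and TIP (molecular-shape / steric hotspot). The total interaction
energy at each grid point is the sum of Lennard–Jones, electrostatic and
hydrogen-bond terms,

    E_xyz = sum E_lj + sum E_el + sum E_hb   [kcal/mol]

with per-pair terms

    E_lj = eps_ij [ (rmin_ij / r)^12 - 2 (rmin_ij / r)^6 ]
    E_el = 332.06 q_probe q_atom / (eps(r) r),  eps(r) = 4 r   (distance-
           dependent dielectric, so E_el ∝ 1/r^2)
    E_hb = eps_hb [ 2 (r0 / r)^6 - 3 (r0 / r)^4 ] cos^2(theta)

where the 6-4 hydrogen-bond well runs only between complementary partners
(acceptor probe vs donor-flagged atom and vice versa) and theta is the angle
between the probe direction and the atom's idealized lone-pair/N-H axis
(the outward vector away from its bonded neighbours; isotropic when the
atom has no neighbours). The published GRID force field is proprietary, so
a small editable per-element parameter table of the same functional shape
is used instead; the downstream method consumes the field only through
node filtering and energy products, which this surrogate preserves.

Repulsive per-pair energies are clamped at +5 kcal/mol so points inside
van der Waals cores cannot produce singular correlogram products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .compounds import Molecule3D

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "ProbeEnergyField",
    "DEFAULT_PROBES",
    "ELEMENT_PARAMS",
    "build_grid",
    "probe_energy",
    "compute_mif",
    "tip_field",
    "compute_all_fields",
    "canonical_frame",
]

COULOMB = 332.06  # kcal mol^-1 Å e^-2
PAIR_ENERGY_CAP = 5.0  # kcal/mol, per-pair clamp inside vdW cores
MIN_DISTANCE = 0.1  # Å, below this a pair is clamped outright

# Per-element Lennard-Jones well depth (kcal/mol) and vdW radius (Å);
# rmin_ij = radius_i + radius_probe (Lorentz-Berthelot arithmetic mixing),
# eps_ij = sqrt(eps_i * eps_probe).
ELEMENT_PARAMS = {
    "H": {"eps": 0.02, "radius": 1.10},
    "C": {"eps": 0.12, "radius": 1.90},
    "N": {"eps": 0.17, "radius": 1.85},
    "O": {"eps": 0.15, "radius": 1.70},
    "P": {"eps": 0.20, "radius": 2.10},
    "S": {"eps": 0.25, "radius": 2.00},
    "*": {"eps": 0.10, "radius": 1.80},
}

# Hydrogen-bond 6-4 well parameters by probe role.
HB_WELL = {
    # probe acting as donor reaching an acceptor-flagged atom
    "donor": {"eps": 4.0, "r0": 2.9},
    # probe acting as acceptor reaching a donor-flagged atom
    "acceptor": {"eps": 3.0, "r0": 2.9},
}


@dataclass(frozen=True)
class ProbeSpec:
    """A chemical probe: LJ parameters, charge, hydrogen-bond role and the
    node-filtering energy cutoff (kcal/mol, negative)."""

    name: str
    lj_epsilon: float
    lj_radius: float
    charge: float
    hb_role: str  # 'acceptor', 'donor' or 'none'
    energy_cutoff: float

    def __post_init__(self):
        if self.energy_cutoff >= 0:
            raise ValueError("energy cutoff must be negative")
        if self.hb_role not in ("acceptor", "donor", "none"):
            raise ValueError("hb_role must be acceptor/donor/none")


DEFAULT_PROBES = {
    "DRY": ProbeSpec("DRY", lj_epsilon=0.25, lj_radius=1.70, charge=0.0,
                     hb_role="none", energy_cutoff=-0.5),
    "O": ProbeSpec("O", lj_epsilon=0.15, lj_radius=1.70, charge=-0.40,
                   hb_role="acceptor", energy_cutoff=-2.6),
    "N1": ProbeSpec("N1", lj_epsilon=0.17, lj_radius=1.85, charge=0.40,
                    hb_role="donor", energy_cutoff=-4.2),
    "TIP": ProbeSpec("TIP", lj_epsilon=0.15, lj_radius=1.70, charge=0.0,
                     hb_role="none", energy_cutoff=-0.75),
}

PROBE_NAMES = ("DRY", "O", "N1", "TIP")


@dataclass(frozen=True)
class GridSpec:
    origin: tuple
    spacing: float
    dims: tuple

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ValueError("grid needs at least 2 points per axis")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))

    def points(self) -> np.ndarray:
        """All grid-point coordinates, shape (n_points, 3), x fastest last."""
        axes = [
            self.origin[a] + self.spacing * np.arange(self.dims[a])
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class ProbeEnergyField:
    grid: GridSpec
    probe: ProbeSpec
    e_lj: np.ndarray
    e_el: np.ndarray
    e_hb: np.ndarray

    @property
    def energy(self) -> np.ndarray:
        return self.e_lj + self.e_el + self.e_hb


def build_grid(molecule: Molecule3D, spacing: float = 0.5,
               margin: float = 5.0) -> GridSpec:
    """Axis-aligned box: atom bounding box expanded by ``margin`` on every
    side, dims = ceil(extent / spacing) + 1 per axis, origin at the minimum
    corner."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = molecule.coords.min(axis=0) - margin
    hi = molecule.coords.max(axis=0) + margin
    extent = hi - lo
    dims = tuple(int(math.ceil(e / spacing - 1e-9)) + 1 for e in extent)
    return GridSpec(origin=tuple(lo), spacing=spacing, dims=dims)


def _element_params(elements):
    eps = np.array([ELEMENT_PARAMS.get(el, ELEMENT_PARAMS["*"])["eps"] for el in elements])
    rad = np.array([ELEMENT_PARAMS.get(el, ELEMENT_PARAMS["*"])["radius"] for el in elements])
    return eps, rad


def hb_directions(molecule: Molecule3D) -> np.ndarray:
    """Idealized lone-pair / N-H axis per atom: unit vector from the mean
    bonded-neighbour position to the atom (zero vector = isotropic)."""
    n = molecule.n_atoms
    dirs = np.zeros((n, 3))
    neigh = [[] for _ in range(n)]
    for b in molecule.bonds:
        neigh[b[0]].append(b[1])
        neigh[b[1]].append(b[0])
    for i in range(n):
        if neigh[i]:
            v = molecule.coords[i] - molecule.coords[neigh[i]].mean(axis=0)
            norm = np.linalg.norm(v)
            if norm > 1e-12:
                dirs[i] = v / norm
    return dirs


def _energy_components(points, molecule: Molecule3D, probe: ProbeSpec,
                       directions=None):
    """Vectorized Eq-style energy components at arbitrary points.

    Returns (e_lj, e_el, e_hb) arrays of len(points).
    """
    pts = np.atleast_2d(np.asarray(points, float))
    xyz = molecule.coords
    eps_a, rad_a = _element_params(molecule.elements)
    r = cdist(pts, xyz)
    clamped = r < MIN_DISTANCE
    r = np.maximum(r, MIN_DISTANCE)

    # Lennard-Jones with per-pair repulsion cap
    eps_ij = np.sqrt(eps_a * probe.lj_epsilon)
    rmin_ij = rad_a + probe.lj_radius
    s6 = (rmin_ij / r) ** 6
    e_lj_pair = eps_ij * (s6 * s6 - 2.0 * s6)
    e_lj_pair = np.clip(e_lj_pair, -PAIR_ENERGY_CAP, PAIR_ENERGY_CAP)
    e_lj_pair[clamped] = PAIR_ENERGY_CAP
    e_lj = e_lj_pair.sum(axis=1)

    # electrostatics, distance-dependent dielectric eps(r) = 4 r; pair
    # terms are clamped symmetrically so core singularities cannot leak
    if probe.charge != 0.0 and np.any(molecule.charges != 0.0):
        e_el_pair = COULOMB * probe.charge * molecule.charges / (4.0 * r * r)
        e_el_pair = np.clip(e_el_pair, -PAIR_ENERGY_CAP, PAIR_ENERGY_CAP)
        e_el = e_el_pair.sum(axis=1)
    else:
        e_el = np.zeros(len(pts))

    # hydrogen bonds between complementary partners only
    e_hb = np.zeros(len(pts))
    if probe.hb_role != "none":
        partner_flag = "hbd" if probe.hb_role == "acceptor" else "hba"
        idx = [i for i, f in enumerate(molecule.flags) if partner_flag in f]
        if idx:
            well = HB_WELL[probe.hb_role]
            if directions is None:
                directions = hb_directions(molecule)
            for i in idx:
                ri = r[:, i]
                s4 = (well["r0"] / ri) ** 4
                s6h = s4 * (well["r0"] / ri) ** 2
                radial = well["eps"] * (2.0 * s6h - 3.0 * s4)
                d = directions[i]
                if np.linalg.norm(d) > 0:
                    v = pts - xyz[i]
                    cos = (v @ d) / np.maximum(np.linalg.norm(v, axis=1), 1e-12)
                    ang = np.where(cos > 0, cos * cos, 0.0)
                else:
                    ang = 1.0
                e_hb += np.clip(radial * ang, -PAIR_ENERGY_CAP, PAIR_ENERGY_CAP)
    return e_lj, e_el, e_hb


def probe_energy(molecule: Molecule3D, point, probe: ProbeSpec):
    """Energy components (E_lj, E_el, E_hb) for one probe position."""
    point = np.asarray(point, float)
    if not np.all(np.isfinite(point)):
        raise ValueError("probe position must be finite")
    e_lj, e_el, e_hb = _energy_components(point[None, :], molecule, probe)
    return float(e_lj[0]), float(e_el[0]), float(e_hb[0])


def compute_mif(molecule: Molecule3D, probe: ProbeSpec,
                grid: GridSpec) -> ProbeEnergyField:
    """Evaluate the probe at every grid point."""
    pts = grid.points()
    dirs = hb_directions(molecule)
    e_lj, e_el, e_hb = _energy_components(pts, molecule, probe, directions=dirs)
    shape = grid.dims
    return ProbeEnergyField(
        grid=grid, probe=probe,
        e_lj=e_lj.reshape(shape), e_el=e_el.reshape(shape),
        e_hb=e_hb.reshape(shape),
    )


def tip_field(molecule: Molecule3D, grid: GridSpec,
              probe: ProbeSpec | None = None, iso: float = 0.5) -> ProbeEnergyField:
    """Molecular-shape (TIP) pseudo-field.

    The exact published shape-probe functional form is unavailable, so the
    field is a documented surrogate: the steric LJ field of the TIP probe
    defines a solid region (E_lj >= ``iso`` kcal/mol); shell points are
    solid points with at least one non-solid 26-neighbour. Each shell point
    scores -1.0 times a convexity weight (the fraction of its
    26-neighbourhood outside the solid, min-max rescaled to [0, 1] over the
    shell), so convex protrusions score most negative. All other points
    are zero.
    """
    if probe is None:
        probe = DEFAULT_PROBES["TIP"]
    pts = grid.points()
    e_lj, _, _ = _energy_components(pts, molecule, probe)
    lj = e_lj.reshape(grid.dims)
    solid = lj >= iso

    outside_count = np.zeros(grid.dims)
    neighbor_count = np.zeros(grid.dims)
    face_exposed = np.zeros(grid.dims, bool)
    pad = np.pad(solid, 1, constant_values=False)
    padded_valid = np.pad(np.ones(grid.dims, bool), 1, constant_values=False)
    nx, ny, nz = grid.dims
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                sl = (slice(1 + dx, 1 + dx + nx), slice(1 + dy, 1 + dy + ny),
                      slice(1 + dz, 1 + dz + nz))
                valid = padded_valid[sl]
                outside = valid & ~pad[sl]
                outside_count += outside
                neighbor_count += valid
                if abs(dx) + abs(dy) + abs(dz) <= 2:
                    face_exposed |= outside
    # shell = solid voxels exposed through a face or an edge (one-voxel
    # surface); convexity weight from the full 26-neighbourhood
    shell = solid & face_exposed
    energy = np.zeros(grid.dims)
    if shell.any():
        frac = np.zeros(grid.dims)
        frac[shell] = outside_count[shell] / neighbor_count[shell]
        fmin, fmax = frac[shell].min(), frac[shell].max()
        span = fmax - fmin
        if span < 1e-12:
            weight = np.ones(shell.sum())
        else:
            weight = (frac[shell] - fmin) / span
        energy[shell] = -1.0 * weight
    return ProbeEnergyField(
        grid=grid, probe=probe, e_lj=energy,
        e_el=np.zeros(grid.dims), e_hb=np.zeros(grid.dims),
    )


def canonical_frame(molecule: Molecule3D) -> Molecule3D:
    """Re-express the molecule in a canonical inertial frame.

    Centroid at the origin; axes along the principal components of the
    coordinates, each axis oriented so the third moment of the coordinates
    is positive (falling back to the farthest atom's sign when the third
    moment vanishes). Makes the grid — and therefore nodes and correlogram
    descriptors — invariant under rigid motion of the input structure.
    """
    xyz = molecule.coords - molecule.coords.mean(axis=0)
    if molecule.n_atoms == 1:
        return molecule.transformed(translation=-molecule.coords.mean(axis=0))
    cov = np.cov(xyz.T)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    proj = xyz @ axes
    for a in range(3):
        m3 = (proj[:, a] ** 3).sum()
        if abs(m3) < 1e-9:
            k = int(np.argmax(np.abs(proj[:, a])))
            m3 = proj[k, a]
        if m3 < 0:
            axes[:, a] = -axes[:, a]
    if np.linalg.det(axes) < 0:
        # keep right-handedness even if it costs the z sign convention
        axes[:, 2] = -axes[:, 2]
    return Molecule3D(
        compound_id=molecule.compound_id,
        elements=list(molecule.elements),
        coords=(xyz @ axes),
        charges=molecule.charges.copy(),
        flags=list(molecule.flags),
        bonds=list(molecule.bonds),
    )


def compute_all_fields(molecule: Molecule3D, spacing: float = 0.5,
                       margin: float = 5.0, probes=None, canonicalize: bool = True):
    """All four probe fields on a shared grid.

    With ``canonicalize`` the molecule is first put into its canonical
    frame (see :func:`canonical_frame`) so descriptors do not depend on the
    input pose. Returns ``(fields_by_probe_name, molecule_used)``.
    """
    if probes is None:
        probes = DEFAULT_PROBES
    mol = canonical_frame(molecule) if canonicalize else molecule
    grid = build_grid(mol, spacing=spacing, margin=margin)
    fields = {}
    for name, probe in probes.items():
        if name == "TIP":
            fields[name] = tip_field(mol, grid, probe=probe)
        else:
            fields[name] = compute_mif(mol, probe, grid)
    return fields, mol
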