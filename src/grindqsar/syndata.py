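"""Synthetic pseudo-compound generator.

Emulates the statistical structure of a small, scaffold-clustered inhibitor
dataset (~40 compounds in four classes, IC50 spanning 0.0029–20,000 µM,
active/inactive threshold 160 µM) so that every downstream stage — fields,
node filtering, correlograms, PLS/FFD, pharmacophore screening — is
testable without external data.

Pseudo-compounds are geometric atom sets (15–60 atoms) with physically
plausible partial charges and pre-labelled pharmacophoric atoms; they are
not chemically valid molecules, which is sufficient because every
downstream operator consumes geometry + types + charges only. A fraction
of compounds carries the "active motif": five feature atoms placed at the
built-in model-1 distance geometry (hydrogen-bond acceptors ~2.6 and
~4.8 Å, donors ~5.6 and ~7.7 Å from a hydrophobic centre). Activities are
a known sparse linear function of the dataset's own correlogram variables
plus Gaussian noise, and the ground truth (placed feature distances, the
coefficient map, noiseless pIC50) is kept alongside the dataset.

One random stream per dataset is split into named substreams (geometry,
charges, labels, noise) so changing one does not shift the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .compounds import ActivityRecord, Molecule3D, make_record
from .grind import GrindDescriptorizer, descriptor_matrix

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "CLASS_GEOMETRY",
    "generate_molecules",
    "generate_activities",
    "generate_dataset",
    "generate_screening_dataset",
    "motif_coordinates",
]

# mirrors the source dataset's class composition: 12 inositol-phosphate-like,
# 6 macrocycle-like, 3 biphenyl-phosphate-like, 19 miscellaneous of 40
DEFAULT_CLASS_WEIGHTS = {"A": 0.30, "B": 0.15, "C": 0.075, "M": 0.475}

# geometry of compounds that do NOT carry the active motif: an
# acceptor pair with a long separation, a donor pair with a short one,
# both hung away from the hydrophobic centre — the anti-motif arrangement
# (two acceptors far apart, two donors close together) that the activity
# model penalizes. Values per class in Å: (hba_sep, hba_centre_dist,
# hbd_sep, hbd_centre_dist).
CLASS_GEOMETRY = {
    "A": {"hba_sep": 9.4, "hba_out": 7.0, "hbd_sep": 2.6, "hbd_out": 3.0},
    "B": {"hba_sep": 9.6, "hba_out": 6.5, "hbd_sep": 2.4, "hbd_out": 3.4},
    "C": {"hba_sep": 9.3, "hba_out": 7.4, "hbd_sep": 2.8, "hbd_out": 2.8},
    "M": {"hba_sep": 9.5, "hba_out": 7.2, "hbd_sep": 2.6, "hbd_out": 3.2},
}

MOTIF_SECOND_RING_DIST = 6.6  # Å; actives are aromatic-rich (two ring systems)

# typical partial charges by role (e); feature charges are drawn uniformly
# from a range per compound — substituent effects make hydrogen-bond
# strengths vary continuously across a series, and that variation is what
# carries the planted activity signal through the field energies
CHARGE_BY_ROLE = {"ring": 0.02, "chain": 0.0}
CHARGE_RANGE = {"hba": (-0.62, -0.28), "hbd": (0.14, 0.36)}
RING2_RADIUS_RANGE = (1.25, 1.55)  # Å; ring compactness varies DRY depth


@dataclass
class GeneratorConfig:
    n_compounds: int = 40
    class_weights: dict = dc_field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    ic50_range: tuple = (0.0029, 20000.0)
    active_threshold: float = 160.0
    noise_sd: float = 0.3
    true_beta: dict | None = None  # label -> coefficient; None = auto-select
    motif_fraction: float = 0.5
    n_atoms_range: tuple = (15, 60)
    motif_jitter: float = 0.05  # Å, per-coordinate noise on motif atoms
    feature_jitter: float = 0.30  # Å, non-motif feature placement noise
    spacing: float = 0.5
    margin: float = 5.0
    bin_width: float = 0.4
    max_distance: float = 24.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class weights must sum to 1")
        lo, hi = self.ic50_range
        if not (0 < lo < hi):
            raise ValueError("ic50_range must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    seed: int
    classes: list = dc_field(default_factory=list)
    has_motif: list = dc_field(default_factory=list)
    feature_distances: list = dc_field(default_factory=list)  # per compound
    drivers: list = dc_field(default_factory=list)  # per-compound signal drivers
    true_beta: dict = dc_field(default_factory=dict)  # label -> coefficient
    intercept: float = 0.0
    noiseless_pic50: np.ndarray | None = None
    compound_ids: list = dc_field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "classes": self.classes,
            "has_motif": list(map(bool, self.has_motif)),
            "feature_distances": self.feature_distances,
            "drivers": self.drivers,
            "true_beta": self.true_beta,
            "intercept": self.intercept,
            "noiseless_pic50": (
                None if self.noiseless_pic50 is None
                else [float(v) for v in self.noiseless_pic50]
            ),
            "compound_ids": self.compound_ids,
        }


def motif_coordinates() -> np.ndarray:
    """3D embedding (classical MDS) of the built-in model-1 distance matrix.

    The printed matrix embeds in 3D to ~4e-3 Å; rows are (Hyd, HBA1, HBA2,
    HBD1, HBD2).
    """
    from .pharmacophore import builtin_models

    D = builtin_models()["model_1"].distances
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:3]
    return V[:, order] * np.sqrt(np.maximum(w[order], 0.0))


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(q)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


@dataclass
class _ClassTemplate:
    """Shared scaffold geometry of one compound class.

    Compounds of a class are this template plus small positional jitter —
    pairwise distances are drawn per class around the template geometry,
    the way congeneric series share a scaffold. Keeping the scaffold fixed
    within a class confines irrelevant correlogram variation to a few
    class-level patterns instead of hundreds of independent noise columns.
    """

    filler: np.ndarray  # (k, 3) skeleton atom positions
    filler_elements: list
    hba_dir: np.ndarray  # unit vector, anti-motif acceptor-pair placement
    hba_axis: np.ndarray
    hbd_dir: np.ndarray
    hbd_axis: np.ndarray
    motif_rotation: np.ndarray  # orientation of the planted motif
    ring2_dir: np.ndarray  # direction of the second ring in motif compounds


def _make_template(cls: str, n_filler: int, rng) -> _ClassTemplate:
    filler = []
    pos = np.array([1.4, 0.0, 0.0])  # walk starts at a ring atom
    envelope = 6.0
    els = []
    for _ in range(n_filler):
        for _ in range(20):
            cand = pos + 1.5 * _random_direction(rng)
            if np.linalg.norm(cand) <= envelope:
                break
        else:
            cand = pos * 0.8
        pos = cand
        filler.append(pos.copy())
        els.append("C" if rng.random() < 0.7 else "H")
    return _ClassTemplate(
        filler=np.array(filler).reshape(-1, 3),
        filler_elements=els,
        hba_dir=_random_direction(rng),
        hba_axis=_random_direction(rng),
        hbd_dir=_random_direction(rng),
        hbd_axis=_random_direction(rng),
        motif_rotation=_random_rotation(rng),
        ring2_dir=_random_direction(rng),
    )


def _class_templates(config, seed_sequence) -> dict:
    """Per-class scaffolds, deterministic for the dataset seed. Class
    scaffold sizes span the configured atom-count range."""
    rng = np.random.default_rng(seed_sequence)
    lo, hi = config.n_atoms_range
    span = hi - lo
    core = 11  # centre + ring (7) + 4 feature atoms
    sizes = {
        "A": int(lo + 0.35 * span), "B": int(lo + 0.75 * span),
        "C": int(lo + 0.55 * span), "M": int(lo + 0.10 * span),
    }
    return {
        cls: _make_template(cls, max(2, sizes.get(cls, lo + span // 2) - core), rng)
        for cls in config.class_weights
    }


def _build_compound(cid: str, cls: str, motif: bool, template: _ClassTemplate,
                    geom_rng, charge_rng, motif_jitter: float,
                    feature_jitter: float, scaffold_jitter: float = 0.12):
    """One pseudo-compound from its class template. Returns
    (Molecule3D, feature_distance_record, driver_record)."""
    elements, coords, charges, flags, bonds = [], [], [], [], []

    def add(el, xyz, q, fl=(), bond_to=None):
        elements.append(el)
        coords.append(np.asarray(xyz, float))
        charges.append(q + charge_rng.normal(0, 0.02))
        flags.append(frozenset(fl))
        if bond_to is not None:
            bonds.append((bond_to, len(elements) - 1, 1))
        return len(elements) - 1

    def draw_charge(kind):
        lo, hi = CHARGE_RANGE[kind]
        return float(charge_rng.uniform(lo, hi))

    # hydrophobic core: flagged centre + 6-carbon ring (shared by classes)
    centre = add("C", (0.0, 0.0, 0.0), CHARGE_BY_ROLE["ring"], ("hydrophobic",))
    ring = []
    for a in range(6):
        ang = 2 * math.pi * a / 6
        xyz = np.array([1.4 * math.cos(ang), 1.4 * math.sin(ang), 0.0])
        ring.append(add("C", xyz, CHARGE_BY_ROLE["ring"],
                        bond_to=ring[-1] if ring else centre))
    bonds.append((ring[-1], ring[0], 1))

    def add_feature(kind, el, xyz, name, q):
        nearest = min(ring, key=lambda i: np.linalg.norm(coords[i] - xyz))
        add(el, xyz, q, (kind,), bond_to=nearest)
        dist_record[name] = float(np.linalg.norm(xyz - coords[centre]))
        drivers.setdefault(f"q_{kind}", []).append(q)

    dist_record = {}
    drivers = {"motif": bool(motif)}
    if motif:
        X = motif_coordinates()
        pts = (X - X[0]) @ template.motif_rotation.T  # Hyd at the centre
        pts = pts + geom_rng.normal(0, motif_jitter, size=pts.shape)
        for name, kind, el, xyz in zip(
                ["HBA1", "HBA2", "HBD1", "HBD2"],
                ["hba", "hba", "hbd", "hbd"], ["O", "O", "N", "N"], pts[1:]):
            add_feature(kind, el, xyz, f"Hyd-{name}", draw_charge(kind))
        # second aromatic-like ring: actives are ring-rich; its compactness
        # (radius) varies per compound and modulates the hydrophobic field
        r2 = float(charge_rng.uniform(*RING2_RADIUS_RANGE))
        drivers["ring2_radius"] = r2
        ring2_centre = (MOTIF_SECOND_RING_DIST
                        + geom_rng.normal(0, motif_jitter)) * template.ring2_dir
        R2 = template.motif_rotation
        prev = first = None
        for a in range(6):
            ang = 2 * math.pi * a / 6
            xyz = (ring2_centre
                   + R2 @ np.array([r2 * math.cos(ang), r2 * math.sin(ang), 0.0])
                   + geom_rng.normal(0, scaffold_jitter, size=3))
            prev = add("C", xyz, CHARGE_BY_ROLE["ring"],
                       bond_to=prev if prev is not None else ring[0])
            if first is None:
                first = prev
        bonds.append((prev, first, 1))
        dist_record["Hyd-Ring2"] = float(np.linalg.norm(ring2_centre - coords[centre]))
    else:
        geom = CLASS_GEOMETRY[cls]
        for kind, el, tag, pdir, paxis in (
                ("hba", "O", "HBA", template.hba_dir, template.hba_axis),
                ("hbd", "N", "HBD", template.hbd_dir, template.hbd_axis)):
            sep = geom[f"{kind}_sep"] + geom_rng.normal(0, feature_jitter)
            out = geom[f"{kind}_out"] + geom_rng.normal(0, feature_jitter)
            pair_centre = coords[centre] + out * pdir
            for k, s in enumerate((-0.5, 0.5)):
                xyz = pair_centre + s * sep * paxis
                add_feature(kind, el, xyz, f"Hyd-{tag}{k + 1}", draw_charge(kind))
            dist_record[f"{tag}-{tag}"] = float(sep)

    # class scaffold skeleton with per-compound jitter
    anchor = ring[0]
    for el, xyz in zip(template.filler_elements, template.filler):
        anchor = add(el, xyz + geom_rng.normal(0, scaffold_jitter, size=3),
                     CHARGE_BY_ROLE["chain"], bond_to=anchor)

    # the stored pose is randomly rotated; descriptors are pose-independent
    Rpose = _random_rotation(geom_rng)
    mol = Molecule3D(compound_id=cid, elements=elements,
                     coords=np.array(coords) @ Rpose.T, charges=np.array(charges),
                     flags=flags, bonds=bonds)
    return mol, dist_record, drivers


def generate_molecules(config: GeneratorConfig):
    """Generate the pseudo-compound set. Returns (molecules, truth)."""
    if config.n_compounds < 5:
        raise ValueError("need at least 5 compounds")
    ss = np.random.SeedSequence(config.seed)
    geom_ss, charge_ss, label_ss, _noise_ss = ss.spawn(4)
    geom_rng = np.random.default_rng(geom_ss)
    charge_rng = np.random.default_rng(charge_ss)
    label_rng = np.random.default_rng(label_ss)
    templates = _class_templates(config, geom_ss.spawn(1)[0])

    classes = list(config.class_weights)
    probs = np.array([config.class_weights[c] for c in classes])
    truth = SyntheticTruth(seed=config.seed)
    molecules = []
    for i in range(config.n_compounds):
        cls = classes[int(label_rng.choice(len(classes), p=probs))]
        motif = bool(label_rng.random() < config.motif_fraction)
        cid = f"S{i + 1:03d}"
        mol, dists, drivers = _build_compound(
            cid, cls, motif, templates[cls], geom_rng, charge_rng,
            config.motif_jitter, config.feature_jitter)
        molecules.append(mol)
        truth.classes.append(cls)
        truth.has_motif.append(motif)
        truth.feature_distances.append(dists)
        truth.drivers.append(drivers)
        truth.compound_ids.append(cid)
    return molecules, truth


# blocks the activity model draws its informative variables from, with the
# sign of their contribution to pIC50: hydrophobic-anchored cross terms act
# favourably; paired donor-probe hotspots (two acceptor groups on the
# molecule) and short paired acceptor-probe hotspots act unfavourably
INFORMATIVE_BLOCKS = (
    ("DRY-DRY", +1, None),
    ("DRY-O", +1, None),
    ("DRY-N1", +1, None),
    ("DRY-TIP", +1, None),
    ("O-O", -1, (2.0, 4.4)),  # short-range donor pairs
    ("N1-N1", -1, None),
)

# bins below this node-node distance are grid-discretization artifacts
# (adjacent nodes in one well), never chemistry — excluded from the signal
MIN_SIGNAL_DISTANCE = 2.0
MIN_SIGNAL_CORRELATION = 0.2


def _block_drivers(truth: SyntheticTruth) -> dict:
    """Per-block continuous signal drivers the generator planted.

    Hydrogen-bond blocks are driven by the feature partial charges
    (substituent strength); hydrophobic/shape blocks by the second ring's
    compactness in motif-bearing compounds.
    """
    qa = np.array([sum(d.get("q_hba", [0])) for d in truth.drivers])
    qd = np.array([sum(d.get("q_hbd", [0])) for d in truth.drivers])
    qa_prod = np.array([float(np.prod(d.get("q_hba", [0]))) for d in truth.drivers])
    qd_prod = np.array([float(np.prod(d.get("q_hbd", [0]))) for d in truth.drivers])
    ring = np.array([
        (1.7 - d["ring2_radius"]) if d.get("motif") else 0.0 for d in truth.drivers
    ])
    return {
        "DRY-DRY": ring, "DRY-TIP": ring,
        "DRY-O": qd, "DRY-N1": qa,
        "O-O": qd_prod, "N1-N1": qa_prod,
    }


def _auto_select_beta(dm, truth: SyntheticTruth, min_support: float = 0.35):
    """Pick one variable per informative block: the column that best tracks
    the block's planted continuous driver (|correlation|), among columns
    populated in at least ``min_support`` of the compounds and at
    physically meaningful node separations. Blocks whose best column
    tracks its driver weaker than ``MIN_SIGNAL_CORRELATION`` are skipped.
    """
    X = dm.X.to_numpy()
    labels = list(dm.X.columns)
    drivers = _block_drivers(truth)
    chosen = {}
    for pair, sign, dist_window in INFORMATIVE_BLOCKS:
        driver = drivers[pair]
        if driver.std() == 0:
            continue
        windows = [dist_window, None] if dist_window is not None else [None]
        best_label, best_score = None, 0.0
        for window in windows:
            for j, lab in enumerate(labels):
                if not lab.startswith(pair + " "):
                    continue
                lo = float(lab.split("[")[1].split("–")[0])
                if lo < MIN_SIGNAL_DISTANCE:
                    continue
                if window is not None and not (window[0] <= lo < window[1]):
                    continue
                col = X[:, j]
                if np.mean(col != 0) < min_support or col.std() == 0:
                    continue
                score = abs(float(np.corrcoef(col, driver)[0, 1]))
                if score > best_score:
                    best_score, best_label = score, lab
            if best_label is not None:
                break
        if best_label is not None and best_score >= MIN_SIGNAL_CORRELATION:
            chosen[best_label] = sign
    return chosen


def generate_activities(molecules, truth: SyntheticTruth,
                        config: GeneratorConfig, descriptors=None):
    """Activities from a sparse linear model on the correlogram variables.

    noiseless pIC50 = intercept + sum(beta * x) over the compound's GRIND
    variables; the coefficients are ``config.true_beta`` if given, otherwise
    auto-selected (one variable per informative probe-pair block, signed)
    and affinely scaled so the noiseless values span the configured IC50
    range. Observed pIC50 adds Normal(0, noise_sd); IC50 is back-
    transformed and the active flag applied at the threshold.

    Returns ``(records, descriptor_matrix)``; the coefficient map and
    noiseless values are stored on ``truth``.
    """
    if [m.compound_id for m in molecules] != truth.compound_ids:
        raise ValueError("molecules do not match the provided truth")
    if descriptors is None:
        enc = GrindDescriptorizer(
            spacing=config.spacing, margin=config.margin,
            bin_width=config.bin_width, max_distance=config.max_distance)
        descriptors = descriptor_matrix(enc.describe(molecules))
    dm = descriptors
    X = dm.X.to_numpy()
    labels = list(dm.X.columns)

    if config.true_beta is not None:
        beta = dict(config.true_beta)
        missing = [l for l in beta if l not in labels]
        if missing:
            raise ValueError(f"true_beta refers to absent variables: {missing}")
        raw = np.zeros(len(molecules))
        for lab, b in beta.items():
            raw += b * X[:, labels.index(lab)]
        intercept = 0.0
        noiseless = raw
        final_beta = beta
    else:
        signs = _auto_select_beta(dm, truth)
        if not signs:
            raise RuntimeError("no informative correlogram variable found")
        # equal signed contributions on the standardized scale, then an
        # affine map into the potency range
        raw = np.zeros(len(molecules))
        w = {}
        for lab, sign in signs.items():
            col = X[:, labels.index(lab)]
            w[lab] = sign / col.std()
            raw += w[lab] * col
        p_lo = -math.log10(config.ic50_range[1] * 1e-6) + 0.1
        p_hi = -math.log10(config.ic50_range[0] * 1e-6) - 0.1
        span = raw.max() - raw.min()
        a = (p_hi - p_lo) / span if span > 0 else 0.0
        b0 = p_lo - a * raw.min()
        noiseless = a * raw + b0
        final_beta = {lab: a * wj for lab, wj in w.items()}
        intercept = b0

    ss = np.random.SeedSequence(config.seed)
    _, _, _, noise_ss = ss.spawn(4)
    noise_rng = np.random.default_rng(noise_ss)
    observed = noiseless + noise_rng.normal(0, config.noise_sd, size=len(molecules))

    clogp_mean = {"A": -6.5, "B": 7.0, "C": -6.0, "M": 2.5}
    records = []
    for i, mol in enumerate(molecules):
        ic50_um = 10.0 ** (6.0 - observed[i])
        clogp = clogp_mean.get(truth.classes[i], 2.0) + noise_rng.normal(0, 1.0)
        records.append(make_record(mol.compound_id, truth.classes[i], ic50_um,
                                   round(clogp, 3),
                                   active_threshold_um=config.active_threshold))
    truth.true_beta = {k: float(v) for k, v in final_beta.items()}
    truth.intercept = float(intercept)
    truth.noiseless_pic50 = noiseless
    return records, dm


def generate_dataset(config: GeneratorConfig):
    """molecules + activity records + truth + descriptor matrix, one call."""
    molecules, truth = generate_molecules(config)
    records, dm = generate_activities(molecules, truth, config)
    return molecules, records, truth, dm


def generate_screening_dataset(n: int = 40, prevalence_active: float = 0.9,
                               prevalence_inactive: float = 0.1,
                               active_fraction: float = 0.5,
                               seed: int = 0):
    """Planted-motif screening benchmark (no field computation).

    Each compound is a single conformer; actives carry the model-1 motif
    with probability ``prevalence_active``, inactives with
    ``prevalence_inactive``. Returns a list of
    ``(compound_id, [conformer], is_active)`` triples ready for
    :func:`grindqsar.pharmacophore.screen`.
    """
    ss = np.random.SeedSequence(seed)
    geom_ss, charge_ss, label_ss, _ = ss.spawn(4)
    geom_rng = np.random.default_rng(geom_ss)
    charge_rng = np.random.default_rng(charge_ss)
    label_rng = np.random.default_rng(label_ss)
    templates = _class_templates(GeneratorConfig(seed=seed), geom_ss.spawn(1)[0])
    dataset = []
    for i in range(n):
        active = bool(label_rng.random() < active_fraction)
        prev = prevalence_active if active else prevalence_inactive
        motif = bool(label_rng.random() < prev)
        mol, _, _ = _build_compound(
            f"V{i + 1:03d}", "M", motif, templates["M"],
            geom_rng=geom_rng, charge_rng=charge_rng,
            motif_jitter=0.05, feature_jitter=0.3)
        dataset.append((mol.compound_id, [mol], active))
    return dataset
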