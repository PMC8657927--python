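"""Grid-independent descriptors (GRIND): node discretization + correlograms.

Each probe field is reduced to a small set of favourable nodes (energy
below the probe cutoff, then a greedy energy/spread trade-off in the style
of the AMANDA discretization). Node pairs are encoded into auto- and
cross-correlogram variables: for every probe pair and distance bin the
descriptor holds the largest node-node energy product (MACC2 rule), or the
consistently-selected variant (CLACC) that prefers, among near-maximal
pairs, the product that is most consistent across the dataset. Because
only inter-node distances enter, the descriptors are independent of the
molecule's pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .mif import DEFAULT_PROBES, ProbeEnergyField, compute_all_fields

__all__ = [
    "Node",
    "CorrelogramDescriptor",
    "PROBE_PAIRS",
    "filter_nodes",
    "nodes_from_fields",
    "encode_macc",
    "encode_clacc",
    "descriptor_matrix",
    "DescriptorMatrix",
    "variable_label",
    "GrindDescriptorizer",
]

# auto blocks first, then cross blocks — fixed variable ordering
PROBE_PAIRS = (
    "DRY-DRY", "O-O", "N1-N1", "TIP-TIP",
    "DRY-O", "DRY-N1", "DRY-TIP", "O-N1", "O-TIP", "N1-TIP",
)

DEFAULT_BIN_WIDTH = 0.4
DEFAULT_MAX_DISTANCE = 24.0


@dataclass(frozen=True)
class Node:
    probe: str
    position: tuple
    energy: float


def filter_nodes(field: ProbeEnergyField, max_nodes: int = 100,
                 spread_weight: float = 0.5) -> list:
    """Discretize a probe field into at most ``max_nodes`` nodes.

    Grid points with energy above the probe's cutoff are discarded. The
    remaining candidates are selected greedily: the first node is the
    global energy minimum, and each subsequent pick maximizes

        (1 - w) * |E| / |E|_max  +  w * d_min / d_max

    where d_min is the candidate's distance to the nearest selected node
    and d_max normalizes over the current candidates. Ties break on the
    lowest candidate index (deterministic).
    """
    energy = field.energy.ravel()
    keep = energy <= field.probe.energy_cutoff
    if not keep.any():
        return []
    pts = field.grid.points()[keep]
    e = energy[keep]
    abs_e = np.abs(e)
    e_norm = abs_e / abs_e.max()

    first = int(np.argmin(e))
    selected = [first]
    dmin = np.linalg.norm(pts - pts[first], axis=1)
    dmin[first] = -np.inf  # never re-pick
    while len(selected) < min(max_nodes, len(e)):
        finite = dmin[dmin > -np.inf]
        dmax = finite.max() if finite.size else 1.0
        if dmax <= 0:
            dmax = 1.0
        score = (1.0 - spread_weight) * e_norm + spread_weight * (dmin / dmax)
        score[dmin == -np.inf] = -np.inf
        best = int(np.argmax(score))
        if score[best] == -np.inf:
            break
        selected.append(best)
        d_new = np.linalg.norm(pts - pts[best], axis=1)
        dmin = np.minimum(dmin, d_new)
        dmin[best] = -np.inf
    return [Node(field.probe.name, tuple(pts[i]), float(e[i])) for i in selected]


def nodes_from_fields(fields: dict, max_nodes: int = 100,
                      spread_weight: float = 0.5) -> dict:
    return {
        name: filter_nodes(fld, max_nodes=max_nodes, spread_weight=spread_weight)
        for name, fld in fields.items()
    }


@dataclass
class CorrelogramDescriptor:
    """GRIND variables for one compound.

    ``values`` maps (probe_pair, bin_index) -> non-negative energy product;
    bin b covers the half-open interval [b*w, (b+1)*w). ``provenance`` maps
    each nonzero variable to the contributing node pair.
    """

    compound_id: str
    bin_width: float = DEFAULT_BIN_WIDTH
    max_distance: float = DEFAULT_MAX_DISTANCE
    values: dict = dc_field(default_factory=dict)
    provenance: dict = dc_field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return int(np.ceil(self.max_distance / self.bin_width - 1e-9))


def variable_label(pair: str, bin_index: int, bin_width: float) -> str:
    lo = bin_index * bin_width
    hi = (bin_index + 1) * bin_width
    return f"{pair} [{lo:.1f}–{hi:.1f} Å]"


def _pair_blocks(nodes_by_probe):
    """Yield (pair_name, positions_i, energies_i, positions_j, energies_j, auto)."""
    for pair in PROBE_PAIRS:
        p, q = pair.split("-")
        ni = nodes_by_probe.get(p, [])
        nj = nodes_by_probe.get(q, [])
        pi = np.array([n.position for n in ni]).reshape(-1, 3)
        ei = np.array([n.energy for n in ni])
        pj = np.array([n.position for n in nj]).reshape(-1, 3)
        ej = np.array([n.energy for n in nj])
        yield pair, pi, ei, pj, ej, p == q


def _qualifying_pairs(pi, ei, pj, ej, auto, bin_width, max_distance):
    """All node pairs with their bin and product; self-pairs excluded in
    auto blocks (i < j)."""
    if len(ei) == 0 or len(ej) == 0:
        return np.empty((0,), int), np.empty((0,)), [], np.empty((0,))
    from scipy.spatial.distance import cdist

    d = cdist(pi, pj)
    prod = ei[:, None] * ej[None, :]
    if auto:
        iu = np.triu_indices(len(ei), k=1)
        d = d[iu]
        prod = prod[iu]
        idx_pairs = list(zip(iu[0].tolist(), iu[1].tolist()))
    else:
        ii, jj = np.meshgrid(np.arange(len(ei)), np.arange(len(ej)), indexing="ij")
        d = d.ravel()
        prod = prod.ravel()
        idx_pairs = list(zip(ii.ravel().tolist(), jj.ravel().tolist()))
    ok = d < max_distance
    bins = np.floor(d[ok] / bin_width).astype(int)
    return bins, prod[ok], [p for p, m in zip(idx_pairs, ok) if m], d[ok]


def encode_macc(nodes_by_probe: dict, bin_width: float = DEFAULT_BIN_WIDTH,
                max_distance: float = DEFAULT_MAX_DISTANCE,
                compound_id: str = "") -> CorrelogramDescriptor:
    """MACC2 encoding: per probe pair and distance bin, the maximum
    node-node energy product (two favourable nodes -> positive value)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    desc = CorrelogramDescriptor(compound_id=compound_id, bin_width=bin_width,
                                 max_distance=max_distance)
    for pair, pi, ei, pj, ej, auto in _pair_blocks(nodes_by_probe):
        out = _qualifying_pairs(pi, ei, pj, ej, auto, bin_width, max_distance)
        bins, prods, idx_pairs, dists = out
        for b in np.unique(bins):
            sel = np.where(bins == b)[0]
            k = sel[np.argmax(prods[sel])]
            desc.values[(pair, int(b))] = float(prods[k])
            desc.provenance[(pair, int(b))] = {
                "nodes": idx_pairs[k],
                "distance": float(dists[k]),
                "energies": (float(ei[idx_pairs[k][0]]), float(ej[idx_pairs[k][1]])),
            }
    return desc


def encode_clacc(nodes_by_probe_list, bin_width: float = DEFAULT_BIN_WIDTH,
                 max_distance: float = DEFAULT_MAX_DISTANCE,
                 compound_ids=None, rel_window: float = 0.9,
                 max_sweeps: int = 10) -> list:
    """Consistently-selected correlogram encoding (CLACC-style).

    Starts from the MACC2 vectors. For each variable, every compound may
    re-choose its contributing node pair among pairs whose product is
    within ``rel_window`` of that compound's bin maximum; choices are
    swept (at most ``max_sweeps`` times, or until stable) to minimize the
    variable's coefficient of variation across compounds. Values never
    exceed the compound's MACC2 value for the same bin.
    """
    if len(nodes_by_probe_list) < 2:
        raise ValueError("CLACC needs at least 2 compounds")
    if compound_ids is None:
        compound_ids = [str(i) for i in range(len(nodes_by_probe_list))]
    descs = [
        encode_macc(nb, bin_width=bin_width, max_distance=max_distance, compound_id=cid)
        for nb, cid in zip(nodes_by_probe_list, compound_ids)
    ]
    # candidate products per compound per variable
    candidates = [dict() for _ in descs]
    for c, nb in enumerate(nodes_by_probe_list):
        for pair, pi, ei, pj, ej, auto in _pair_blocks(nb):
            bins, prods, idx_pairs, dists = _qualifying_pairs(
                pi, ei, pj, ej, auto, bin_width, max_distance)
            for b in np.unique(bins):
                sel = np.where(bins == b)[0]
                vmax = prods[sel].max()
                cand = sorted(
                    (float(prods[k]) for k in sel if prods[k] >= rel_window * vmax),
                    reverse=True,
                )
                candidates[c][(pair, int(b))] = cand

    variables = sorted({v for c in candidates for v in c})
    for var in variables:
        holders = [c for c in range(len(descs)) if var in candidates[c]]
        if len(holders) < 2:
            continue
        current = {c: descs[c].values[var] for c in holders}
        for _ in range(max_sweeps):
            changed = False
            for c in holders:
                others = [current[o] for o in holders if o != c]
                best_v, best_cv = current[c], None
                for v in candidates[c][var]:
                    vals = np.array(others + [v])
                    mean = vals.mean()
                    cv = vals.std() / abs(mean) if mean != 0 else np.inf
                    if best_cv is None or cv < best_cv - 1e-15:
                        best_cv, best_v = cv, v
                if best_v != current[c]:
                    current[c] = best_v
                    changed = True
            if not changed:
                break
        for c in holders:
            descs[c].values[var] = current[c]
    return descs


@dataclass
class DescriptorMatrix:
    """Dense compounds-by-variables table with the dropped-column record."""

    X: pd.DataFrame  # rows: compound ids, columns: variable labels
    mask: np.ndarray  # over the full (pair, bin) grid; True = kept
    all_labels: list
    bin_width: float
    max_distance: float

    def to_csv(self, path):
        self.X.to_csv(path, float_format="%.10g")

    def mask_to_json(self):
        return {
            "bin_width": self.bin_width,
            "max_distance": self.max_distance,
            "all_labels": self.all_labels,
            "mask": self.mask.astype(int).tolist(),
        }


def descriptor_matrix(descriptors, drop_zero: bool = True) -> DescriptorMatrix:
    """Assemble correlogram descriptors into a dense matrix.

    All-zero columns are dropped (recorded in ``mask``). Variable labels
    carry the probe pair and the distance interval, e.g.
    ``"DRY-N1 [7.6–8.0 Å]"``.
    """
    if not descriptors:
        raise ValueError("no descriptors")
    bw = descriptors[0].bin_width
    md = descriptors[0].max_distance
    for d in descriptors:
        if d.bin_width != bw or d.max_distance != md:
            raise ValueError("mixed binning across compounds")
    n_bins = descriptors[0].n_bins
    all_vars = [(pair, b) for pair in PROBE_PAIRS for b in range(n_bins)]
    all_labels = [variable_label(p, b, bw) for p, b in all_vars]
    M = np.zeros((len(descriptors), len(all_vars)))
    col = {v: k for k, v in enumerate(all_vars)}
    for i, d in enumerate(descriptors):
        for v, val in d.values.items():
            if v in col:
                M[i, col[v]] = val
    mask = M.any(axis=0) if drop_zero else np.ones(len(all_vars), bool)
    df = pd.DataFrame(
        M[:, mask],
        index=[d.compound_id for d in descriptors],
        columns=[l for l, m in zip(all_labels, mask) if m],
    )
    return DescriptorMatrix(X=df, mask=mask, all_labels=all_labels,
                            bin_width=bw, max_distance=md)


class GrindDescriptorizer(BaseEstimator, TransformerMixin):
    """Molecules -> GRIND correlogram matrix, as a scikit-learn transformer.

    Parameters
    ----------
    spacing, margin : grid geometry, Å.
    bin_width, max_distance : correlogram binning, Å.
    encoder : 'macc2' (per-compound maximum product) or 'clacc'
        (dataset-consistent selection).
    max_nodes, spread_weight : node discretization controls.
    canonicalize : compute fields in the molecule's canonical frame so the
        output is independent of input pose.

    After ``fit`` the kept variable labels are in ``feature_names_`` and the
    full-grid retention mask in ``mask_``.
    """

    def __init__(self, spacing: float = 0.5, margin: float = 5.0,
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 max_distance: float = DEFAULT_MAX_DISTANCE,
                 encoder: str = "macc2", max_nodes: int = 100,
                 spread_weight: float = 0.5, canonicalize: bool = True):
        self.spacing = spacing
        self.margin = margin
        self.bin_width = bin_width
        self.max_distance = max_distance
        self.encoder = encoder
        self.max_nodes = max_nodes
        self.spread_weight = spread_weight
        self.canonicalize = canonicalize

    def describe(self, molecules) -> list:
        """Full CorrelogramDescriptor objects (with provenance)."""
        nodes = []
        ids = []
        for mol in molecules:
            fields, _ = compute_all_fields(
                mol, spacing=self.spacing, margin=self.margin,
                canonicalize=self.canonicalize)
            nodes.append(nodes_from_fields(
                fields, max_nodes=self.max_nodes, spread_weight=self.spread_weight))
            ids.append(mol.compound_id)
        if self.encoder == "clacc" and len(molecules) >= 2:
            return encode_clacc(nodes, bin_width=self.bin_width,
                                max_distance=self.max_distance, compound_ids=ids)
        if self.encoder not in ("macc2", "clacc"):
            raise ValueError("encoder must be 'macc2' or 'clacc'")
        return [
            encode_macc(nb, bin_width=self.bin_width,
                        max_distance=self.max_distance, compound_id=cid)
            for nb, cid in zip(nodes, ids)
        ]

    def fit(self, X, y=None):
        descs = self.describe(X)
        dm = descriptor_matrix(descs)
        self.mask_ = dm.mask
        self.all_labels_ = dm.all_labels
        self.feature_names_ = list(dm.X.columns)
        self.n_features_in_ = len(X)
        return self

    def transform(self, X):
        descs = self.describe(X)
        dm = descriptor_matrix(descs, drop_zero=False)
        if not hasattr(self, "mask_"):
            raise RuntimeError("GrindDescriptorizer is not fitted")
        return dm.X.to_numpy()[:, self.mask_]

    def fit_transform(self, X, y=None):
        descs = self.describe(X)
        dm = descriptor_matrix(descs)
        self.mask_ = dm.mask
        self.all_labels_ = dm.all_labels
        self.feature_names_ = list(dm.X.columns)
        self.n_features_in_ = len(X)
        return dm.X.to_numpy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
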