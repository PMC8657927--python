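"""PLS modelling of GRIND variables against pIC50.

The regression core is PLS1 (delegated to scikit-learn's NIPALS-based
``PLSRegression``), centered by default and optionally unit-variance
scaled — GRIND variables share an energy-product scale, so centering-only
is the convention. Model quality is reported as training R², the
cross-validated Q² = 1 - PRESS / SS_tot (leave-one-out, or seeded
leave-many-out groups) and SDEP = sqrt(PRESS / n). Fractional factorial
design (FFD) variable selection removes variables whose exclusion improves
cross-validated error more than appended dummy variables do.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "PLSQsar",
    "CVResult",
    "FFDResult",
    "FFDSelector",
    "fit_pls",
    "cross_validate",
    "select_lv",
    "ffd_select",
    "coefficient_correlogram",
]


class PLSQsar(BaseEstimator, RegressorMixin):
    """PLS1 regressor with QSAR-flavoured reporting.

    Parameters
    ----------
    n_components : number of latent variables (capped at min(n-1, p)).
    scale : unit-variance scale the X columns (centering always happens).

    Fitted attributes include ``coef_`` / ``intercept_`` on the original
    variable scale, the score/weight/loading factorization
    (``x_weights_``, ``x_loadings_``, ``x_scores_``, ``y_loadings_``),
    the centering/scaling vectors and the training ``r2_``.
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2D with one row per y value")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("missing or non-finite values are not allowed")
        if np.std(y) == 0:
            raise ValueError("y has zero variance")
        n, p = X.shape
        lv = int(min(self.n_components, n - 1, p))
        if lv < 1:
            raise ValueError("cannot fit with fewer than 1 latent variable")
        pls = PLSRegression(n_components=lv, scale=self.scale)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # y residual may become tiny
            pls.fit(X, y)
        self.n_components_ = lv
        self._pls = pls
        self.coef_ = pls.coef_.ravel()
        # intercept on the raw-X scale: y_mean - x_mean . coef
        self.intercept_ = float(np.mean(y) - X.mean(axis=0) @ self.coef_)
        self.x_weights_ = pls.x_weights_
        self.x_loadings_ = pls.x_loadings_
        self.x_scores_ = pls.x_scores_
        self.y_loadings_ = pls.y_loadings_
        self.x_mean_ = pls._x_mean
        self.x_std_ = pls._x_std
        self.y_mean_ = float(np.mean(y))
        yhat = self.predict(X)
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        self.r2_ = 1.0 - ss_res / ss_tot
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        return self.coef_ @ X.T + self.intercept_ if X.ndim == 1 else X @ self.coef_ + self.intercept_


def fit_pls(X, y, n_latent: int = 2, scale: bool = False) -> PLSQsar:
    """Fit a PLS1 model; see :class:`PLSQsar`."""
    return PLSQsar(n_components=n_latent, scale=scale).fit(X, y)


@dataclass
class CVResult:
    q2: float
    sdep: float
    press: float
    predictions: np.ndarray
    scheme: str


def _lmo_groups(n: int, k: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i : i + k] for i in range(0, n, k)]


def _center_scale(X, y, scale):
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    if scale:
        x_std = X.std(axis=0, ddof=1)
        x_std = np.where(x_std < 1e-12, 1.0, x_std)
        Xc = Xc / x_std
    else:
        x_std = np.ones(X.shape[1])
    return Xc, y - y_mean, x_mean, x_std, y_mean


def _pls1_coef(Xc, yc, n_components):
    """NIPALS PLS1 regression vector in the centered/scaled space.

    Lightweight path used by cross-validation loops and FFD row models;
    algebraically the same PLS1 sequence as the full estimator.
    """
    X = Xc.copy()
    y = yc.copy()
    W, P, Q = [], [], []
    for _ in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = (X.T @ t) / tt
        q = (y @ t) / tt
        X -= np.outer(t, p)
        y -= q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    if not W:
        return np.zeros(Xc.shape[1])
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    return Wm @ np.linalg.solve(Pm.T @ Wm, qv)


def _fast_press(X, y, n_components, folds, scale):
    """PRESS of a PLS1 model over the given CV folds (internal fast path)."""
    n = len(y)
    press = 0.0
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        Xc, yc, xm, xs, ym = _center_scale(X[mask], y[mask], scale)
        a = min(n_components, mask.sum() - 1, X.shape[1])
        b = _pls1_coef(Xc, yc, a)
        pred = ((X[fold] - xm) / xs) @ b + ym
        press += float(((y[fold] - pred) ** 2).sum())
    return press


def cross_validate(X, y, n_latent: int = 2, scheme: str = "loo", k: int = 5,
                   seed: int = 0, scale: bool = False) -> CVResult:
    """Cross-validated Q² and SDEP.

    ``scheme='loo'`` refits n models leaving one compound out;
    ``scheme='lmo'`` partitions the compounds into ceil(n/k) seeded random
    disjoint groups (the paper-style leave-five-out uses k=5).
    Q² = 1 - PRESS / SS_tot(centered y), SDEP = sqrt(PRESS / n).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 compounds for cross-validation")
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "lmo":
        if k >= n:
            raise ValueError("LMO group size must be smaller than n")
        folds = _lmo_groups(n, k, np.random.default_rng(seed))
    else:
        raise ValueError("scheme must be 'loo' or 'lmo'")
    pred = np.empty(n)
    for fold in folds:
        mask = np.ones(n, bool)
        mask[fold] = False
        Xc, yc, xm, xs, ym = _center_scale(X[mask], y[mask], scale)
        a = min(n_latent, int(mask.sum()) - 1, X.shape[1])
        b = _pls1_coef(Xc, yc, a)
        pred[fold] = ((X[fold] - xm) / xs) @ b + ym
    press = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return CVResult(q2=1.0 - press / ss_tot, sdep=float(np.sqrt(press / n)),
                    press=press, predictions=pred, scheme=scheme)


def select_lv(X, y, max_lv: int = 5, scheme: str = "loo", k: int = 5,
              seed: int = 0, scale: bool = False):
    """Latent-variable choice: maximize Q² (ties -> fewer LVs).

    Returns ``(chosen_lv, table)`` where the table lists (LV, Q², R²) for
    LV = 1..max_lv. Warns when R² - Q² of the chosen model exceeds 0.3,
    the usual overfitting red flag.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    rows = []
    for lv in range(1, max_lv + 1):
        cv = cross_validate(X, y, n_latent=lv, scheme=scheme, k=k, seed=seed, scale=scale)
        r2 = fit_pls(X, y, n_latent=lv, scale=scale).r2_
        rows.append({"lv": lv, "q2": cv.q2, "r2": r2, "sdep": cv.sdep})
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["q2"].idxmax(), "lv"])
    row = table[table["lv"] == chosen].iloc[0]
    if row["r2"] - row["q2"] > 0.3:
        warnings.warn(
            f"R² - Q² = {row['r2'] - row['q2']:.2f} exceeds 0.3 at LV={chosen}; "
            "the model may be overfitted",
            UserWarning,
        )
    return chosen, table


@dataclass
class FFDResult:
    retained: np.ndarray  # boolean mask over the input variables
    cycle_stats: list  # per cycle: dict(q2, r2, sdep, n_retained)
    n_cycles: int

    @property
    def support_(self):
        return self.retained


def _ffd_design(n_vars: int, rng) -> np.ndarray:
    """Two-level fractional factorial design (boolean inclusion matrix).

    Columns are taken from a Sylvester Hadamard matrix (excluding the
    all-ones column) with randomized column assignment and random sign
    flips per column, giving exactly balanced, mutually orthogonal
    inclusion patterns — the large effects of strong variables then do not
    leak noise into other variables' effect estimates.
    """
    from scipy.linalg import hadamard

    size = 4
    while size - 1 < n_vars:
        size *= 2
    H = hadamard(size)
    cols = 1 + rng.permutation(size - 1)[:n_vars]
    signs = rng.choice([-1, 1], size=n_vars)
    D = (H[:, cols] * signs) > 0
    # foldover: adding the complementary fraction de-aliases main effects
    # from pairwise interactions
    return np.vstack([D, ~D])


def ffd_select(X, y, n_latent: int = 2, cycles: int = 2,
               dummy_fraction: float = 0.2, seed: int = 0,
               scale: bool = False) -> FFDResult:
    """Fractional-factorial-design variable selection.

    Per cycle: append ceil(dummy_fraction * p) dummy (placebo) variables;
    build an orthogonal two-level inclusion design over real + dummy
    variables (a Hadamard fraction: between p and 2p rows, every column
    exactly balanced); for each design row fit a PLS model on the included
    real variables and record its leave-one-out SDEP; each variable's
    effect is mean SDEP over rows excluding it minus mean SDEP over rows
    including it. A real variable is removed when its effect is more
    negative than the mean absolute dummy effect — its exclusion helps
    more than noise. Survivors feed the next cycle. Deterministic for a
    fixed seed.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p0 = X.shape
    if p0 < 10:
        raise ValueError("FFD needs at least 10 variables")
    rng = np.random.default_rng(seed)
    retained = np.ones(p0, bool)
    cycle_stats = []
    loo = [np.array([i]) for i in range(n)]
    for cycle in range(cycles):
        idx = np.where(retained)[0]
        p = len(idx)
        if p < 2:
            break
        n_dummy = int(np.ceil(dummy_fraction * p))
        design = _ffd_design(p + n_dummy, rng)
        n_rows = design.shape[0]
        sdep = np.full(n_rows, np.nan)
        for r in range(n_rows):
            inc = idx[design[r, :p]]
            if len(inc) == 0:
                continue
            press = _fast_press(X[:, inc], y, n_latent, loo, scale)
            sdep[r] = np.sqrt(press / n)
        ok = np.isfinite(sdep)
        effects = np.empty(p + n_dummy)
        for j in range(p + n_dummy):
            inc_rows = ok & design[:, j]
            exc_rows = ok & ~design[:, j]
            effects[j] = sdep[exc_rows].mean() - sdep[inc_rows].mean()
        dummy_level = np.abs(effects[p:]).mean() if n_dummy else 0.0
        remove = effects[:p] < -dummy_level
        if remove.all():
            raise RuntimeError(
                "FFD removed every variable; effects: "
                + np.array2string(effects[:p], precision=3)
            )
        retained[idx[remove]] = False
        kept = np.where(retained)[0]
        cv = cross_validate(X[:, kept], y, n_latent=n_latent, seed=seed, scale=scale)
        r2 = fit_pls(X[:, kept], y, n_latent=n_latent, scale=scale).r2_
        cycle_stats.append({
            "cycle": cycle + 1, "q2": cv.q2, "r2": r2, "sdep": cv.sdep,
            "n_retained": int(retained.sum()),
        })
    return FFDResult(retained=retained, cycle_stats=cycle_stats, n_cycles=len(cycle_stats))


class FFDSelector(BaseEstimator, SelectorMixin):
    """scikit-learn selector wrapper around :func:`ffd_select`."""

    def __init__(self, n_components: int = 2, cycles: int = 2,
                 dummy_fraction: float = 0.2, seed: int = 0,
                 scale: bool = False):
        self.n_components = n_components
        self.cycles = cycles
        self.dummy_fraction = dummy_fraction
        self.seed = seed
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, float)
        self.result_ = ffd_select(
            X, y, n_latent=self.n_components, cycles=self.cycles,
            dummy_fraction=self.dummy_fraction, seed=self.seed, scale=self.scale)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.result_.retained


_LABEL_RE = re.compile(r"^(?P<pair>[A-Z0-9]+-[A-Z0-9]+) \[(?P<lo>[\d.]+)[–-](?P<hi>[\d.]+) Å\]$")


def coefficient_correlogram(model: PLSQsar, labels) -> pd.DataFrame:
    """Signed PLS coefficients per labeled GRIND variable.

    Rows are grouped by probe pair and ordered by distance bin; positive
    coefficients mark variables that raise predicted pIC50 (direct
    correlation), negative ones inverse correlation.
    """
    coef = np.asarray(model.coef_, float).ravel()
    labels = list(labels)
    if len(labels) != coef.size:
        raise ValueError("labels and coefficients have different lengths")
    rows = []
    for lab, c in zip(labels, coef):
        m = _LABEL_RE.match(lab)
        if m:
            rows.append({"label": lab, "pair": m["pair"], "lo": float(m["lo"]),
                         "hi": float(m["hi"]), "coefficient": c})
        else:
            rows.append({"label": lab, "pair": "", "lo": np.nan, "hi": np.nan,
                         "coefficient": c})
    df = pd.DataFrame(rows)
    df = df.sort_values(["pair", "lo"], kind="stable").reset_index(drop=True)
    return df
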