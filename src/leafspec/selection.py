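"""CARS-SPA hybrid wavelength selection with a PLS1 cross-validation core.

CARS (competitive adaptive reweighted sampling) runs a Monte-Carlo loop: at
each run a PLS model fitted on a random sample subset scores every retained
wavelength by its normalized absolute regression coefficient; an
exponentially decreasing function caps how many survive, and adaptive
reweighted sampling (weighted draws with replacement) thins them further.
The run whose retained set achieves the lowest cross-validated RMSE wins.

SPA (successive projections algorithm) then prunes collinearity: starting
from each candidate wavelength it grows a chain by repeatedly taking the
column with the largest norm after orthogonal projection onto the
complement of the chain's span, and the (start, length) subset with minimal
multiple-linear-regression RMSE is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["PLSModel", "CARSRun", "CARSTrace", "SelectedWavelengths",
           "pls_fit", "pls_rmsecv", "cars_select", "spa_select", "cars_spa",
           "load_reference_wavelengths"]


# ---------------------------------------------------------------------------
# PLS1 core
# ---------------------------------------------------------------------------

def _pls1_paths(Xc: np.ndarray, yc: np.ndarray, max_components: int):
    """NIPALS PLS1 on centred data; returns coefficient vectors for every
    component count 1..k (columns of B, shape (p, k))."""
    X = Xc.copy()
    y = yc.copy()
    p = X.shape[1]
    W, P, Q, Rv = [], [], [], []
    B = np.zeros((p, 0))
    b_cur = np.zeros(p)
    for _ in range(max_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-24:
            break
        pl = X.T @ t / tt
        q = (y @ t) / tt
        X = X - np.outer(t, pl)
        y = y - q * t
        # r_k = w_k - sum_{j<k} (p_j . w_k) r_j  gives B_k = B_{k-1} + q_k r_k
        r = w.copy()
        for pj, rj in zip(P, Rv):
            r -= (pj @ w) * rj
        W.append(w); P.append(pl); Q.append(q); Rv.append(r)
        b_cur = b_cur + q * r
        B = np.column_stack([B, b_cur])
    return B


@dataclass
class PLSModel:
    """Fitted PLS1 regression over a fixed variable subset."""

    n_components: int
    coef: np.ndarray          # (p,) regression coefficients on raw scale
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) @ self.coef + self.y_mean


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Mean-centred PLS1 with the requested number of components
    (capped at min(p, n-1) with a warning-free silent cap)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    k = max(1, min(n_components, p, n - 1))
    xm, ym = X.mean(axis=0), y.mean()
    B = _pls1_paths(X - xm, y - ym, k)
    if B.shape[1] == 0:
        return PLSModel(0, np.zeros(p), xm, ym)
    return PLSModel(B.shape[1], B[:, -1], xm, ym)


def _kfold_indices(n: int, folds: int, seed) -> list:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def pls_rmsecv(X: np.ndarray, y: np.ndarray, max_components: int = 10,
               folds: int = 5, seed: int = 0):
    """Seeded k-fold RMSECV curve over component counts.

    Returns ``(best_n_components, rmsecv_curve)`` where the curve has one
    entry per component count 1..max and the best is its argmin.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < folds or folds < 2:
        raise ValueError("need n >= folds >= 2")
    kmax = max(1, min(max_components, p, n - 1 - int(np.ceil(n / folds))))
    press = np.zeros(kmax)
    counts = np.zeros(kmax)
    for test_idx in _kfold_indices(n, folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        Xtr, ytr = X[mask], y[mask]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        B = _pls1_paths(Xtr - xm, ytr - ym, kmax)
        kk = B.shape[1]
        if kk == 0:
            press += ((y[test_idx] - ym) ** 2).sum()
            counts += len(test_idx)
            continue
        pred = (X[test_idx] - xm) @ B + ym        # (n_test, kk)
        err2 = ((pred - y[test_idx][:, None]) ** 2).sum(axis=0)
        press[:kk] += err2
        press[kk:] += err2[-1]                    # curve flat past extracted comps
        counts += len(test_idx)
    curve = np.sqrt(press / counts)
    return int(np.argmin(curve) + 1), curve


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

@dataclass
class CARSRun:
    run: int
    ratio: float
    retained: np.ndarray
    rmsecv: float
    n_components: int


@dataclass
class CARSTrace:
    runs: list
    winner: int                 # index into runs
    edf_a: float
    edf_k: float
    terminated_early: bool = False

    @property
    def selected(self) -> np.ndarray:
        return self.runs[self.winner].retained


def edf_ratio(i: int, p: int, n_runs: int):
    """Exponentially decreasing retention ratio r_i = a exp(-k i) with the
    endpoints r_1 = 1 (all variables) and r_N = 2/p (two variables)."""
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    return a * np.exp(-k * i), a, k


def edf_retained(i: int, p: int, n_runs: int) -> int:
    """ceil(r_i * p) with a guard against rounding the exact endpoints up."""
    ratio, _, _ = edf_ratio(i, p, n_runs)
    return int(np.ceil(ratio * p - 1e-9))


def cars_select(X: np.ndarray, y: np.ndarray, n_runs: int = 50,
                subset_fraction: float = 0.8, folds: int = 5,
                max_components: int = 10, seed: int = 0) -> CARSTrace:
    """Competitive adaptive reweighted sampling over the columns of X.

    Each run fits PLS on a Monte-Carlo subset of the samples restricted to
    the currently retained wavelengths, keeps the top ``ceil(r_i * p)``
    wavelengths by normalized |coefficient| (EDF cap), thins them by
    weighted sampling with replacement (ARS), and records the 5-fold RMSECV
    of the retained set.  The run with minimal RMSECV wins.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if p < 10 or n < 10:
        raise ValueError("CARS needs at least 10 samples and 10 variables")
    rng = np.random.default_rng(seed)
    retained = np.arange(p)
    runs = []
    _, a, k_const = edf_ratio(1, p, n_runs)
    early = False
    n_sub = max(2, int(np.ceil(subset_fraction * n)))
    for i in range(1, n_runs + 1):
        sub = rng.choice(n, size=n_sub, replace=False)
        ncomp = max(1, min(max_components, len(retained), n_sub - 1))
        model = pls_fit(X[np.ix_(sub, retained)], y[sub], ncomp)
        w = np.abs(model.coef)
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()
        ratio, _, _ = edf_ratio(i, p, n_runs)
        cap = min(len(retained), edf_retained(i, p, n_runs))
        top = np.argsort(-w, kind="stable")[:cap]
        retained = retained[np.sort(top)]
        w_top = w[np.sort(top)]
        w_top = w_top / w_top.sum()
        # adaptive reweighted sampling: weighted draws with replacement
        draws = rng.choice(len(retained), size=cap, replace=True, p=w_top)
        retained = retained[np.unique(draws)]
        if len(retained) < 2:
            early = True
            break
        best_k, curve = pls_rmsecv(X[:, retained], y,
                                   max_components=min(max_components, len(retained)),
                                   folds=folds, seed=seed + i)
        runs.append(CARSRun(i, float(ratio), retained.copy(),
                            float(curve[best_k - 1]), best_k))
    if not runs:
        raise RuntimeError("CARS terminated before completing a single run")
    winner = int(np.argmin([r.rmsecv for r in runs]))
    return CARSTrace(runs, winner, a, k_const, terminated_early=early)


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

@dataclass
class SelectedWavelengths:
    indices: np.ndarray          # indices into the full wavelength grid,
                                 # in selection (chain) order
    wavelengths: np.ndarray      # nm
    rmse: float                  # validation RMSE of the winning subset
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selected indices must be unique")

    def __len__(self):
        return len(self.indices)


def projection_chain(X: np.ndarray, start: int, max_vars: int) -> tuple:
    """Successive-projections chain from a starting column.

    Returns ``(order, residual_norms)``: at each step the column with the
    largest norm after orthogonal projection onto the complement of the
    span of the already-selected columns; truncates when the best residual
    norm drops below 1e-10.
    """
    Xr = np.asarray(X, float).copy()
    p = Xr.shape[1]
    order = [start]
    norms = [float(np.linalg.norm(Xr[:, start]))]
    available = np.ones(p, dtype=bool)
    available[start] = False
    for _ in range(min(max_vars, p) - 1):
        q = Xr[:, order[-1]]
        nq = np.linalg.norm(q)
        if nq < 1e-10:
            break
        q = q / nq
        Xr = Xr - np.outer(q, q @ Xr)           # deflate: MGS step
        res = np.linalg.norm(Xr, axis=0)
        res[~available] = -1.0
        nxt = int(np.argmax(res))
        if res[nxt] < 1e-10:
            break
        order.append(nxt)
        norms.append(float(res[nxt]))
        available[nxt] = False
    return np.array(order), np.array(norms)


def _mlr_rmse(Xtr, ytr, Xval, yval) -> float:
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    pred = np.column_stack([np.ones(len(Xval)), Xval]) @ coef
    return float(np.sqrt(np.mean((pred - yval) ** 2)))


def spa_select(X: np.ndarray, y: np.ndarray, candidate_indices,
               max_vars: int = 20, min_vars: int = 1, folds: int = 5,
               seed: int = 0,
               validation: tuple | None = None) -> SelectedWavelengths:
    """SPA forward selection over the candidate columns of X.

    Every candidate start grows a projection chain; every (start, length)
    prefix is scored by multiple-linear-regression RMSE, either by seeded
    k-fold cross-validation on (X, y) (default) or on an explicit
    ``validation=(X_val, y_val)`` hold-out.  The minimal-RMSE subset wins;
    ties break toward fewer variables, then the earlier start.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    cand = np.asarray(candidate_indices, dtype=int)
    n = len(y)
    max_vars = min(max_vars, len(cand), n - 2)
    if max_vars < 1:
        raise ValueError("max_vars must allow at least one variable")
    Xc = X[:, cand]
    if validation is None:
        fold_idx = _kfold_indices(n, folds, seed)
    best = None
    min_vars = max(1, min(min_vars, max_vars))
    for s in range(len(cand)):
        order, _ = projection_chain(Xc, s, max_vars)
        for length in range(min_vars, len(order) + 1):
            cols = order[:length]
            if validation is not None:
                Xval, yval = validation
                rmse = _mlr_rmse(Xc[:, cols], y,
                                 np.asarray(Xval, float)[:, cand][:, cols], yval)
            else:
                sse, cnt = 0.0, 0
                for te in fold_idx:
                    mask = np.ones(n, dtype=bool)
                    mask[te] = False
                    r = _mlr_rmse(Xc[np.ix_(mask, cols)], y[mask],
                                  Xc[np.ix_(te, cols)], y[te])
                    sse += r ** 2 * len(te)
                    cnt += len(te)
                rmse = float(np.sqrt(sse / cnt))
            key = (rmse, length, s)
            if best is None or key < best[0]:
                best = (key, cols)
    (rmse, _, _), cols = best
    idx = cand[cols]
    return SelectedWavelengths(idx, np.asarray(idx, float), rmse,
                               provenance={"method": "SPA", "max_vars": int(max_vars),
                                           "folds": folds, "seed": seed})


def cars_spa(X: np.ndarray, y: np.ndarray, wavelengths: np.ndarray,
             n_runs: int = 50, subset_fraction: float = 0.8, folds: int = 5,
             max_components: int = 10, max_vars: int = 20, min_vars: int = 1,
             seed: int = 0, validation: tuple | None = None):
    """CARS then SPA; returns ``(SelectedWavelengths, CARSTrace)``.

    ``wavelengths`` maps column indices to nm for reporting.  Run on
    training rows only unless the caller deliberately passes more.
    """
    trace = cars_select(X, y, n_runs=n_runs, subset_fraction=subset_fraction,
                        folds=folds, max_components=max_components, seed=seed)
    sel = spa_select(X, y, trace.selected, max_vars=max_vars,
                     min_vars=min_vars, folds=folds, seed=seed,
                     validation=validation)
    wl = np.asarray(wavelengths, float)[sel.indices]
    sel = SelectedWavelengths(sel.indices, wl, sel.rmse,
                              provenance={**sel.provenance,
                                          "cars_runs": n_runs,
                                          "cars_winner_size": len(trace.selected),
                                          "seed": seed})
    return sel, trace


def load_reference_wavelengths() -> SelectedWavelengths:
    """The published 15-wavelength reference selection for the NSS stage,
    shipped as a fixture for comparisons on real-data workflows."""
    text = resources.files("leafspec").joinpath("data/paper_wavelengths.json").read_text()
    d = json.loads(text)
    wl = np.asarray(d["wavelengths_nm"], float)
    idx = (wl - d["grid_start_nm"]).astype(int)
    return SelectedWavelengths(idx, wl, d["rmse"], provenance={"source": d["source"]})
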