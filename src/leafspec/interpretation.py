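"""Shapley-value attribution for fitted spectral regressors.

The value of a coalition S is the model prediction with the features
outside S replaced by a fixed baseline vector (training-set column means by
default).  Feature i's Shapley value is the weighted average of its
marginal contribution f(S u {i}) - f(S) over all subsets S, with the
classical weight |S|! (p-|S|-1)! / p!.  The exact enumerator evaluates all
2^p coalitions per sample (feasible for the 15-wavelength models used
here); a seeded permutation-sampling estimator covers larger p and reports
a Monte-Carlo standard error per value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

__all__ = ["ShapExplanation", "shapley_exact", "shapley_sampled",
           "rank_and_export"]

_EXACT_LIMIT = 16


@dataclass
class ShapExplanation:
    phi: np.ndarray                  # (n, p) Shapley values, units of the target
    baseline_value: float            # model prediction on the all-baseline point
    predictions: np.ndarray          # (n,) full-coalition predictions
    feature_names: list = field(default_factory=list)
    standard_errors: np.ndarray | None = None
    method: str = "exact"

    def ranking(self) -> np.ndarray:
        """Feature order by decreasing mean |phi|; ties keep feature order."""
        mean_abs = np.abs(self.phi).mean(axis=0)
        return np.argsort(-mean_abs, kind="stable")


def _coalition_matrix(x: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """All 2^p masked versions of one sample (row index = coalition bitmask)."""
    p = len(x)
    masks = (np.arange(2 ** p)[:, None] >> np.arange(p)) & 1
    return np.where(masks.astype(bool), x[None, :], baseline[None, :])


def shapley_exact(predict_fn, X_explain: np.ndarray,
                  baseline: np.ndarray) -> ShapExplanation:
    """Exact Shapley values by coalition enumeration with cached evaluations.

    ``predict_fn`` maps an (m, p) array to (m,) predictions (e.g.
    ``bundle.predict``).  Requires p <= 16.
    """
    X = np.atleast_2d(np.asarray(X_explain, float))
    baseline = np.asarray(baseline, float)
    n, p = X.shape
    if p > _EXACT_LIMIT:
        raise ValueError(
            f"p = {p} > {_EXACT_LIMIT}: exact enumeration infeasible, "
            "use shapley_sampled")
    # weights indexed by |S| (S excludes i)
    w = np.array([factorial(s) * factorial(p - s - 1) / factorial(p)
                  for s in range(p)])
    bits = np.arange(2 ** p)
    popcount = np.zeros(2 ** p, dtype=int)
    for i in range(p):
        popcount += (bits >> i) & 1

    phi = np.zeros((n, p))
    preds = np.zeros(n)
    base_val = float(np.asarray(predict_fn(baseline[None, :])).ravel()[0])
    for s_idx in range(n):
        vals = np.asarray(predict_fn(_coalition_matrix(X[s_idx], baseline))).ravel()
        preds[s_idx] = vals[-1]
        for i in range(p):
            without = bits[(bits >> i) & 1 == 0]
            with_i = without | (1 << i)
            contrib = vals[with_i] - vals[without]
            phi[s_idx, i] = float(np.sum(w[popcount[without]] * contrib))
    return ShapExplanation(phi, base_val, preds, method="exact")


def shapley_sampled(predict_fn, X_explain: np.ndarray, baseline: np.ndarray,
                    n_permutations: int = 2048, seed: int = 0,
                    batch_permutations: int = 32) -> ShapExplanation:
    """Permutation-sampling Shapley estimator with per-value standard errors.

    For each sampled feature ordering, features are switched from baseline
    to their observed values one at a time; the prediction increments are
    unbiased draws of the marginal contributions.  Whole staircases of
    masked samples are batched into single model calls, so estimators over
    models with per-call overhead (forests, networks) stay fast.
    """
    X = np.atleast_2d(np.asarray(X_explain, float))
    baseline = np.asarray(baseline, float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    base_val = float(np.asarray(predict_fn(baseline[None, :])).ravel()[0])
    preds = np.asarray(predict_fn(X)).ravel()

    phi = np.zeros((n, p))
    phi_sq = np.zeros((n, p))
    done = 0
    while done < n_permutations:
        chunk = min(batch_permutations, n_permutations - done)
        orders = np.vstack([rng.permutation(p) for _ in range(chunk)])
        # cumulative inclusion masks: (chunk, p+1, p)
        masks = np.zeros((chunk, p + 1, p), dtype=bool)
        for c in range(chunk):
            for k, feat in enumerate(orders[c]):
                masks[c, k + 1] = masks[c, k]
                masks[c, k + 1, feat] = True
        tiled = np.where(masks[:, :, None, :], X[None, None, :, :],
                         baseline[None, None, None, :])
        vals = np.asarray(
            predict_fn(tiled.reshape(-1, p))).reshape(chunk, p + 1, n)
        deltas = np.diff(vals, axis=1)              # (chunk, p, n)
        for c in range(chunk):
            np.add.at(phi.T, orders[c], deltas[c])
            np.add.at(phi_sq.T, orders[c], deltas[c] ** 2)
        done += chunk
    phi /= n_permutations
    var = phi_sq / n_permutations - phi ** 2
    se = np.sqrt(np.clip(var, 0.0, None) / n_permutations)
    return ShapExplanation(phi, base_val, preds, standard_errors=se,
                           method="sampled")


def rank_and_export(expl: ShapExplanation, wavelengths: np.ndarray,
                    feature_values: np.ndarray | None = None):
    """Rank features by mean |phi| and build a beeswarm-ready long table.

    Returns ``(ranking DataFrame, beeswarm DataFrame)``.  The ranking holds
    one row per wavelength with mean |phi| and, when feature values are
    given, the sign association corr(feature value, phi).
    """
    wavelengths = np.asarray(wavelengths, float)
    n, p = expl.phi.shape
    if len(wavelengths) != p:
        raise ValueError("wavelength list does not match phi columns")
    order = expl.ranking()
    mean_abs = np.abs(expl.phi).mean(axis=0)

    sign_assoc = np.full(p, np.nan)
    if feature_values is not None:
        fv = np.asarray(feature_values, float)
        for j in range(p):
            if np.std(fv[:, j]) > 0 and np.std(expl.phi[:, j]) > 0:
                sign_assoc[j] = np.corrcoef(fv[:, j], expl.phi[:, j])[0, 1]
    ranking = pd.DataFrame({
        "rank": np.arange(1, p + 1),
        "wavelength_nm": wavelengths[order],
        "mean_abs_shap": mean_abs[order],
        "value_shap_correlation": sign_assoc[order],
    })
    rows = []
    if feature_values is None:
        feature_values = np.full((n, p), np.nan)
    for s in range(n):
        for j in range(p):
            rows.append((s, wavelengths[j], feature_values[s, j], expl.phi[s, j]))
    beeswarm = pd.DataFrame(rows, columns=["sample", "wavelength_nm",
                                           "feature_value", "shap_value"])
    return ranking, beeswarm
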