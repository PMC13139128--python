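"""Model evaluation: R2 / RMSE / RPD metrics, residual diagnostics and the
cross-stage validation protocol.

Two RPD variants are reported.  ``rpd_conventional`` is the usual
sd(observed; n-1 denominator) / RMSE used throughout spectroscopy
(< 1.4 poor, 1.4-2.0 moderate, > 2.0 strong).  ``rpd_paper`` follows the
source formula verbatim, which places the *predicted* deviations from the
observed mean in the numerator: sqrt(sum (yhat_i - ybar)^2 / (n-1)) / RMSE.
The two coincide when predictions are perfect; for any other model they
differ, and both are kept so results remain comparable either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RegressionMetrics", "ResidualDiagnostics", "compute_metrics",
           "residual_diagnostics", "cross_stage_validate"]


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    rpd_paper: float
    rpd_conventional: float
    n: int

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "rpd_paper": self.rpd_paper,
                "rpd_conventional": self.rpd_conventional, "n": self.n}


@dataclass
class ResidualDiagnostics:
    residuals: np.ndarray
    sd: float
    within_1sd_fraction: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    normal_curve: np.ndarray         # fitted-normal ordinates at bin centres
    qq_theoretical: np.ndarray
    qq_observed: np.ndarray


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> RegressionMetrics:
    """R2 = 1 - SSE/SST, RMSE = sqrt(mean squared error), plus both RPD forms."""
    y = np.asarray(y_true, float).ravel()
    yhat = np.asarray(y_pred, float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y_true and y_pred lengths differ")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in predictions or observations")
    ybar = y.mean()
    sst = float(((y - ybar) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values have zero variance; R2 undefined")
    sse = float(((y - yhat) ** 2).sum())
    rmse = float(np.sqrt(sse / n))
    rpd_paper = float(np.sqrt(((yhat - ybar) ** 2).sum() / (n - 1)) / rmse) \
        if rmse > 0 else np.inf
    sd_y = float(np.sqrt(sst / (n - 1)))
    rpd_conv = sd_y / rmse if rmse > 0 else np.inf
    return RegressionMetrics(1.0 - sse / sst, rmse, rpd_paper, rpd_conv, n)


def residual_diagnostics(y_true: np.ndarray, y_pred: np.ndarray,
                         bins: int = 20) -> ResidualDiagnostics:
    """Residual spread, +-1-sd coverage (boundary inclusive), histogram with
    fitted-normal ordinates, and normal Q-Q pairs (Blom plotting positions)."""
    y = np.asarray(y_true, float).ravel()
    yhat = np.asarray(y_pred, float).ravel()
    if len(y) < 10:
        raise ValueError("need at least 10 samples for diagnostics")
    r = y - yhat
    mu = r.mean()
    sd = float(r.std(ddof=1))
    within = float(np.mean(np.abs(r - mu) <= sd)) if sd > 0 else 1.0
    counts, edges = np.histogram(r, bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    curve = stats.norm.pdf(centres, loc=mu, scale=sd if sd > 0 else 1.0)
    n = len(r)
    probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)      # Blom
    qq_theo = stats.norm.ppf(probs)
    # standardize against the plotting-position quantiles' own spread, so an
    # exactly normal (affine-transformed) residual set lands on the identity
    sd_theo = float(qq_theo.std(ddof=1))
    qq_obs = (np.sort(r) - mu) * (sd_theo / sd) if sd > 0 else np.zeros(n)
    return ResidualDiagnostics(r, sd, within, counts, edges, curve,
                               qq_theo, qq_obs)


def cross_stage_validate(bundle, X_external: np.ndarray, y_external: np.ndarray):
    """Evaluate a fitted model on an external (different-stage) dataset.

    Returns ``(RegressionMetrics, ResidualDiagnostics, slope)`` where slope
    is the ordinary-least-squares slope of predicted vs observed.
    """
    X = np.asarray(X_external, float)
    if X.shape[1] != bundle.n_features:
        raise ValueError(
            f"external data has {X.shape[1]} bands but the model was trained "
            f"on {bundle.n_features} "
            f"({np.asarray(bundle.feature_wavelengths).tolist() if bundle.feature_wavelengths is not None else 'unknown'})")
    y = np.asarray(y_external, float)
    pred = bundle.predict(X)
    metrics = compute_metrics(y, pred)
    diag = residual_diagnostics(y, pred)
    slope = float(np.polyfit(y, pred, 1)[0])
    return metrics, diag, slope
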