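"""Spectral preprocessing: Savitzky-Golay smoothing and second derivative,
multiplicative scatter correction (MSC), standard normal variate (SNV), and
per-wavelength Pearson correlation screening.

SG filtering replaces each point by the value (or second derivative) of a
local least-squares polynomial fit over a moving window.  Interior points
use the classical convolution weights; within half a window of either band
edge the polynomial is re-fitted on the truncated window so no reflected or
padded data ever enters the result.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datasets import SpectraMatrix

__all__ = ["SGKernel", "MSCModel", "sg_smooth", "second_derivative",
           "msc", "snv", "pearson_by_wavelength"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SGKernel:
    """Savitzky-Golay window: ``2*half_width + 1`` points, polynomial fit.

    ``deriv_order`` 0 smooths; 2 yields the second derivative scaled by
    the squared grid spacing.
    """

    half_width: int = 7
    poly_order: int = 2
    deriv_order: int = 0

    def __post_init__(self):
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.window <= self.poly_order:
            raise ValueError(
                f"window {self.window} must exceed polynomial order {self.poly_order}")
        if self.deriv_order > self.poly_order:
            raise ValueError("derivative order cannot exceed polynomial order")

    @property
    def window(self) -> int:
        return 2 * self.half_width + 1


def _sg_transform(X: np.ndarray, kernel: SGKernel, delta: float) -> np.ndarray:
    """Apply SG filtering with truncated-window re-fit at the band edges."""
    n, m = X.shape
    w = kernel.half_width
    if m < kernel.window:
        raise ValueError(
            f"window of {kernel.window} points is wider than the {m}-point spectrum")
    out = savgol_filter(X, kernel.window, kernel.poly_order, axis=1,
                        deriv=kernel.deriv_order, delta=delta, mode="interp")
    # re-fit truncated windows at both edges, per-point
    t = np.arange(m, dtype=float)
    scale = math.factorial(kernel.deriv_order) / delta ** kernel.deriv_order \
        if kernel.deriv_order else 1.0
    for k in list(range(w)) + list(range(m - w, m)):
        lo, hi = max(0, k - w), min(m, k + w + 1)
        tt = t[lo:hi] - t[k]
        order = min(kernel.poly_order, hi - lo - 1)
        if order < kernel.deriv_order:
            continue  # too few points to estimate the derivative; keep interp value
        V = np.vander(tt, order + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, X[:, lo:hi].T, rcond=None)
        out[:, k] = coef[kernel.deriv_order] * scale
    return out


def sg_smooth(X: SpectraMatrix, kernel: SGKernel | None = None) -> SpectraMatrix:
    """Savitzky-Golay smoothing (default 15-point window, order 2)."""
    kernel = kernel or SGKernel()
    if kernel.deriv_order != 0:
        raise ValueError("sg_smooth requires deriv_order=0; use second_derivative")
    return X.copy(reflectance=_sg_transform(X.reflectance, kernel, delta=1.0))


def second_derivative(X: SpectraMatrix, kernel: SGKernel | None = None) -> SpectraMatrix:
    """SG second derivative in reflectance / nm^2; requires a uniform grid."""
    kernel = kernel or SGKernel(deriv_order=2)
    if kernel.deriv_order != 2:
        raise ValueError("second_derivative requires deriv_order=2")
    steps = np.diff(X.wavelengths)
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError(
            "second derivative needs a uniform wavelength grid; resample first")
    delta = float(steps[0])
    return X.copy(reflectance=_sg_transform(X.reflectance, kernel, delta=delta))


@dataclass
class MSCModel:
    """Fitted multiplicative scatter correction: per-sample slope and offset
    against a reference spectrum."""

    reference: np.ndarray
    slopes: np.ndarray
    offsets: np.ndarray


def msc(X: SpectraMatrix, reference="mean"):
    """Multiplicative scatter correction.

    Each spectrum R_i is regressed on the reference, R_i = k_i * ref + b_i,
    and corrected as (R_i - b_i) / k_i.  ``reference`` is either an m-vector
    (e.g. the training-set mean, to avoid test leakage) or the string
    ``"mean"`` for the mean spectrum of X itself.

    Returns ``(corrected SpectraMatrix, MSCModel)``.
    """
    R = X.reflectance
    ref = R.mean(axis=0) if isinstance(reference, str) else np.asarray(reference, float)
    if ref.shape != (X.n_wavelengths,):
        raise ValueError("reference length does not match wavelength grid")
    if not np.all(np.isfinite(ref)) or np.ptp(ref) == 0:
        raise ValueError("MSC reference must be finite and non-constant")
    ref_c = ref - ref.mean()
    slopes = (R - R.mean(axis=1, keepdims=True)) @ ref_c / (ref_c @ ref_c)
    bad = np.flatnonzero(np.abs(slopes) < 1e-12)
    if bad.size:
        raise ValueError(
            f"MSC slope is zero for sample(s) {[X.sample_ids[i] for i in bad]}")
    offsets = R.mean(axis=1) - slopes * ref.mean()
    corrected = (R - offsets[:, None]) / slopes[:, None]
    return X.copy(reflectance=corrected), MSCModel(ref, slopes, offsets)


def snv(X: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: row-wise centre and scale by the sample
    standard deviation (m-1 denominator)."""
    if X.n_wavelengths < 2:
        raise ValueError("SNV needs at least two wavelengths")
    R = X.reflectance
    sd = R.std(axis=1, ddof=1)
    # relative floor: a numerically-constant row has sd at rounding level
    floor = 1e-12 * np.maximum(1.0, np.abs(R).max(axis=1))
    bad = np.flatnonzero(sd <= floor)
    if bad.size:
        raise ValueError(
            f"constant spectrum for sample(s) {[X.sample_ids[i] for i in bad]}")
    return X.copy(reflectance=(R - R.mean(axis=1, keepdims=True)) / sd[:, None])


def pearson_by_wavelength(X: SpectraMatrix, y: np.ndarray) -> np.ndarray:
    """Pearson correlation between each wavelength column and the response.

    Zero-variance columns are reported as r = 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation screen")
    R = X.reflectance
    Rc = R - R.mean(axis=0)
    yc = y - y.mean()
    denom_x = np.sqrt((Rc ** 2).sum(axis=0))
    denom_y = np.sqrt((yc ** 2).sum())
    r = np.zeros(X.n_wavelengths)
    ok = denom_x > 0
    if not np.all(ok):
        log.warning("zero-variance columns at %d wavelength(s); r set to 0",
                    int((~ok).sum()))
    if denom_y == 0:
        raise ValueError("response has zero variance")
    r[ok] = (Rc[:, ok].T @ yc) / (denom_x[ok] * denom_y)
    return np.clip(r, -1.0, 1.0)
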