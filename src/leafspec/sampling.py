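"""Outlier screening and train/test partitioning.

Outliers are flagged by squared Mahalanobis distance in a PCA score space
(enough components for 95 % of the spectral variance, capped) against a
chi-square quantile.  Partitioning uses SPXY: Kennard-Stone max-min
selection on a joint distance that normalizes Euclidean spectral distance
and absolute nitrogen distance by their respective maxima, so the training
set spans both the spectral and the response space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.decomposition import PCA

from .datasets import SpectraMatrix

__all__ = ["OutlierReport", "DataSplit", "mahalanobis_outliers", "spxy_split",
           "random_split"]

log = logging.getLogger(__name__)


@dataclass
class OutlierReport:
    flagged: np.ndarray          # integer row indices
    flagged_ids: list
    distances_sq: np.ndarray     # squared Mahalanobis distance per sample
    threshold: float             # chi-square quantile on the squared distance
    n_components: int


@dataclass
class DataSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    method: str = "SPXY"
    seed: int | None = None

    def __post_init__(self):
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")


def mahalanobis_outliers(X: SpectraMatrix, variance_kept: float = 0.95,
                         max_pcs: int = 10, alpha: float = 0.025) -> OutlierReport:
    """Flag spectral outliers by Mahalanobis distance in PCA score space.

    Samples whose squared distance exceeds the chi-square(1 - alpha, k)
    quantile (k = retained components) are flagged in a single pass.
    ``alpha=0`` flags nothing.
    """
    n = X.n_samples
    if n <= max_pcs + 1:
        raise ValueError(f"need more than {max_pcs + 1} samples, got {n}")
    R = X.reflectance
    k_cap = min(max_pcs, n - 1, X.n_wavelengths)
    pca = PCA(n_components=k_cap, svd_solver="full")
    scores = pca.fit_transform(R)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_kept) + 1)
    k = min(k, k_cap)
    # drop components with numerically zero variance (singular directions)
    var = pca.explained_variance_[:k]
    keep = var > max(var[0], 1e-300) * 1e-12
    if not np.all(keep):
        log.warning("dropping %d singular PCA component(s)", int((~keep).sum()))
        k = int(keep.sum())
    scores = scores[:, :k]
    d2 = ((scores / np.sqrt(pca.explained_variance_[:k])) ** 2).sum(axis=1)
    threshold = np.inf if alpha <= 0 else float(stats.chi2.ppf(1 - alpha, df=k))
    flagged = np.flatnonzero(d2 > threshold)
    return OutlierReport(flagged, [X.sample_ids[i] for i in flagged],
                         d2, threshold, k)


def _joint_distance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = squareform(pdist(X, metric="euclidean"))
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 or my == 0:
        raise ValueError("degenerate data: all spectra or all responses identical")
    return dx / mx + dy / my


def spxy_split(X: SpectraMatrix, y: np.ndarray,
               train_fraction: float = 0.6) -> DataSplit:
    """SPXY partitioning (Kennard-Stone on the joint X-Y distance).

    The training set is seeded with the most distant pair, then grown by
    repeatedly adding the sample whose minimum joint distance to the current
    training set is largest, until ``round(train_fraction * n)`` samples.
    Ties break toward the lowest sample index, so the split is fully
    deterministic and row-permutation robust up to those ties.
    """
    y = np.asarray(y, dtype=float)
    n = X.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 2), n - 1)
    D = _joint_distance(X.reflectance, y)

    i, j = np.unravel_index(np.argmax(D), D.shape)  # argmax -> lowest flat index on ties
    selected = [min(i, j), max(i, j)]
    in_train = np.zeros(n, dtype=bool)
    in_train[selected] = True
    # min distance of every sample to the current training set
    dmin = np.minimum(D[selected[0]], D[selected[1]])
    dmin[selected] = -np.inf
    while len(selected) < n_train:
        nxt = int(np.argmax(dmin))
        selected.append(nxt)
        in_train[nxt] = True
        dmin = np.minimum(dmin, D[nxt])
        dmin[nxt] = -np.inf
    train = np.array(sorted(selected))
    test = np.flatnonzero(~in_train)
    return DataSplit(train, test, method="SPXY")


def random_split(n: int, train_fraction: float = 0.6, seed: int = 0) -> DataSplit:
    """Seeded random baseline split with the same rounding rule as SPXY."""
    n_train = int(np.floor(train_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return DataSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]),
                     method="random", seed=seed)
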