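"""Model/Results front-end tying the whole inversion pipeline together.

:class:`NitrogenInversion` is constructed from spectra and nitrogen values
(or from the synthetic generator) and its :meth:`fit` runs the full chain --
outlier screening, Savitzky-Golay smoothing + second derivative, SPXY
partitioning, CARS-SPA wavelength selection, and one or more regressors --
returning a :class:`NitrogenInversionResults` that carries the fitted
bundles, their train/test metrics, diagnostics, Shapley attribution and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, interpretation, preprocess, sampling, selection, synth
from .datasets import SpectraMatrix
from .models import (CNNConfig, PSOConfig, cnn_fit, derive_seed, pso_cnn_fit,
                     rf_fit, svm_fit)

__all__ = ["InversionSettings", "NitrogenInversion", "NitrogenInversionResults"]

ALL_MODELS = ("rf", "svm", "cnn", "pso-cnn")


@dataclass
class InversionSettings:
    """Tunable knobs of the analysis chain (defaults follow the study)."""

    sg_half_width: int = 7             # 15-point window
    sg_poly_order: int = 2
    outlier_alpha: float = 0.025
    outlier_max_pcs: int = 10
    train_fraction: float = 0.6
    cars_runs: int = 50
    cars_subset_fraction: float = 0.8
    cars_max_components: int = 10
    spa_max_vars: int = 20
    spa_min_vars: int = 8              # two pooling stages need >= 8 inputs
    cv_folds: int = 5
    paper_mode: bool = False           # selection/fitness use the held-out test set
    cnn: CNNConfig = field(default_factory=CNNConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)


class NitrogenInversion:
    """Leaf-nitrogen inversion model over hyperspectral reflectance.

    Parameters
    ----------
    spectra : SpectraMatrix
    nitrogen : array of % dry-mass nitrogen, one value per spectrum
    settings : InversionSettings, optional
    """

    def __init__(self, spectra: SpectraMatrix, nitrogen, settings=None):
        self.spectra = spectra
        self.nitrogen = np.asarray(nitrogen, float)
        if len(self.nitrogen) != spectra.n_samples:
            raise ValueError("nitrogen length does not match spectra")
        self.settings = settings or InversionSettings()

    @classmethod
    def from_synthetic(cls, stage="NSS", n=None, seed=0, settings=None,
                       config=None):
        ds = synth.generate_dataset(stage=stage, n=n, seed=seed, config=config)
        return cls(ds.spectra, ds.nitrogen, settings=settings)

    # -- pipeline stages ----------------------------------------------------
    def preprocessed(self) -> SpectraMatrix:
        """SG smoothing followed by the SG second derivative."""
        s = self.settings
        sm = preprocess.sg_smooth(
            self.spectra, preprocess.SGKernel(s.sg_half_width, s.sg_poly_order, 0))
        return preprocess.second_derivative(
            sm, preprocess.SGKernel(s.sg_half_width, s.sg_poly_order, 2))

    def fit(self, models=ALL_MODELS, seed: int = 0) -> "NitrogenInversionResults":
        s = self.settings
        report = sampling.mahalanobis_outliers(
            self.spectra, max_pcs=s.outlier_max_pcs, alpha=s.outlier_alpha)
        keep = np.setdiff1d(np.arange(self.spectra.n_samples), report.flagged)
        spectra = self.spectra.take(keep)
        nitrogen = self.nitrogen[keep]

        sgsd = preprocess.second_derivative(
            preprocess.sg_smooth(
                spectra, preprocess.SGKernel(s.sg_half_width, s.sg_poly_order, 0)),
            preprocess.SGKernel(s.sg_half_width, s.sg_poly_order, 2))

        split = sampling.spxy_split(sgsd, nitrogen, train_fraction=s.train_fraction)
        Xtr_full = sgsd.reflectance[split.train_indices]
        ytr = nitrogen[split.train_indices]
        Xte_full = sgsd.reflectance[split.test_indices]
        yte = nitrogen[split.test_indices]

        validation = (Xte_full, yte) if s.paper_mode else None
        sel, trace = selection.cars_spa(
            Xtr_full, ytr, sgsd.wavelengths,
            n_runs=s.cars_runs, subset_fraction=s.cars_subset_fraction,
            folds=s.cv_folds, max_components=s.cars_max_components,
            max_vars=min(s.spa_max_vars, len(ytr) - 2),
            min_vars=s.spa_min_vars,
            seed=derive_seed("select", seed), validation=validation)

        # design matrices use wavelength order so convolution locality is
        # spectral adjacency
        band_order = np.sort(sel.indices)
        sel = selection.SelectedWavelengths(
            band_order, sgsd.wavelengths[band_order], sel.rmse, sel.provenance)
        Xtr = Xtr_full[:, band_order]
        Xte = Xte_full[:, band_order]
        bundles = {}
        for kind in models:
            if kind == "rf":
                b = rf_fit(Xtr, ytr, seed=derive_seed("rf", seed))
            elif kind == "svm":
                b = svm_fit(Xtr, ytr, folds=s.cv_folds, seed=derive_seed("svm", seed))
            elif kind == "cnn":
                cfg = dataclasses.replace(s.cnn, seed=derive_seed("cnn", seed))
                b = cnn_fit(Xtr, ytr, config=cfg)
            elif kind == "pso-cnn":
                base_cnn = dataclasses.replace(s.cnn, seed=derive_seed("cnn", seed))
                b = pso_cnn_fit(Xtr, ytr,
                                eval_set=(Xte, yte) if s.paper_mode else None,
                                cnn_config=base_cnn, pso_config=s.pso,
                                paper_mode=s.paper_mode,
                                seed=derive_seed("pso-cnn", seed))
            else:
                raise ValueError(f"unknown model kind {kind!r}")
            b.feature_wavelengths = sel.wavelengths
            bundles[kind] = b

        return NitrogenInversionResults(
            model=self, seed=seed, outliers=report, split=split,
            selected=sel, cars_trace=trace, bundles=bundles,
            Xtr=Xtr, ytr=ytr, Xte=Xte, yte=yte,
            retained_indices=keep,
            refl_tr=spectra.reflectance[np.ix_(split.train_indices, band_order)],
            refl_te=spectra.reflectance[np.ix_(split.test_indices, band_order)])


@dataclass
class NitrogenInversionResults:
    """Fitted pipeline state: splits, selection, bundles and metrics."""

    model: NitrogenInversion
    seed: int
    outliers: sampling.OutlierReport
    split: sampling.DataSplit
    selected: selection.SelectedWavelengths
    cars_trace: selection.CARSTrace
    bundles: dict
    Xtr: np.ndarray
    ytr: np.ndarray
    Xte: np.ndarray
    yte: np.ndarray
    retained_indices: np.ndarray
    refl_tr: np.ndarray | None = None   # raw reflectance at selected bands
    refl_te: np.ndarray | None = None

    def metrics(self, kind: str, subset: str = "test") -> evaluation.RegressionMetrics:
        b = self.bundles[kind]
        X, y = (self.Xtr, self.ytr) if subset == "train" else (self.Xte, self.yte)
        return evaluation.compute_metrics(y, b.predict(X))

    def metrics_table(self) -> dict:
        out = {}
        for kind in self.bundles:
            out[kind] = {sub: self.metrics(kind, sub).as_dict()
                         for sub in ("train", "test")}
        return out

    def best_model(self) -> str:
        """Model kind with the highest test R2."""
        return max(self.bundles, key=lambda k: self.metrics(k, "test").r2)

    def residuals(self, kind: str, subset: str = "test"):
        b = self.bundles[kind]
        X, y = (self.Xtr, self.ytr) if subset == "train" else (self.Xte, self.yte)
        return evaluation.residual_diagnostics(y, b.predict(X))

    def explain(self, kind: str | None = None, on: str = "test",
                method: str = "exact", n_permutations: int = 512,
                max_samples: int | None = None):
        """Shapley attribution of a fitted bundle over the selected bands.

        Baseline = training-set column means.  The beeswarm export colours
        points by raw reflectance at each band (the conventional reading of
        "high/low feature value"), while the attribution itself acts on the
        model's actual SG-SD inputs.  Returns ``(ShapExplanation,
        ranking DataFrame, beeswarm DataFrame)``.
        """
        kind = kind or self.best_model()
        b = self.bundles[kind]
        X = self.Xte if on == "test" else self.Xtr
        refl = self.refl_te if on == "test" else self.refl_tr
        if max_samples is not None:
            X = X[:max_samples]
            refl = None if refl is None else refl[:max_samples]
        baseline = self.Xtr.mean(axis=0)
        if method == "exact" and X.shape[1] > 16:
            method = "sampled"          # enumeration infeasible past 2^16
        if method == "exact":
            expl = interpretation.shapley_exact(b.predict, X, baseline)
        else:
            expl = interpretation.shapley_sampled(
                b.predict, X, baseline, n_permutations=n_permutations,
                seed=derive_seed("shap", self.seed))
        ranking, beeswarm = interpretation.rank_and_export(
            expl, self.selected.wavelengths,
            feature_values=refl if refl is not None else X)
        return expl, ranking, beeswarm

    def cross_stage(self, spectra: SpectraMatrix, nitrogen,
                    kind: str | None = None):
        """Validate a fitted bundle on an external stage's dataset.

        The external spectra receive the same SG-SD preprocessing and band
        subset before prediction.  Returns (metrics, diagnostics, slope).
        """
        kind = kind or self.best_model()
        ext = NitrogenInversion(spectra, nitrogen, settings=self.model.settings)
        sgsd = ext.preprocessed()
        X_ext = sgsd.reflectance[:, self.selected.indices]
        return evaluation.cross_stage_validate(self.bundles[kind], X_ext,
                                               np.asarray(nitrogen, float))

    def summary(self) -> str:
        lines = ["Leaf nitrogen inversion results",
                 "=" * 64,
                 f"samples: {len(self.retained_indices)} "
                 f"(train {len(self.ytr)}, test {len(self.yte)}; "
                 f"{len(self.outliers.flagged)} outlier(s) removed)",
                 f"selected wavelengths ({len(self.selected)}): "
                 + ", ".join(f"{w:.0f}" for w in np.sort(self.selected.wavelengths))
                 + " nm",
                 f"selection RMSE: {self.selected.rmse:.4f}",
                 "-" * 64,
                 f"{'model':<9}{'set':<7}{'R2':>8}{'RMSE':>8}{'RPD':>8}{'RPD*':>8}"]
        for kind in self.bundles:
            for sub in ("train", "test"):
                m = self.metrics(kind, sub)
                lines.append(f"{kind:<9}{sub:<7}{m.r2:>8.3f}{m.rmse:>8.3f}"
                             f"{m.rpd_conventional:>8.3f}{m.rpd_paper:>8.3f}")
        lines.append("-" * 64)
        lines.append("RPD = sd(observed)/RMSE; RPD* uses predicted deviations")
        return "\n".join(lines)
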