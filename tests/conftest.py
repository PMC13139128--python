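import numpy as np
import pytest

from leafspec import synth
from leafspec.datasets import SpectraMatrix


@pytest.fixture(scope="session")
def nss_dataset():
    """Default synthetic NSS dataset (n=125, seed 42)."""
    return synth.generate_dataset("NSS", seed=42)


@pytest.fixture(scope="session")
def small_spectra():
    """A tiny deterministic spectra matrix for shape-level tests."""
    rng = np.random.default_rng(7)
    wl = np.arange(400.0, 460.0, 1.0)
    refl = 0.3 + 0.05 * rng.random((12, len(wl)))
    return SpectraMatrix(refl, wl)


@pytest.fixture(scope="session")
def selected_features(nss_dataset):
    """SG-SD spectra, SPXY split and CARS-SPA bands for the default dataset.

    Session-scoped: several model and interpretation tests reuse it.
    """
    from leafspec import preprocess, sampling, selection

    ds = nss_dataset
    sgsd = preprocess.second_derivative(preprocess.sg_smooth(ds.spectra))
    split = sampling.spxy_split(sgsd, ds.nitrogen)
    Xtr = sgsd.reflectance[split.train_indices]
    ytr = ds.nitrogen[split.train_indices]
    Xte = sgsd.reflectance[split.test_indices]
    yte = ds.nitrogen[split.test_indices]
    sel, trace = selection.cars_spa(Xtr, ytr, sgsd.wavelengths,
                                    max_vars=18, min_vars=8, seed=142)
    idx = np.sort(sel.indices)
    return {
        "Xtr": Xtr[:, idx], "ytr": ytr, "Xte": Xte[:, idx], "yte": yte,
        "wavelengths": sgsd.wavelengths[idx], "trace": trace, "selected": sel,
    }
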