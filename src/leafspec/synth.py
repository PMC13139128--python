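"""Synthetic leaf reflectance spectra with controllable nitrogen signal.

Real ASD FieldSpec leaf spectra share a characteristic shape: low visible
reflectance governed by photosynthetic pigments, a sharp red-edge rise near
700 nm, a bright near-infrared plateau (780-1300 nm) shaped by mesophyll
scattering, deep water-absorption troughs near 1400 and 1900 nm, and local
maxima around 1700 and 2200 nm between the SWIR absorption features of
water, proteins and structural carbohydrates.

The generator reproduces that shape as a smooth continuum multiplied by
``exp(-sum_k d_k * G(lambda; mu_k, sigma_k))`` where the Gaussian profiles G
sit at pigment (430/460/680 nm), water (970/1200/1450/1940 nm), protein
(2045/2180 nm) and structural-carbohydrate (2340/2385 nm) centres.  Each
absorption depth d_k is linear in a per-sample latent constituent level
(chlorophyll, water, protein, structural carbohydrate) which is itself
linear in standardized leaf nitrogen plus independent biological noise, so
that pigment and protein absorptions deepen -- and NIR/SWIR reflectance
falls -- as nitrogen rises, while structural-carbohydrate absorption moves
the opposite way.  Per-sample multiplicative/additive scatter and
wavelength-dependent sensor noise are added on top.

Nothing here attempts radiative-transfer realism; the goal is a data set
whose statistical structure (nitrogen distribution, band-nitrogen
correlations, scatter effects, covariate shift between phenological stages)
matches what the downstream pipeline assumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .datasets import SpectraMatrix, read_wide_csv, write_wide_csv

__all__ = [
    "NitrogenDistribution",
    "AbsorptionFeature",
    "LatentSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "NSS_NITROGEN",
    "ASS_NITROGEN",
    "sample_nitrogen",
    "generate_spectra",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class NitrogenDistribution:
    """Truncated-normal description of leaf nitrogen (% dry mass) for a stage."""

    mean: float
    sd: float
    lower: float
    upper: float
    n: int

    def __post_init__(self):
        if not (self.lower < self.mean < self.upper):
            raise ValueError(
                f"degenerate nitrogen bounds: need lower < mean < upper, got "
                f"[{self.lower}, {self.upper}] around mean {self.mean}"
            )
        if self.sd <= 0:
            raise ValueError("nitrogen sd must be positive")
        if self.n < 2:
            raise ValueError("need at least 2 samples")


#: New-shoot-stop stage statistics (n=125, mean 2.479 %, sd 0.201, range 2.035-2.873).
NSS_NITROGEN = NitrogenDistribution(mean=2.479, sd=0.201, lower=2.035, upper=2.873, n=125)
#: Autumn-shoot-stop stage statistics (n=118, mean 2.795 %, sd 0.248, range 2.235-3.752).
ASS_NITROGEN = NitrogenDistribution(mean=2.795, sd=0.248, lower=2.235, upper=3.752, n=118)

_STAGE_NITROGEN = {"NSS": NSS_NITROGEN, "ASS": ASS_NITROGEN}


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption profile tied to a latent constituent."""

    center: float          # nm
    width: float           # Gaussian sigma, nm
    base_depth: float      # optical depth at latent level 1.0
    latent: str            # chlorophyll | water | protein | structural

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("absorption width must be positive")


@dataclass(frozen=True)
class LatentSpec:
    """Latent constituent = 1 + slope * z_N + noise_sd * u, u ~ N(0,1).

    ``slope`` carries the nitrogen dependence (implied correlation
    slope / sqrt(slope^2 + noise_sd^2)); ``noise_sd`` is nitrogen-independent
    biological variability.
    """

    slope: float
    noise_sd: float


def _default_features() -> tuple:
    return (
        # pigments: deepen with chlorophyll, shape the visible shelf + red edge
        AbsorptionFeature(430.0, 22.0, 0.55, "chlorophyll"),
        AbsorptionFeature(460.0, 20.0, 0.45, "chlorophyll"),
        AbsorptionFeature(680.0, 24.0, 0.60, "chlorophyll"),
        # water: weak NIR dips, deep 1450/1940 troughs
        AbsorptionFeature(970.0, 20.0, 0.12, "water"),
        AbsorptionFeature(1200.0, 28.0, 0.14, "water"),
        AbsorptionFeature(1450.0, 45.0, 0.85, "water"),
        AbsorptionFeature(1940.0, 60.0, 1.30, "water"),
        # protein (amide/C-H) bands
        AbsorptionFeature(2045.0, 17.0, 0.30, "protein"),
        AbsorptionFeature(2180.0, 17.0, 0.24, "protein"),
        # structural carbohydrates (cellulose/lignin C-H)
        AbsorptionFeature(2340.0, 15.0, 0.22, "structural"),
        AbsorptionFeature(2385.0, 14.0, 0.20, "structural"),
    )


def _default_latents() -> dict:
    return {
        "chlorophyll": LatentSpec(slope=0.40, noise_sd=0.24),
        "water": LatentSpec(slope=0.15, noise_sd=0.48),
        "protein": LatentSpec(slope=0.45, noise_sd=0.20),
        "structural": LatentSpec(slope=-0.35, noise_sd=0.28),
    }


@dataclass
class GeneratorConfig:
    """All knobs of the spectra generator; nothing is hard-coded elsewhere."""

    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 2501.0, 1.0))
    stage: str = "NSS"
    features: tuple = field(default_factory=_default_features)
    latents: dict = field(default_factory=_default_latents)
    # continuum: visible shelf -> logistic red edge -> NIR plateau -> SWIR tilt
    shelf: float = 0.17
    plateau_rise: float = 0.38
    red_edge_center: float = 705.0
    red_edge_width: float = 16.0
    # chlorophyll-driven red-edge shift (nm per unit latent above 1.0): richer
    # canopies push the inflection toward longer wavelengths
    red_edge_shift: float = 14.0
    swir_tilt: float = 6e-5            # per nm beyond 1300 nm
    # per-sample scatter and sensor noise
    scatter_slope_sd: float = 0.04
    scatter_offset_sd: float = 0.008
    noise_sd_core: float = 0.002
    noise_sd_edge: float = 0.008
    edge_span: float = 200.0           # nm over which edge noise blends in
    # structural-carbohydrate enrichment applied for the ASS stage
    ass_structural_gain: float = 1.25
    seed: int = 0

    def __post_init__(self):
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        if self.wavelength_grid.ndim != 1 or len(self.wavelength_grid) < 5:
            raise ValueError("wavelength grid must be a 1-D array of >= 5 points")
        if not np.all(np.diff(self.wavelength_grid) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.stage not in _STAGE_NITROGEN:
            raise ValueError(f"unknown stage {self.stage!r}; expected NSS or ASS")
        for sd in (self.noise_sd_core, self.noise_sd_edge):
            if not (0.0 <= sd < 0.05):
                raise ValueError("noise sds must lie in [0, 0.05)")
        lo, hi = self.wavelength_grid[0], self.wavelength_grid[-1]
        for f in self.features:
            if not (lo <= f.center <= hi):
                raise ValueError(
                    f"wavelength grid [{lo}, {hi}] nm does not cover the "
                    f"absorption centre at {f.center} nm")

    @property
    def nitrogen(self) -> NitrogenDistribution:
        return _STAGE_NITROGEN[self.stage]

    def noise_free(self) -> "GeneratorConfig":
        """Copy with scatter, sensor noise and latent noise all zeroed."""
        cfg = dataclasses.replace(
            self, scatter_slope_sd=0.0, scatter_offset_sd=0.0,
            noise_sd_core=0.0, noise_sd_edge=0.0)
        cfg.latents = {k: LatentSpec(v.slope, 0.0) for k, v in self.latents.items()}
        return cfg

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["wavelength_grid"] = [float(self.wavelength_grid[0]),
                                float(self.wavelength_grid[-1]),
                                float(np.median(np.diff(self.wavelength_grid)))]
        d["features"] = [dataclasses.asdict(f) for f in self.features]
        d["latents"] = {k: dataclasses.asdict(v) for k, v in self.latents.items()}
        return d

    @classmethod
    def from_json(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        lo, hi, step = d["wavelength_grid"]
        d["wavelength_grid"] = np.arange(lo, hi + step / 2, step)
        d["features"] = tuple(AbsorptionFeature(**f) for f in d["features"])
        d["latents"] = {k: LatentSpec(**v) for k, v in d["latents"].items()}
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Spectra + nitrogen + the latent constituent table + provenance."""

    spectra: SpectraMatrix
    nitrogen: np.ndarray
    latents: dict
    config: GeneratorConfig
    seed: int

    def __post_init__(self):
        self.nitrogen = np.asarray(self.nitrogen, dtype=float)
        if len(self.nitrogen) != self.spectra.n_samples:
            raise ValueError("nitrogen length does not match spectra rows")


def _matched_truncnorm(dist: NitrogenDistribution):
    """(loc, scale) of the truncated normal whose post-truncation mean and sd
    equal the stage's recorded sample statistics."""
    from scipy import optimize

    def gap(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (dist.lower - loc) / scale, (dist.upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - dist.mean, np.sqrt(v) - dist.sd]

    sol = optimize.root(gap, x0=[dist.mean, dist.sd * 1.2])
    if not sol.success:  # pragma: no cover - well-posed for Table-style stats
        raise RuntimeError(f"truncated-normal calibration failed: {sol.message}")
    return float(sol.x[0]), float(abs(sol.x[1]))


def sample_nitrogen(dist: NitrogenDistribution, seed: int,
                    n: int | None = None, calibrate: bool = False) -> np.ndarray:
    """Draw nitrogen values (%) from normal(mean, sd) truncated to [lower, upper].

    Deterministic given ``seed``; ``n`` defaults to the stage's recorded
    sample count.  With ``calibrate=True`` the underlying (loc, scale) are
    adjusted so the *truncated* distribution's mean and sd equal ``dist``'s
    values (truncation otherwise shrinks the realized sd below the recorded
    sample statistic).
    """
    n = dist.n if n is None else int(n)
    loc, scale = _matched_truncnorm(dist) if calibrate else (dist.mean, dist.sd)
    a = (dist.lower - loc) / scale
    b = (dist.upper - loc) / scale
    rng = np.random.default_rng(seed)
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale,
                               size=n, random_state=rng)


def _continuum(cfg: GeneratorConfig, chlorophyll: np.ndarray) -> np.ndarray:
    """Per-sample continuum (n, m): shelf, logistic red edge whose inflection
    tracks the chlorophyll latent, NIR plateau and a gentle SWIR tilt."""
    lam = cfg.wavelength_grid
    centers = cfg.red_edge_center + cfg.red_edge_shift * (chlorophyll - 1.0)
    edge = 1.0 / (1.0 + np.exp(-(lam[None, :] - centers[:, None]) / cfg.red_edge_width))
    tilt = cfg.swir_tilt * np.clip(lam - 1300.0, 0.0, None)
    return cfg.shelf + cfg.plateau_rise * edge - tilt[None, :]


def generate_spectra(nitrogen: np.ndarray, config: GeneratorConfig) -> SyntheticDataset:
    """Generate reflectance spectra for the given nitrogen values.

    Reflectance is ``clip(a_s * continuum * exp(-sum d_k G_k) + b_s + eps,
    0.001, 0.999)`` with per-sample scatter (a_s, b_s), depths linear in the
    latent constituents and edge-inflated Gaussian noise.  Fully determined
    by (nitrogen, config, config.seed).
    """
    nitrogen = np.asarray(nitrogen, dtype=float)
    if nitrogen.ndim != 1 or len(nitrogen) < 2:
        raise ValueError("need at least two nitrogen values")
    n = len(nitrogen)
    lam = config.wavelength_grid
    m = len(lam)
    rng = np.random.default_rng(config.seed)

    dist = config.nitrogen
    z = (nitrogen - dist.mean) / dist.sd

    latent_names = sorted(config.latents)
    u = rng.standard_normal((n, len(latent_names)))
    latents = {}
    for j, name in enumerate(latent_names):
        spec = config.latents[name]
        level = 1.0 + spec.slope * z + spec.noise_sd * u[:, j]
        latents[name] = np.clip(level, 0.05, None)

    # optical depth per sample per wavelength
    depth = np.zeros((n, m))
    for f in config.features:
        gain = (config.ass_structural_gain
                if (config.stage == "ASS" and f.latent == "structural") else 1.0)
        profile = np.exp(-0.5 * ((lam - f.center) / f.width) ** 2)
        depth += np.outer(f.base_depth * gain * latents[f.latent], profile)

    base = _continuum(config, latents["chlorophyll"]) * np.exp(-depth)

    a_s = 1.0 + config.scatter_slope_sd * rng.standard_normal(n)
    b_s = config.scatter_offset_sd * rng.standard_normal(n)

    span = max(config.edge_span, 1.0)
    edge_frac = np.clip(
        np.maximum(lam[0] + span - lam, lam - (lam[-1] - span)) / span, 0.0, 1.0)
    noise_sd = config.noise_sd_core + (config.noise_sd_edge - config.noise_sd_core) * edge_frac
    eps = rng.standard_normal((n, m)) * noise_sd[None, :]

    refl = np.clip(a_s[:, None] * base + b_s[:, None] + eps, 0.001, 0.999)
    spectra = SpectraMatrix(refl, lam.copy())
    return SyntheticDataset(spectra, nitrogen, latents, config, config.seed)


def generate_dataset(stage: str = "NSS", n: int | None = None, seed: int = 0,
                     config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Convenience wrapper: draw nitrogen for a stage, then spectra.

    The nitrogen draw uses ``seed`` and the spectra use ``seed + 1`` so the
    two sources of randomness never overlap.
    """
    if config is None:
        config = GeneratorConfig(stage=stage, seed=seed + 1)
    else:
        config = dataclasses.replace(config, stage=stage, seed=seed + 1)
    nitrogen = sample_nitrogen(config.nitrogen, seed=seed, n=n, calibrate=True)
    ds = generate_spectra(nitrogen, config)
    return SyntheticDataset(ds.spectra, ds.nitrogen, ds.latents, config, seed)


def write_dataset(ds: SyntheticDataset, path) -> Path:
    """Write wide CSV plus a sidecar JSON with config and seed."""
    path = Path(path)
    meta = {"seed": ds.seed, "config": ds.config.to_json()}
    write_wide_csv(path, ds.spectra, ds.nitrogen, meta=meta)
    return path


def read_dataset(path):
    """Read a wide CSV written by :func:`write_dataset`; returns (spectra, nitrogen, meta)."""
    path = Path(path)
    spectra, nitrogen = read_wide_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return spectra, nitrogen, meta
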