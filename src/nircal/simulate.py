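"""Seeded simulator for NIR spectra of mixture standards and kernel samples.

The simulator stands in for physical data: gravimetric mixtures of pure
components (amylopectin, protein, crude fiber, fructose, glucose, sucrose;
total sugar is the sum of the three sugars) and real maize-kernel flours.

Pure-component absorptivity curves are sums of Gaussian bands with widths
of 30-200 cm^-1, roughly the width of NIR overtone/combination bands of
hydrogen-bearing groups.  Standards mix linearly (Beer-Lambert) with
wide, independent composition spreads and exact (gravimetric) reference
values.  Realistic kernel samples draw narrower, correlated compositions
from a three-type variety population (sweet / waxy / sweet-waxy) and add
kernel-matrix effects: a broad matrix absorption band, a constant
reference bias and wet-chemistry reference noise.  Both sample kinds
pass through the same instrument/presentation chain (multiplicative
scatter, saturating detector response, structured cubic baseline,
heteroscedastic noise) because standards are scanned on the same
spectrometer in the same cups.  The kernel-specific effects give the
prediction network a systematic error the correction network can
demonstrably remove, mirroring the over/under-estimation a network
trained purely on standards shows on real kernels.

Every generator is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset
from .nn import ANNConfig

__all__ = [
    "COMPONENTS", "PURE_COMPONENTS",
    "PureSpectrumLibrary", "CompositionConfig", "DistortionConfig",
    "default_grid", "gen_pure_spectra", "standards_composition",
    "realistic_composition", "kernel_population", "gen_standard_samples",
    "gen_realistic_samples",
    "Benchmark", "benchmark_suite",
]

PURE_COMPONENTS = ("amylopectin", "protein", "crude_fiber",
                   "fructose", "glucose", "sucrose")
#: reported components; total_sugar = fructose + glucose + sucrose
COMPONENTS = PURE_COMPONENTS + ("total_sugar",)

#: nominal purity of the physical standards each curve emulates
PURITIES = {
    "amylopectin": 0.971, "protein": 0.920, "crude_fiber": 0.800,
    "fructose": 0.990, "glucose": 0.990, "sucrose": 0.980,
}


def default_grid(kind: str = "fresh_maize") -> np.ndarray:
    """Instrument grids: FT-NIR wavenumber grids or the FOSS nm grid."""
    if kind == "fresh_maize":
        return np.linspace(3999.64, 10001.03, 1557)
    if kind == "forage_maize":
        return np.linspace(3999.64, 7899.0, 1012)
    if kind == "barley":
        return np.linspace(3999.64, 11998.92, 2075)
    if kind == "rice_wheat":  # FOSS grid, nm
        return np.arange(1100.0, 2498.0 + 1, 2.0)
    raise ValueError(f"unknown grid kind {kind!r}")


@dataclass
class PureSpectrumLibrary:
    """Per-component absorptivity curves on a grid (non-negative)."""

    grid: np.ndarray
    curves: dict  # name -> ndarray over grid
    purities: dict = field(default_factory=lambda: dict(PURITIES))

    def mix(self, concentrations: dict) -> np.ndarray:
        """Beer-Lambert linear mixture for one sample (% concentrations)."""
        out = np.zeros_like(self.grid, dtype=float)
        for name, c in concentrations.items():
            out += (c / 100.0) * self.purities[name] * self.curves[name]
        return out


def gen_pure_spectra(seed: int, grid=None, shared_fraction: float = 0.0
                     ) -> PureSpectrumLibrary:
    """Seeded Gaussian-band absorptivity curves for the six pure components.

    NIR absorptivities of organic components are dominated by the same
    C-H / O-H / N-H overtone and combination bands, so the curves share a
    common envelope (weight ``shared_fraction``) on top of which each
    component carries its own distinctive bands.  The resulting strong
    overlap — and hence collinearity between component signals in mixture
    spectra — is an essential feature of the domain, not noise.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if not 0 <= shared_fraction < 1:
        raise ValueError("shared_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = float(grid.min()), float(grid.max())

    def band_sum(n_bands):
        centers = rng.uniform(lo, hi, size=n_bands)
        widths = rng.uniform(30.0, 200.0, size=n_bands)
        amps = rng.lognormal(mean=0.0, sigma=0.6, size=n_bands)
        curve = np.zeros_like(grid)
        for c, w, a in zip(centers, widths, amps):
            curve += a * np.exp(-0.5 * ((grid - c) / w) ** 2)
        return curve / curve.mean()

    envelope = band_sum(int(rng.integers(10, 16)))
    curves = {}
    for name in PURE_COMPONENTS:
        own = band_sum(int(rng.integers(8, 16)))
        mixture = shared_fraction * envelope + (1 - shared_fraction) * own
        # normalise so a typical mixture sits at O(1) absorbance
        curves[name] = 2.0 * mixture
    return PureSpectrumLibrary(grid=grid, curves=curves)


@dataclass
class CompositionConfig:
    """Truncated-normal composition distribution (%, dry basis)."""

    means: dict
    sds: dict
    lower: dict
    upper: dict
    correlation: pd.DataFrame | None = None  # realistic mode only

    def __post_init__(self):
        for name in PURE_COMPONENTS:
            if not self.lower[name] <= self.means[name] <= self.upper[name]:
                raise ValueError(f"mean of {name} outside its bounds")
        if self.correlation is not None:
            C = self.correlation.loc[list(PURE_COMPONENTS),
                                     list(PURE_COMPONENTS)].to_numpy()
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError("correlation matrix must be positive definite")


_MEANS = {"amylopectin": 30.0, "protein": 12.0, "crude_fiber": 2.5,
          "fructose": 2.0, "glucose": 2.0, "sucrose": 8.0}
_WIDE_SD = {"amylopectin": 14.0, "protein": 5.5, "crude_fiber": 1.4,
            "fructose": 1.5, "glucose": 1.5, "sucrose": 5.0}
_NARROW_SD = {"amylopectin": 5.5, "protein": 2.0, "crude_fiber": 0.55,
              "fructose": 0.45, "glucose": 0.45, "sucrose": 1.6}


def _bounds(sds):
    lower = {k: 0.05 for k in PURE_COMPONENTS}
    upper = {k: _MEANS[k] + 4.0 * sds[k] for k in PURE_COMPONENTS}
    return lower, upper


def standards_composition() -> CompositionConfig:
    """Wide, independent spreads: the mixture-standard design space."""
    lower, upper = _bounds(_WIDE_SD)
    return CompositionConfig(dict(_MEANS), dict(_WIDE_SD), lower, upper)


def realistic_composition() -> CompositionConfig:
    """Narrower, correlated spreads typical of real kernel flours."""
    names = list(PURE_COMPONENTS)
    C = pd.DataFrame(np.eye(6), index=names, columns=names)

    def set_r(a, b, r):
        C.loc[a, b] = C.loc[b, a] = r

    set_r("fructose", "glucose", 0.75)
    set_r("fructose", "sucrose", 0.40)
    set_r("glucose", "sucrose", 0.40)
    set_r("amylopectin", "sucrose", -0.45)
    set_r("amylopectin", "fructose", -0.30)
    set_r("amylopectin", "glucose", -0.30)
    set_r("protein", "crude_fiber", 0.30)
    lower, upper = _bounds(_NARROW_SD)
    return CompositionConfig(dict(_MEANS), dict(_NARROW_SD), lower, upper,
                             correlation=C)


#: variety-type composition shifts (%, relative to the overall means) and
#: population fractions of a fresh-maize panel: sweet types are sugar-rich
#: and starch-poor, waxy types the opposite, sweet-waxy in between.  The
#: minority types are exactly why representative (SELECT) calibration
#: sampling matters: a small random draw can miss them entirely.
_VARIETY_TYPES = {
    "sweet": (140 / 246, {"sucrose": 2.5, "fructose": 0.45, "glucose": 0.45,
                          "amylopectin": -4.0, "protein": 0.3}),
    "waxy": (72 / 246, {"sucrose": -2.8, "fructose": -0.55, "glucose": -0.55,
                        "amylopectin": 5.0, "protein": -0.35}),
    "sweet_waxy": (34 / 246, {"sucrose": -0.8, "amylopectin": 2.0,
                              "crude_fiber": 0.4, "protein": -0.1}),
}


def kernel_population() -> list:
    """Three-type mixture population of kernel compositions.

    Returns ``[(fraction, CompositionConfig), ...]`` for the sweet, waxy
    and sweet-waxy variety types; within-type spreads are narrower than
    the pooled realistic spread, and the between-type mean shifts create
    the multimodal structure of a real variety panel.
    """
    names = list(PURE_COMPONENTS)
    base = realistic_composition()
    # protein varies continuously across varieties; the starch/sugar
    # axes carry most of the between-type structure
    within_factor = {k: 0.6 for k in _NARROW_SD}
    within_factor["protein"] = 0.9
    within_sd = {k: within_factor[k] * v for k, v in _NARROW_SD.items()}
    out = []
    for _type, (frac, shifts) in _VARIETY_TYPES.items():
        means = dict(_MEANS)
        for k, dv in shifts.items():
            means[k] = means[k] + dv
        lower, upper = _bounds(_NARROW_SD)
        out.append((frac, CompositionConfig(means, dict(within_sd), lower,
                                            upper, correlation=base.correlation)))
    return out


@dataclass
class DistortionConfig:
    """Instrument/presentation chain plus kernel-matrix effects.

    The first five fields model the shared measurement chain (any powder
    in the sample cup sees them): multiplicative scatter, a saturating
    detector response tanh(gamma*A)/gamma, baseline drift and
    heteroscedastic noise.  The remaining fields are specific to real
    kernel samples: a broad matrix absorption band (think bound-water /
    matrix interactions) whose mean amplitude systematically perturbs the
    spectra, a constant reference bias (offset between the gravimetric
    standards scale and the wet-chemistry scale) and wet-chemistry
    repeatability noise on the recorded reference values.

    All strengths >= 0; everything zero reduces to exact Beer-Lambert
    mixing with exact references.
    """

    scatter_sd: float = 0.005         # multiplicative scatter, 1 +- sd
    saturation_gamma: float = 0.6     # response tanh(gamma*A)/gamma
    drift_sd: float = 0.02            # sd of cubic-baseline coefficients
    noise_base: float = 5e-4          # additive noise floor (absorbance)
    noise_prop: float = 2e-3          # noise proportional to absorbance
    matrix_band_amp_mean: float = 0.0  # mean amplitude of the matrix band
    matrix_band_amp_sd: float = 0.0    # per-sample amplitude scatter
    matrix_band_center: float = 5150.0  # cm^-1, water combination region
    matrix_band_width: float = 500.0    # cm^-1
    reference_bias: dict = field(default_factory=dict)
    reference_noise_sd: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("scatter_sd", "saturation_gamma", "drift_sd",
                     "noise_base", "noise_prop", "matrix_band_amp_sd",
                     "matrix_band_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.reference_noise_sd.values()):
            raise ValueError("reference_noise_sd values must be >= 0")

    @classmethod
    def none(cls) -> "DistortionConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def chain(self, A: np.ndarray, x: np.ndarray, rng) -> np.ndarray:
        """Apply the shared instrument/presentation chain to one spectrum."""
        if self.scatter_sd > 0:
            A = A * (1.0 + rng.normal(0.0, self.scatter_sd))
        if self.saturation_gamma > 0:
            A = np.tanh(self.saturation_gamma * A) / self.saturation_gamma
        if self.drift_sd > 0:
            # smooth structured baseline: random cubic in Legendre form,
            # the low-frequency artifact family FT-NIR baselines show
            c = rng.normal(0.0, self.drift_sd, size=4)
            A = A + c[0] + c[1] * x + c[2] * (3 * x**2 - 1) \
                  + c[3] * (5 * x**3 - 3 * x)
        sd = self.noise_base + self.noise_prop * np.abs(A)
        if np.any(sd > 0):
            A = A + rng.normal(0.0, 1.0, size=A.shape) * sd
        return A


def _draw_compositions(cfg: CompositionConfig, n: int, rng) -> pd.DataFrame:
    names = list(PURE_COMPONENTS)
    mu = np.array([cfg.means[k] for k in names])
    sd = np.array([cfg.sds[k] for k in names])
    lo = np.array([cfg.lower[k] for k in names])
    hi = np.array([cfg.upper[k] for k in names])
    if cfg.correlation is None:
        cov = np.diag(sd**2)
    else:
        C = cfg.correlation.loc[names, names].to_numpy()
        cov = C * np.outer(sd, sd)
    L = np.linalg.cholesky(cov)
    out = np.empty((n, 6))
    filled = 0
    for _ in range(1000):
        draw = mu + rng.standard_normal(size=(2 * n, 6)) @ L.T
        ok = draw[np.all((draw >= lo) & (draw <= hi), axis=1)]
        take = min(n - filled, len(ok))
        out[filled:filled + take] = ok[:take]
        filled += take
        if filled == n:
            break
    else:
        raise ValueError("truncation region too small; could not draw compositions")
    df = pd.DataFrame(out, columns=names)
    df["total_sugar"] = df[["fructose", "glucose", "sucrose"]].sum(axis=1)
    return df


def _assemble(lib, comp: pd.DataFrame, spectra, prefix, role,
              bias=None) -> SpectralDataset:
    ids = [f"{prefix}{i + 1:03d}" for i in range(len(comp))]
    table = comp.copy()
    table.index = pd.Index(ids, name="id")
    if bias:
        for name, beta in bias.items():
            if name in table.columns:
                table[name] = table[name] + beta
    ds = SpectralDataset(ids, lib.grid, spectra, components=table)
    return ds.assign_role(role)


def gen_standard_samples(lib: PureSpectrumLibrary, comp_cfg: CompositionConfig,
                         n: int = 99, seed: int = 0, noise_sd: float = 5e-4,
                         baseline_sd: float = 2e-3,
                         distortion: DistortionConfig | None = None,
                         ) -> SpectralDataset:
    """Synthetic standard mixtures: linear mixing, wide independent spreads.

    With ``distortion=None`` and ``noise_sd = baseline_sd = 0`` the
    spectra are exactly linear in the concentrations.  Passing a
    :class:`DistortionConfig` applies its shared instrument/presentation
    chain (scatter, saturation, drift, noise) instead — standards are
    scanned on the same spectrometer and in the same cups as real
    samples, so the measurement chain belongs to both; the kernel-matrix
    band and the reference bias/noise never apply to standards, whose
    reference values are recorded exactly as mixed (gravimetric).
    """
    rng = np.random.default_rng(seed)
    comp = _draw_compositions(comp_cfg, n, rng)
    g = lib.grid
    x = (g - g.mean()) / (g.max() - g.min())
    spectra = np.empty((n, g.size))
    for i in range(n):
        conc = {k: comp.iloc[i][k] for k in PURE_COMPONENTS}
        A = lib.mix(conc)
        if distortion is not None:
            A = distortion.chain(A, x, rng)
        else:
            if baseline_sd > 0:
                A = A + rng.normal(0.0, baseline_sd)
            if noise_sd > 0:
                A = A + rng.normal(0.0, noise_sd, size=A.shape)
        spectra[i] = A
    return _assemble(lib, comp, spectra, "std", "synthetic")


def gen_realistic_samples(lib: PureSpectrumLibrary, comp_cfg: CompositionConfig,
                          distortion: DistortionConfig, n: int,
                          seed: int = 0) -> SpectralDataset:
    """Kernel-like samples: correlated compositions + matrix effects.

    Adds the kernel-matrix absorption band, passes the spectrum through
    the shared instrument/presentation chain, and perturbs the recorded
    reference values with the configured wet-chemistry noise and constant
    bias.
    """
    rng = np.random.default_rng(seed)
    if isinstance(comp_cfg, (list, tuple)):
        # mixture population: per-type counts by fraction, rows interleaved
        fracs = np.array([f for f, _ in comp_cfg], dtype=float)
        counts = np.floor(fracs / fracs.sum() * n).astype(int)
        counts[0] += n - counts.sum()
        parts = [_draw_compositions(cfg, c, rng)
                 for (_, cfg), c in zip(comp_cfg, counts) if c > 0]
        comp = pd.concat(parts, ignore_index=True)
        comp = comp.iloc[rng.permutation(len(comp))].reset_index(drop=True)
    else:
        comp = _draw_compositions(comp_cfg, n, rng)
    g = lib.grid
    x = (g - g.mean()) / (g.max() - g.min())
    band = np.exp(-0.5 * ((g - distortion.matrix_band_center)
                          / distortion.matrix_band_width) ** 2)
    spectra = np.empty((n, g.size))
    for i in range(n):
        conc = {k: comp.iloc[i][k] for k in PURE_COMPONENTS}
        A = lib.mix(conc)
        if distortion.matrix_band_amp_mean or distortion.matrix_band_amp_sd:
            amp = rng.normal(distortion.matrix_band_amp_mean,
                             distortion.matrix_band_amp_sd)
            A = A + amp * band
        A = distortion.chain(A, x, rng)
        spectra[i] = A
    for name, nsd in distortion.reference_noise_sd.items():
        if name in comp.columns and nsd > 0:
            comp[name] = comp[name] + rng.normal(0.0, nsd, size=n)
    return _assemble(lib, comp, spectra, "krn", "unassigned",
                     bias=distortion.reference_bias)


# ----------------------------------------------------------------------


@dataclass
class Benchmark:
    """Reproducible bundle with the experimental shape of the study design:
    99 standards, 246 realistic samples, 10 shuffle seeds, the NH sweep
    grid and default network configurations."""

    standards: SpectralDataset
    realistic: SpectralDataset
    shuffle_seeds: list
    nh_sweep: np.ndarray
    component: str
    pnn_config: ANNConfig
    cnn_config: ANNConfig
    ann_config: ANNConfig
    threshold: float
    k: int
    n_validation: int
    target_calibration: int
    reference_bias: dict
    #: leading PCs used for SELECT distances; diversity is judged on the
    #: main composition/variance axes, not on low-variance noise directions
    n_select_pcs: int = 10


def benchmark_suite(seed: int, component: str = "protein",
                    n_standards: int = 99, n_realistic: int = 246) -> Benchmark:
    """Build the full synthetic benchmark from one seed.

    Defaults mirror the study conditions: 99 standards, 246 realistic
    samples, 51 validation samples, ~32-sample SELECT calibration sets and
    10 shuffle repeats.  Network settings are convergence-checked defaults
    for the simulated protein component (hidden widths from the published
    optima; epochs long enough for the Adam loss to plateau at lr 1e-3).
    """
    ss = np.random.SeedSequence(seed)
    s_lib, s_std, s_real, s_shuf = ss.spawn(4)
    int_seed = lambda s: int(s.generate_state(1)[0] % (2**31))
    lib = gen_pure_spectra(int_seed(s_lib))
    bias = {"protein": -1.0}
    distortion = DistortionConfig(matrix_band_amp_mean=0.03,
                                  matrix_band_amp_sd=0.005,
                                  reference_bias=dict(bias),
                                  reference_noise_sd={"protein": 0.35})
    standards = gen_standard_samples(lib, standards_composition(),
                                     n=n_standards, seed=int_seed(s_std),
                                     distortion=distortion)
    realistic = gen_realistic_samples(lib, kernel_population(), distortion,
                                      n=n_realistic, seed=int_seed(s_real))
    shuffle_seeds = [int_seed(s) for s in s_shuf.spawn(10)]
    return Benchmark(
        standards=standards,
        realistic=realistic,
        shuffle_seeds=shuffle_seeds,
        nh_sweep=np.arange(0.2, 1.81, 0.2),
        component=component,
        pnn_config=ANNConfig(n_neurons=20, activation="tanh", epochs=10000,
                             seed=int_seed(ss.spawn(1)[0])),
        cnn_config=ANNConfig(n_neurons=2, activation="tanh", epochs=1000,
                             seed=int_seed(ss.spawn(1)[0])),
        ann_config=ANNConfig(n_neurons=9, activation="tanh", epochs=4000,
                             seed=int_seed(ss.spawn(1)[0])),
        threshold=0.3,
        k=26,
        n_validation=51,
        target_calibration=32,
        reference_bias=bias,
    )
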