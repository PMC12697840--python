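"""Wavelength selection, PCA projection and min-max target scaling.

Wavelength selection keeps the grid points whose absolute Pearson
correlation with the reference component exceeds a threshold; a threshold
of 0 keeps the full spectrum.  PCA provides the shared low-dimensional
score space in which sample selection and the neural networks operate.
Reference values are min-max scaled to [0, 1] before network training and
always reported back in original units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

__all__ = ["WavelengthMask", "select_wavelengths", "PCAModel", "fit_pca", "MinMaxScaler"]


@dataclass
class WavelengthMask:
    """Indices of retained grid points plus the correlation profile."""

    kept_indices: np.ndarray
    threshold: float
    correlations: np.ndarray

    def apply(self, spectra: np.ndarray) -> np.ndarray:
        return np.asarray(spectra)[:, self.kept_indices]

    @property
    def n_kept(self) -> int:
        return self.kept_indices.size


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X against y; zero-variance columns -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0  # constant columns carry no information
    return r


def select_wavelengths(ds, component: str, threshold: float) -> WavelengthMask:
    """Correlation-threshold wavelength selection on a fitting subset.

    Keeps grid points with |r| > ``threshold`` where r is the Pearson
    correlation between the absorbance column and the component vector over
    the samples of ``ds``.  Must be fed calibration (or synthetic-fit)
    samples only — never validation samples.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    y = ds.component_values(component)
    if np.isnan(y).any():
        raise ValueError(f"component {component!r} missing for some fitting samples")
    if ds.n_samples < 3:
        raise ValueError("need at least 3 fitting samples for correlations")
    if np.ptp(y) == 0:
        raise ValueError(f"component {component!r} has zero variance")
    r = _pearson_columns(ds.absorbance, y)
    if threshold == 0:
        kept = np.arange(ds.n_points)
    else:
        kept = np.flatnonzero(np.abs(r) > threshold)
    if kept.size == 0:
        raise ValueError(
            f"threshold {threshold} removed every grid point "
            f"(max |r| = {np.abs(r).max():.3f})"
        )
    return WavelengthMask(kept_indices=kept, threshold=float(threshold), correlations=r)


@dataclass
class PCAModel:
    """Mean-centred principal-component basis shared across subsets."""

    center: np.ndarray
    loadings: np.ndarray  # (n_points_kept, k), orthonormal columns
    explained_variance: np.ndarray
    k: int

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        spectra = np.asarray(spectra, dtype=float)
        if spectra.shape[1] != self.center.size:
            raise ValueError(
                f"spectra have {spectra.shape[1]} points, PCA expects {self.center.size}"
            )
        return (spectra - self.center) @ self.loadings


def fit_pca(spectra: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA by mean-centred SVD.

    Scores of any subset are obtained with :meth:`PCAModel.transform` so
    synthetic standards, calibration and validation samples share one
    coordinate system.
    """
    spectra = np.asarray(spectra, dtype=float)
    n, p = spectra.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p) = {min(n - 1, p)}")
    rank = np.linalg.matrix_rank(spectra - spectra.mean(axis=0))
    if k > rank:
        raise ValueError(f"k={k} exceeds attainable rank {rank}")
    sk = _SKPCA(n_components=k, svd_solver="full")
    sk.fit(spectra)
    return PCAModel(
        center=sk.mean_,
        loadings=sk.components_.T,
        explained_variance=sk.explained_variance_,
        k=k,
    )


class MinMaxScaler:
    """Affine [min, max] -> [0, 1] map for reference values; no clipping.

    Values outside the fit range map outside [0, 1] by design: predictions
    are inverse-transformed back to original units, and clipping would warp
    that affine round trip.
    """

    def __init__(self):
        self.min_ = None
        self.max_ = None

    def fit(self, values) -> "MinMaxScaler":
        v = np.asarray(values, dtype=float)
        self.min_ = float(v.min())
        self.max_ = float(v.max())
        if not self.max_ > self.min_:
            raise ValueError("cannot min-max scale a constant vector")
        return self

    def transform(self, values) -> np.ndarray:
        self._check()
        return (np.asarray(values, dtype=float) - self.min_) / (self.max_ - self.min_)

    def inverse_transform(self, scaled) -> np.ndarray:
        self._check()
        return np.asarray(scaled, dtype=float) * (self.max_ - self.min_) + self.min_

    def fit_transform(self, values) -> np.ndarray:
        return self.fit(values).transform(values)

    def _check(self):
        if self.min_ is None:
            raise ValueError("scaler is not fitted")
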