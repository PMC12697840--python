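"""Calibration engines: PLS, single-hidden-layer ANN, and the PCNN.

Each engine follows the model/results idiom: a model object is built from
data, ``fit()`` returns a results object carrying the estimates and
diagnostics, and prediction, reporting and plotting hang off the results.

The prediction-correction neural network (PCNN) is the centrepiece.  A
*prediction network* (PNN) is trained on synthetic standard mixtures whose
compositions are known exactly, so it learns the spectra-to-composition
map over a wider composition range than real kernels span.  Real samples
deviate from that map (matrix effects, instrument response, reference
bias), so a second *correction network* (CNN — correction, not
convolutional) is trained on the calibration set's residuals
y_C - PNN(Z_C).  The final estimate for any sample is the sum

    y_hat = PNN(Z) + CNN(Z)

with both parts computed in original measurement units.  The two networks
consume the same PC scores: wavelengths are first filtered by correlation
threshold (computed on the calibration set), then a single PCA basis is
fitted on the union of standard and calibration spectra so that standards,
calibration and validation samples share one coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .metrics import MetricsReport, score
from .nn import ANNConfig, MLPParams, mlp_forward, train_mlp
from .preprocess import MinMaxScaler, WavelengthMask, fit_pca, select_wavelengths

__all__ = [
    "PLSCalibration", "PLSResults",
    "ANNCalibration", "ANNResults",
    "PCNNCalibration", "PCNNResults",
    "PredictionResult",
    "fit_pls", "fit_ann", "predict_ann",
]


# ----------------------------------------------------------------------
# low-level functional layer (matrix in, model out)


def fit_pls(X, y, n_latent: int):
    """NIPALS PLS1 with mean-centring; deterministic for fixed input."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if not 1 <= n_latent:
        raise ValueError("n_latent must be >= 1")
    if n_latent > rank:
        raise ValueError(f"n_latent={n_latent} exceeds attainable rank {rank}")
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, y)
    return pls


def fit_ann(Z, y_scaled, cfg: ANNConfig) -> MLPParams:
    """Train the MLP on PC scores against scaled targets (full-batch Adam)."""
    return train_mlp(Z, y_scaled, cfg)


def predict_ann(params: MLPParams, Z, scaler: MinMaxScaler | None = None):
    """Network output per row, inverse-scaled to original units if given."""
    out = mlp_forward(params, Z)
    return scaler.inverse_transform(out) if scaler is not None else out


def _select_n_latent_cv(X, y, cap: int = 20, n_folds: int = 10, seed: int = 0) -> int:
    """Pick the latent count minimising 10-fold CV RMSE, capped at ``cap``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    max_lv = int(min(cap, rank, n - int(np.ceil(n / n_folds)) - 1))
    max_lv = max(max_lv, 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, min(n_folds, n))
    press = np.zeros(max_lv)
    for hold in folds:
        train = np.setdiff1d(order, hold)
        Xt, yt = X[train], y[train]
        fold_rank = np.linalg.matrix_rank(Xt - Xt.mean(axis=0))
        for lv in range(1, max_lv + 1):
            if lv > fold_rank:
                press[lv - 1] = np.inf
                continue
            m = PLSRegression(n_components=lv, scale=False).fit(Xt, yt)
            press[lv - 1] += np.sum((m.predict(X[hold]).ravel() - y[hold]) ** 2)
    return int(np.argmin(press) + 1)


# ----------------------------------------------------------------------
# dataset-level pipeline helpers


@dataclass
class _Pipeline:
    """Mask + shared PCA, the preprocessing state every engine reuses."""

    mask: WavelengthMask | None
    pca: object
    k: int

    def scores(self, ds) -> np.ndarray:
        X = ds.absorbance if self.mask is None else self.mask.apply(ds.absorbance)
        return self.pca.transform(X)


def _build_pipeline(calibration, component, threshold, k, basis_spectra) -> _Pipeline:
    mask = None
    X = basis_spectra
    if threshold > 0:
        mask = select_wavelengths(calibration, component, threshold)
        X = mask.apply(basis_spectra)
    k_eff = int(min(k, X.shape[0] - 1, X.shape[1]))
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k_eff = int(min(k_eff, rank))
    pca = fit_pca(X, k_eff)
    return _Pipeline(mask, pca, k_eff)


class _ResultsBase:
    """Shared reporting for all engine results."""

    method = ""

    def predict_values(self, ds) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def validation_report(self, val_ds) -> MetricsReport:
        y_val = val_ds.component_values(self.model.component)
        val = score(y_val, self.predict_values(val_ds), role="validation")
        cal = score(self._y_cal, self._yhat_cal, role="calibration")
        return MetricsReport.from_scores(
            cal, val, method=self.method, component=self.model.component
        )

    def summary(self) -> str:
        cal = score(self._y_cal, self._yhat_cal, role="calibration")
        lines = [
            f"{self.method} calibration results — component: {self.model.component}",
            "-" * 58,
            f"calibration samples      {cal.n:>10d}",
            f"R2 (calibration)         {cal.r2:>10.4f}",
            f"RMSEC                    {cal.rmse:>10.4f}",
        ]
        lines += self._summary_extra()
        return "\n".join(lines)

    def _summary_extra(self):
        return []

    def plot_predictions(self, ds=None, ax=None):
        """Scatter of predictions vs reference (calibration, plus ``ds``)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self._y_cal, self._yhat_cal, c="tab:red", label="calibration", s=18)
        if ds is not None:
            y = ds.component_values(self.model.component)
            ax.scatter(y, self.predict_values(ds), c="tab:green",
                       label="validation", s=18)
        lims = ax.get_xlim()
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"reference {self.model.component} (%)")
        ax.set_ylabel("predicted (%)")
        ax.legend()
        return ax


# ----------------------------------------------------------------------
# PLS


class PLSCalibration:
    """PLS1 calibration of one component on (masked) spectra.

    ``n_latent=None`` selects the latent count by 10-fold cross-validation
    on the calibration set, capped at 20.
    """

    def __init__(self, calibration, component: str, n_latent: int | None = None,
                 threshold: float = 0.0):
        self.calibration = calibration
        self.component = component
        self.n_latent = n_latent
        self.threshold = threshold

    def fit(self) -> "PLSResults":
        ds = self.calibration
        y = ds.component_values(self.component)
        mask = None
        X = ds.absorbance
        if self.threshold > 0:
            mask = select_wavelengths(ds, self.component, self.threshold)
            X = mask.apply(X)
        n_latent = self.n_latent
        if n_latent is None:
            n_latent = _select_n_latent_cv(X, y)
        pls = fit_pls(X, y, n_latent)
        return PLSResults(self, pls, mask, n_latent, y, pls.predict(X).ravel())


class PLSResults(_ResultsBase):
    method = "PLS"

    def __init__(self, model, pls, mask, n_latent, y_cal, yhat_cal):
        self.model = model
        self.pls = pls
        self.mask = mask
        self.n_latent = n_latent
        self._y_cal = y_cal
        self._yhat_cal = yhat_cal

    @property
    def coef_(self) -> np.ndarray:
        return self.pls.coef_.ravel()

    def predict_values(self, ds) -> np.ndarray:
        X = ds.absorbance if self.mask is None else self.mask.apply(ds.absorbance)
        return self.pls.predict(X).ravel()

    def _summary_extra(self):
        return [f"latent variables         {self.n_latent:>10d}"]


# ----------------------------------------------------------------------
# ANN


class ANNCalibration:
    """Single-hidden-layer ANN calibration on PC scores of the spectra.

    The wavelength mask (optional), PCA basis and target min-max scaler
    are all fitted on the calibration set alone.
    """

    def __init__(self, calibration, component: str, config: ANNConfig,
                 k: int = 26, threshold: float = 0.0):
        self.calibration = calibration
        self.component = component
        self.config = config
        self.k = k
        self.threshold = threshold

    def fit(self) -> "ANNResults":
        ds = self.calibration
        y = ds.component_values(self.component)
        pipe = _build_pipeline(ds, self.component, self.threshold, self.k,
                               ds.absorbance)
        scaler = MinMaxScaler().fit(y)
        Z = pipe.scores(ds)
        params = fit_ann(Z, scaler.transform(y), self.config)
        yhat = predict_ann(params, Z, scaler)
        return ANNResults(self, pipe, scaler, params, y, yhat)


class ANNResults(_ResultsBase):
    method = "ANN"

    def __init__(self, model, pipe, scaler, params, y_cal, yhat_cal):
        self.model = model
        self.pipeline = pipe
        self.scaler = scaler
        self.params = params
        self._y_cal = y_cal
        self._yhat_cal = yhat_cal

    @property
    def loss_trace(self) -> np.ndarray:
        return self.params.loss_trace

    def predict_values(self, ds) -> np.ndarray:
        return predict_ann(self.params, self.pipeline.scores(ds), self.scaler)

    def _summary_extra(self):
        c = self.model.config
        return [
            f"hidden neurons           {c.n_neurons:>10d}",
            f"activation               {c.activation:>10s}",
            f"epochs                   {c.epochs:>10d}",
            f"final training loss      {self.params.loss_trace[-1]:>10.3e}",
            f"PCs used                 {self.pipeline.k:>10d}",
        ]


# ----------------------------------------------------------------------
# PCNN


@dataclass
class PredictionResult:
    """PNN estimate, CNN correction and their sum, all in original units."""

    y0: np.ndarray
    y_eps: np.ndarray

    @property
    def y_hat(self) -> np.ndarray:
        return self.y0 + self.y_eps


class PCNNCalibration:
    """Prediction-correction network built from standards + a small real set.

    Parameters
    ----------
    standards : SpectralDataset
        Synthetic standard mixtures with exactly known compositions; train
        the prediction network.
    calibration : SpectralDataset
        Small set of real samples with reference values; trains the
        correction network on the prediction network's residuals.
    component : str
        Component to calibrate.
    pnn_config, cnn_config : ANNConfig
        Architecture/training settings of the two networks.
    k : int
        Number of shared principal components (default 26).
    threshold : float
        Correlation threshold for wavelength selection, computed on the
        calibration set (default 0.3; 0 keeps the full spectrum).
    """

    def __init__(self, standards, calibration, component: str,
                 pnn_config: ANNConfig, cnn_config: ANNConfig,
                 k: int = 26, threshold: float = 0.3):
        if calibration.n_samples < 3:
            raise ValueError("calibration set must hold at least 3 samples")
        if not np.array_equal(standards.grid, calibration.grid):
            raise ValueError("standards and calibration must share one grid; "
                             "resample first")
        self.standards = standards
        self.calibration = calibration
        self.component = component
        self.pnn_config = pnn_config
        self.cnn_config = cnn_config
        self.k = k
        self.threshold = threshold

    def fit(self) -> "PCNNResults":
        y_tilde = self.standards.component_values(self.component)
        y_cal = self.calibration.component_values(self.component)
        if np.isnan(y_tilde).any():
            raise ValueError("standards must carry complete reference values")
        if np.isnan(y_cal).any():
            raise ValueError("calibration must carry complete reference values")

        basis = np.vstack([self.standards.absorbance, self.calibration.absorbance])
        pipe = _build_pipeline(self.calibration, self.component, self.threshold,
                               self.k, basis)
        Z0 = pipe.scores(self.standards)
        Zc = pipe.scores(self.calibration)

        # stage 1: prediction network on the standards
        pnn_scaler = MinMaxScaler().fit(y_tilde)
        pnn = fit_ann(Z0, pnn_scaler.transform(y_tilde), self.pnn_config)
        if not np.isfinite(pnn.loss_trace[-1]):
            raise FloatingPointError("PNN training diverged")

        # stage 2: correction network on calibration residuals
        residuals = y_cal - predict_ann(pnn, Zc, pnn_scaler)
        cnn_scaler = MinMaxScaler().fit(residuals)
        cnn = fit_ann(Zc, cnn_scaler.transform(residuals), self.cnn_config)

        res = PCNNResults(self, pipe, pnn, pnn_scaler, cnn, cnn_scaler, y_cal)
        res._yhat_cal = res.predict(self.calibration).y_hat
        return res


class PCNNResults(_ResultsBase):
    method = "PCNN"

    def __init__(self, model, pipe, pnn, pnn_scaler, cnn, cnn_scaler, y_cal):
        self.model = model
        self.pipeline = pipe
        self.pnn = pnn
        self.pnn_scaler = pnn_scaler
        self.cnn = cnn
        self.cnn_scaler = cnn_scaler
        self._y_cal = y_cal
        self._yhat_cal = None  # filled by fit()

    @property
    def loss1(self) -> np.ndarray:
        """PNN training-loss trace (scaled units)."""
        return self.pnn.loss_trace

    @property
    def loss2(self) -> np.ndarray:
        """CNN training-loss trace (scaled units)."""
        return self.cnn.loss_trace

    def predict(self, ds) -> PredictionResult:
        """PNN estimate + CNN correction for every sample of ``ds``."""
        Z = self.pipeline.scores(ds)
        y0 = predict_ann(self.pnn, Z, self.pnn_scaler)
        y_eps = predict_ann(self.cnn, Z, self.cnn_scaler)
        return PredictionResult(y0=y0, y_eps=y_eps)

    def predict_values(self, ds) -> np.ndarray:
        return self.predict(ds).y_hat

    def _summary_extra(self):
        pc, cc = self.model.pnn_config, self.model.cnn_config
        return [
            f"standards (s)            {self.model.standards.n_samples:>10d}",
            f"PCs used                 {self.pipeline.k:>10d}",
            f"PNN  {pc.n_neurons:>3d} x {pc.activation:<10s} loss1 {self.loss1[-1]:.3e}",
            f"CNN  {cc.n_neurons:>3d} x {cc.activation:<10s} loss2 {self.loss2[-1]:.3e}",
        ]
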