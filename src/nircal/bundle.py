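"""Plain-text model bundles: persist a fitted calibration for later use.

A bundle is a directory of human-auditable files — ``meta.json`` with the
format version, method, configuration echo and scaler statistics, plus one
CSV per array (wavelength mask, PCA centre/loadings, network weights).  No
binary formats, so a bundle can be versioned and diffed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .models import ANNResults, PCNNResults, _Pipeline
from .nn import ANNConfig, MLPParams
from .preprocess import MinMaxScaler, PCAModel, WavelengthMask

FORMAT_VERSION = 1

__all__ = ["save_bundle", "load_bundle", "FORMAT_VERSION"]


def _save_arr(path: Path, arr) -> None:
    np.savetxt(path, np.atleast_1d(np.asarray(arr, dtype=float)), fmt="%.17g")


def _load_arr(path: Path) -> np.ndarray:
    return np.loadtxt(path, dtype=float)


def _scaler_meta(s: MinMaxScaler) -> dict:
    return {"min": s.min_, "max": s.max_}


def _scaler_from(meta: dict) -> MinMaxScaler:
    s = MinMaxScaler()
    s.min_, s.max_ = float(meta["min"]), float(meta["max"])
    return s


def _cfg_meta(c: ANNConfig) -> dict:
    return {"n_neurons": c.n_neurons, "activation": c.activation,
            "epochs": c.epochs, "learning_rate": c.learning_rate,
            "seed": c.seed}


def _save_net(d: Path, prefix: str, p: MLPParams) -> dict:
    _save_arr(d / f"{prefix}_W1.csv", p.W1)
    _save_arr(d / f"{prefix}_b1.csv", p.b1)
    _save_arr(d / f"{prefix}_W2.csv", p.W2)
    return {"activation": p.activation, "b2": p.b2,
            "shape": [int(p.W1.shape[0]), int(p.W1.shape[1])]}


def _load_net(d: Path, prefix: str, meta: dict) -> MLPParams:
    k, h = meta["shape"]
    return MLPParams(
        W1=_load_arr(d / f"{prefix}_W1.csv").reshape(k, h),
        b1=np.atleast_1d(_load_arr(d / f"{prefix}_b1.csv")),
        W2=np.atleast_1d(_load_arr(d / f"{prefix}_W2.csv")),
        b2=float(meta["b2"]),
        activation=meta["activation"],
    )


def _save_pipeline(d: Path, pipe: _Pipeline) -> dict:
    meta = {"k": pipe.k, "has_mask": pipe.mask is not None}
    if pipe.mask is not None:
        _save_arr(d / "mask_indices.csv", pipe.mask.kept_indices)
        _save_arr(d / "mask_correlations.csv", pipe.mask.correlations)
        meta["mask_threshold"] = pipe.mask.threshold
    _save_arr(d / "pca_center.csv", pipe.pca.center)
    np.savetxt(d / "pca_loadings.csv", pipe.pca.loadings, fmt="%.17g",
               delimiter=",")
    _save_arr(d / "pca_explained_variance.csv", pipe.pca.explained_variance)
    return meta


def _load_pipeline(d: Path, meta: dict) -> _Pipeline:
    mask = None
    if meta["has_mask"]:
        mask = WavelengthMask(
            kept_indices=np.atleast_1d(_load_arr(d / "mask_indices.csv")).astype(int),
            threshold=float(meta["mask_threshold"]),
            correlations=np.atleast_1d(_load_arr(d / "mask_correlations.csv")),
        )
    center = np.atleast_1d(_load_arr(d / "pca_center.csv"))
    loadings = np.loadtxt(d / "pca_loadings.csv", delimiter=",", dtype=float)
    loadings = loadings.reshape(center.size, -1)
    pca = PCAModel(
        center=center,
        loadings=loadings,
        explained_variance=np.atleast_1d(_load_arr(d / "pca_explained_variance.csv")),
        k=int(meta["k"]),
    )
    return _Pipeline(mask, pca, int(meta["k"]))


def save_bundle(results, out_dir) -> Path:
    """Write a fitted PCNN or ANN results object to a bundle directory."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    if isinstance(results, PCNNResults):
        meta = {
            "format_version": FORMAT_VERSION,
            "method": "pcnn",
            "component": results.model.component,
            "threshold": results.model.threshold,
            "k": results.model.k,
            "pipeline": _save_pipeline(d, results.pipeline),
            "pnn": _save_net(d, "pnn", results.pnn),
            "cnn": _save_net(d, "cnn", results.cnn),
            "pnn_scaler": _scaler_meta(results.pnn_scaler),
            "cnn_scaler": _scaler_meta(results.cnn_scaler),
            "pnn_config": _cfg_meta(results.model.pnn_config),
            "cnn_config": _cfg_meta(results.model.cnn_config),
        }
    elif isinstance(results, ANNResults):
        meta = {
            "format_version": FORMAT_VERSION,
            "method": "ann",
            "component": results.model.component,
            "threshold": results.model.threshold,
            "k": results.model.k,
            "pipeline": _save_pipeline(d, results.pipeline),
            "net": _save_net(d, "net", results.params),
            "scaler": _scaler_meta(results.scaler),
            "config": _cfg_meta(results.model.config),
        }
    else:
        raise TypeError(f"cannot bundle {type(results).__name__}")
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    return d


class LoadedModel:
    """Prediction-only view of a bundle (no training data attached)."""

    def __init__(self, meta: dict, pipeline: _Pipeline, nets: dict,
                 scalers: dict):
        self.meta = meta
        self.method = meta["method"]
        self.component = meta["component"]
        self.pipeline = pipeline
        self._nets = nets
        self._scalers = scalers

    def predict_values(self, ds) -> np.ndarray:
        from .models import predict_ann

        Z = self.pipeline.scores(ds)
        if self.method == "pcnn":
            y0 = predict_ann(self._nets["pnn"], Z, self._scalers["pnn"])
            y_eps = predict_ann(self._nets["cnn"], Z, self._scalers["cnn"])
            return y0 + y_eps
        return predict_ann(self._nets["net"], Z, self._scalers["net"])

    def predict(self, ds):
        from .models import PredictionResult, predict_ann

        if self.method != "pcnn":
            raise ValueError("split predictions only available for PCNN bundles")
        Z = self.pipeline.scores(ds)
        return PredictionResult(
            y0=predict_ann(self._nets["pnn"], Z, self._scalers["pnn"]),
            y_eps=predict_ann(self._nets["cnn"], Z, self._scalers["cnn"]),
        )


def load_bundle(bundle_dir) -> LoadedModel:
    """Load a bundle written by :func:`save_bundle`."""
    d = Path(bundle_dir)
    meta = json.loads((d / "meta.json").read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported bundle format {meta.get('format_version')}")
    pipeline = _load_pipeline(d, meta["pipeline"])
    if meta["method"] == "pcnn":
        nets = {"pnn": _load_net(d, "pnn", meta["pnn"]),
                "cnn": _load_net(d, "cnn", meta["cnn"])}
        scalers = {"pnn": _scaler_from(meta["pnn_scaler"]),
                   "cnn": _scaler_from(meta["cnn_scaler"])}
    elif meta["method"] == "ann":
        nets = {"net": _load_net(d, "net", meta["net"])}
        scalers = {"net": _scaler_from(meta["scaler"])}
    else:
        raise ValueError(f"unknown bundle method {meta['method']!r}")
    return LoadedModel(meta, pipeline, nets, scalers)
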