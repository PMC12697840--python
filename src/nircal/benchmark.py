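"""Shuffle-evaluation protocol on the synthetic benchmark.

Reproduces the shape of the small-sample study: shuffle the realistic
sample pool, hold out a fixed validation set, draw a ~32-sample
calibration set by SELECT (or size-matched random sampling), train, and
score — repeated over 10 seeds and averaged.  Also provides the
parameter-sweep curves (correlation threshold, PC count, NH distance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ANNCalibration, PCNNCalibration, _build_pipeline
from .sampling import nh_for_target_count, repeated_evaluation

__all__ = ["pool_scores_fn", "default_nh", "evaluate_strategies",
           "bias_recovery", "threshold_sweep", "pc_sweep", "nh_sweep"]


def pool_scores_fn(bench):
    """Score extractor for SELECT: mask + PCA fitted on the pool itself."""

    n_pcs = getattr(bench, "n_select_pcs", None) or bench.k

    def scores(pool):
        pipe = _build_pipeline(pool, bench.component, bench.threshold,
                               bench.k, pool.absorbance)
        return pipe.scores(pool)[:, :n_pcs]

    return scores


def default_nh(bench) -> float:
    """NH distance giving ~``bench.target_calibration`` retained samples.

    Derived by bisection on the first shuffle's candidate pool, honouring
    the target calibration-set size of the study design rather than an
    absolute distance scale.
    """
    ds = bench.realistic.shuffled(bench.shuffle_seeds[0])
    pool = ds.subset(np.arange(ds.n_samples - bench.n_validation))
    nh, _ = nh_for_target_count(pool_scores_fn(bench)(pool),
                                bench.target_calibration, tol=2)
    return nh


def _factory(bench, method: str):
    if method == "pcnn":
        def make(cal, val, seed):
            return PCNNCalibration(bench.standards, cal, bench.component,
                                   bench.pnn_config, bench.cnn_config,
                                   k=bench.k, threshold=bench.threshold).fit()
    elif method == "ann":
        def make(cal, val, seed):
            return ANNCalibration(cal, bench.component, bench.ann_config,
                                  k=bench.k, threshold=bench.threshold).fit()
    else:
        raise ValueError(f"unknown method {method!r}")
    return make


def evaluate_strategies(bench, nh: float | None = None,
                        strategies=("pcnn-select", "ann-select", "pcnn-random")):
    """Run the 10-shuffle protocol for each (method, sampling) strategy.

    Returns a dict strategy -> :class:`RepeatedEvaluation`.
    """
    if nh is None:
        nh = default_nh(bench)
    scores = pool_scores_fn(bench)
    out = {}
    for strat in strategies:
        method, sampling = strat.split("-")
        out[strat] = repeated_evaluation(
            bench.realistic,
            strategy="select" if sampling == "select" else "random",
            nh_distance=nh,
            model_factory=_factory(bench, method),
            seed_list=bench.shuffle_seeds,
            n_validation=bench.n_validation,
            scores_fn=scores,
        )
    return out


def bias_recovery(bench, nh: float | None = None):
    """Mean validation error of PNN-only vs corrected predictions.

    Uses the first shuffle's SELECT calibration set.  With a constant
    reference bias injected by the generator, the PNN-only mean error
    tracks the bias while the corrected predictions should cancel it.
    """
    if nh is None:
        nh = default_nh(bench)
    ds = bench.realistic.shuffled(bench.shuffle_seeds[0])
    pool = ds.subset(np.arange(ds.n_samples - bench.n_validation))
    val = ds.subset(np.arange(ds.n_samples - bench.n_validation, ds.n_samples))
    from .sampling import select_samples

    sel = select_samples(pool_scores_fn(bench)(pool), nh)
    cal = pool.subset(sel.retained_indices)
    res = PCNNCalibration(bench.standards, cal, bench.component,
                          bench.pnn_config, bench.cnn_config,
                          k=bench.k, threshold=bench.threshold).fit()
    pred = res.predict(val)
    y = val.component_values(bench.component)
    return {
        "n_calibration": cal.n_samples,
        "bias": bench.reference_bias.get(bench.component, 0.0),
        "mean_error_pnn_only": float(np.mean(pred.y0 - y)),
        "mean_error_corrected": float(np.mean(pred.y_hat - y)),
        "mean_correction": float(np.mean(pred.y_eps)),
    }


def _sweep(bench, param: str, values, nh=None):
    rows = []
    for v in values:
        b = bench
        kw = {}
        if param == "threshold":
            b = _with(bench, threshold=float(v))
        elif param == "k":
            b = _with(bench, k=int(v))
        elif param == "nh":
            kw["nh"] = float(v)
        else:
            raise ValueError(param)
        ev = evaluate_strategies(b, nh=kw.get("nh", nh),
                                 strategies=("pcnn-select",))["pcnn-select"]
        rows.append({param: v, "rpd": ev.mean_rpd, "r2_val": ev.mean_r2_val,
                     "rmse_val": ev.mean_rmsev,
                     "n_cal_mean": float(np.mean([r.n_cal for r in ev.reports]))})
    return pd.DataFrame(rows)


def _with(bench, **kw):
    from dataclasses import replace

    return replace(bench, **kw)


def threshold_sweep(bench, thresholds=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5), nh=None):
    """Correlation-threshold sweep of averaged validation metrics."""
    return _sweep(bench, "threshold", thresholds, nh=nh)


def pc_sweep(bench, ks=range(10, 41, 2), nh=None):
    """PC-count sweep of averaged validation metrics."""
    return _sweep(bench, "k", list(ks), nh=nh)


def nh_sweep(bench, nhs=None):
    """NH-distance sweep of averaged validation metrics and set sizes."""
    if nhs is None:
        nhs = bench.nh_sweep
    return _sweep(bench, "nh", list(nhs))
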