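"""Residual-based nonlinearity diagnostics: runs test and Durbin-Watson.

Whether a spectra-to-component relationship warrants a nonlinear model is
decided from the residuals of a preliminary ordinary-least-squares fit of
the component on the first k PC scores.  Residuals are ordered by
ascending reference value; systematic structure then shows up as (a)
too few sign runs (Wald-Wolfowitz runs test, normal approximation) and
(b) positive lag-1 autocorrelation (Durbin-Watson d below its lower
critical bound).  A component is flagged nonlinear when either test
rejects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import fit_pca

__all__ = [
    "RunsTestResult",
    "DWTestResult",
    "runs_test",
    "durbin_watson",
    "nonlinearity_report",
    "NonlinearityReport",
    "DEFAULT_DW_BOUNDS",
]

# lower/upper Durbin-Watson critical bounds shipped as documented defaults
# for the large-n spectroscopic regime this package targets (alpha = 0.05);
# pass your own (d_L, d_U) for other sample sizes / regressor counts.
DEFAULT_DW_BOUNDS = (1.738, 1.799)


@dataclass
class RunsTestResult:
    n1: int
    n2: int
    r: int
    mu: float
    sigma: float
    z: float
    z_crit: float
    verdict: str  # nonlinear | linear | underpowered


@dataclass
class DWTestResult:
    d: float
    d_lower: float
    d_upper: float
    verdict: str  # nonlinear | linear | inconclusive


def _count_runs(signs: np.ndarray) -> int:
    return int(1 + np.count_nonzero(signs[1:] != signs[:-1]))


def runs_test(residuals, alpha: float = 0.05) -> RunsTestResult:
    """Wald-Wolfowitz runs test on the sign sequence of residuals.

    Uses the normal approximation z = (r - mu + 0.5) / sigma with
    mu = 2 n1 n2 / (n1 + n2) + 1 and
    sigma^2 = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1)).

    The +0.5 continuity correction is applied with a fixed sign, not the
    sign-adaptive textbook variant; the difference shifts the rejection
    boundary by one half run count.  Zero residuals are dropped before
    taking signs.  The approximation is only trusted when n1 > 10 and
    n2 > 10; otherwise the verdict is ``underpowered``.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    e = e[e != 0]
    if e.size == 0:
        raise ValueError("all residuals are zero; runs test undefined")
    signs = np.sign(e)
    n1 = int(np.count_nonzero(signs > 0))
    n2 = int(np.count_nonzero(signs < 0))
    r = _count_runs(signs)
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        mu = 1.0
        sigma = 0.0
        z = np.nan
    else:
        mu = 2.0 * n1 * n2 / n + 1.0
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
        sigma = float(np.sqrt(var))
        z = (r - mu + 0.5) / sigma if sigma > 0 else np.nan
    z_crit = float(stats.norm.ppf(1 - alpha / 2))
    if n1 <= 10 or n2 <= 10:
        verdict = "underpowered"
    else:
        verdict = "nonlinear" if abs(z) > z_crit else "linear"
    return RunsTestResult(n1, n2, r, float(mu), sigma, float(z), z_crit, verdict)


def durbin_watson(residuals, d_lower: float, d_upper: float) -> DWTestResult:
    """Durbin-Watson statistic d = sum (e_i - e_{i-1})^2 / sum e_i^2.

    d < d_lower rejects the no-autocorrelation null (read here as evidence
    of nonlinearity), d > d_upper accepts it, in between is inconclusive.
    Critical bounds are supplied by the caller (tables or simulation) since
    they depend on n, the regressor count and alpha.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    if not d_lower < d_upper:
        raise ValueError("require d_lower < d_upper")
    denom = float(np.sum(e**2))
    if denom == 0:
        raise ValueError("all residuals are zero; d undefined")
    d = float(np.sum(np.diff(e) ** 2) / denom)
    if d < d_lower:
        verdict = "nonlinear"
    elif d > d_upper:
        verdict = "linear"
    else:
        verdict = "inconclusive"
    return DWTestResult(d, float(d_lower), float(d_upper), verdict)


@dataclass
class NonlinearityReport:
    component: str
    runs: RunsTestResult
    dw: DWTestResult
    verdict: str  # nonlinear | linear | inconclusive


def _ols_residuals(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), Z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def nonlinearity_report(ds, component: str, k: int,
                        bounds=DEFAULT_DW_BOUNDS, alpha: float = 0.05,
                        pca=None) -> NonlinearityReport:
    """Combined runs + Durbin-Watson verdict for one component.

    Fits an OLS preliminary linear model of the component on the first k
    PC scores of the dataset's spectra, orders the residuals by ascending
    reference value, and runs both tests.  The component is flagged
    ``nonlinear`` if either test rejects, ``linear`` if both accept, and
    ``inconclusive`` otherwise.
    """
    y = ds.component_values(component)
    if np.isnan(y).any():
        raise ValueError(f"component {component!r} missing for some samples")
    if ds.n_samples < k + 2:
        raise ValueError(f"need at least k+2 = {k + 2} samples")
    if pca is None:
        pca = fit_pca(ds.absorbance, k)
    Z = pca.transform(ds.absorbance)[:, :k]
    e = _ols_residuals(Z, y)
    e_sorted = e[np.argsort(y, kind="stable")]
    runs = runs_test(e_sorted, alpha=alpha)
    dw = durbin_watson(e_sorted, *bounds)
    rejects = (runs.verdict == "nonlinear") or (dw.verdict == "nonlinear")
    accepts = (runs.verdict == "linear") and (dw.verdict == "linear")
    verdict = "nonlinear" if rejects else ("linear" if accepts else "inconclusive")
    return NonlinearityReport(component, runs, dw, verdict)
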