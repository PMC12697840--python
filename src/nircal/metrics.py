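"""Calibration/validation metrics and method-comparison arithmetic.

R^2 and RMSE follow the spectroscopic conventions: RMSE divides by n,
while the validation-set standard deviation S divides by q - 1, so the
residual predictive deviation RPD = S / RMSEV inherits the identity
RPD = sqrt(q / ((q - 1) (1 - R2_V))).  RPD > 2 is conventionally usable
and > 3 good for quantitative work.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["SetScores", "MetricsReport", "score", "percent_change", "compare_methods"]


@dataclass
class SetScores:
    """R^2 / RMSE of one subset; S and RPD only for validation roles."""

    n: int
    r2: float
    rmse: float
    s: float | None = None
    rpd: float | None = None

    @property
    def rpd_is_infinite(self) -> bool:
        return self.rpd is not None and np.isinf(self.rpd)


@dataclass
class MetricsReport:
    """Joint calibration + validation report for one fitted model."""

    r2_cal: float
    r2_val: float
    rmse_cal: float
    rmse_val: float
    s_val: float
    rpd: float
    n_cal: int
    n_val: int
    method: str = ""
    component: str = ""

    @classmethod
    def from_scores(cls, cal: SetScores, val: SetScores, **kw) -> "MetricsReport":
        return cls(cal.r2, val.r2, cal.rmse, val.rmse, val.s, val.rpd,
                   cal.n, val.n, **kw)


def score(y, y_hat, role: str = "validation") -> SetScores:
    """Score predictions against measurements for one subset.

    R^2 = 1 - SSE/SST and RMSE = sqrt(SSE/n); for ``role='validation'``
    also S = sqrt(SST/(q-1)) and RPD = S/RMSEV.  A perfect fit yields
    RPD = inf (flagged, not a usable number).
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("measurements have zero variance")
    sse = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / y.size))
    if role == "calibration":
        return SetScores(y.size, r2, rmse)
    s = float(np.sqrt(sst / (y.size - 1)))
    rpd = np.inf if rmse == 0 else s / rmse
    return SetScores(y.size, r2, rmse, s, rpd)


def percent_change(delta: float, baseline: float) -> float:
    """100 * delta / baseline, rounded half-up to 2 decimals.

    This is the reporting convention for improvement figures such as
    "RPD increased by 40.87% (1.240/3.034)".
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if delta < 0:
        raise ValueError("delta must be >= 0 (pass the magnitude)")
    pct = Decimal(100 * delta / baseline)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compare_methods(reports: dict) -> pd.DataFrame:
    """Pairwise RPD / R^2_V / RMSEV deltas and percent changes.

    ``reports`` maps method name -> :class:`MetricsReport`; every pair
    (method, baseline) with method != baseline yields one row.  All
    reports must share the validation-set size q.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 methods to compare")
    qs = {r.n_val for r in reports.values()}
    if len(qs) != 1:
        raise ValueError(f"validation sizes differ across methods: {sorted(qs)}")
    rows = []
    for name, rep in reports.items():
        for base_name, base in reports.items():
            if name == base_name:
                continue
            row = {"method": name, "baseline": base_name}
            for label, a, b in (
                ("rpd", rep.rpd, base.rpd),
                ("r2_val", rep.r2_val, base.r2_val),
                ("rmse_val", rep.rmse_val, base.rmse_val),
            ):
                delta = a - b
                row[f"{label}_delta"] = delta
                row[f"{label}_pct"] = (
                    percent_change(abs(delta), b) if b > 0 else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)
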