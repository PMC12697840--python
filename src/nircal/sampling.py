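"""Representative-sample selection (SELECT) and the shuffle-evaluation loop.

SELECT prunes a candidate pool down to a diverse calibration set: pairwise
Mahalanobis distances are computed between samples in PC-score space, and a
greedy pass over the pool discards any sample lying within a neighbourhood
distance H of an already-retained sample.  Larger H keeps fewer samples.

Distances are divided by sqrt(k) (k = number of PCs) so that typical
inter-sample distances are O(1) regardless of the score dimensionality;
the exact standardisation used by commercial SELECT implementations is not
public, so :func:`nh_for_target_count` is provided to pick H by the
calibration-set size one wants instead of by absolute distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelectionResult",
    "mahalanobis_matrix",
    "select_samples",
    "nh_for_target_count",
    "repeated_evaluation",
    "RepeatedEvaluation",
]


def mahalanobis_matrix(scores: np.ndarray) -> np.ndarray:
    """Pairwise sqrt(k)-normalised Mahalanobis distance matrix of PC scores.

    D[i, j] = sqrt((z_i - z_j)^T Sigma^-1 (z_i - z_j)) / sqrt(k) with Sigma
    the score covariance, ridge-regularised by 1e-8 * trace/k on the
    diagonal before inversion.
    """
    Z = np.atleast_2d(np.asarray(scores, dtype=float))
    if Z.ndim != 2:
        raise ValueError("scores must be a 2-D matrix")
    n, k = Z.shape
    if n < k + 2:
        raise ValueError(f"need at least k+2 = {k + 2} samples, got {n}")
    cov = np.cov(Z, rowvar=False)
    cov = np.atleast_2d(cov)
    cov = cov + np.eye(k) * (1e-8 * np.trace(cov) / k)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "score covariance singular even after regularization"
        ) from None
    # whiten, then Euclidean distances
    Wh = np.linalg.solve(L, Z.T).T  # rows of Wh are whitened scores
    sq = np.sum(Wh**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Wh @ Wh.T)
    np.maximum(d2, 0.0, out=d2)
    D = np.sqrt(d2) / np.sqrt(k)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


@dataclass
class SelectionResult:
    """Outcome of one greedy SELECT pass."""

    retained_indices: np.ndarray
    nh_distance: float
    discarded_map: dict = field(default_factory=dict)  # discarded -> absorbing retained
    pairwise_min: float = np.nan
    pairwise_median: float = np.nan

    @property
    def n_retained(self) -> int:
        return self.retained_indices.size


def select_samples(scores_or_dist, nh_distance: float, *, is_distance=False) -> SelectionResult:
    """Greedy SELECT over samples in dataset order.

    A sample is retained unless its distance to an already-retained sample
    is <= H; the first such retained neighbour absorbs it.  H = 0 therefore
    removes exact duplicates only, and the first-seen sample wins ties.
    """
    if nh_distance < 0:
        raise ValueError("NH distance must be >= 0")
    D = np.asarray(scores_or_dist, dtype=float)
    if not is_distance:
        D = mahalanobis_matrix(D)
    n = D.shape[0]
    if n == 0:
        raise ValueError("empty input")
    retained: list[int] = []
    discarded: dict[int, int] = {}
    for i in range(n):
        absorbed = None
        for j in retained:
            if D[i, j] <= nh_distance:
                absorbed = j
                break
        if absorbed is None:
            retained.append(i)
        else:
            discarded[i] = absorbed
    idx = np.array(retained, dtype=int)
    if idx.size >= 2:
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        pmin, pmed = float(sub[iu].min()), float(np.median(sub[iu]))
    else:
        pmin = pmed = np.nan
    return SelectionResult(idx, float(nh_distance), discarded, pmin, pmed)


def nh_for_target_count(scores_or_dist, target: int, *, is_distance=False,
                        tol: int = 0, max_iter: int = 60):
    """Bisect the NH distance so SELECT retains ~``target`` samples.

    Returns ``(nh, result)``.  Retained count is non-increasing in H, so a
    bisection on H converges; ``tol`` allows +-tol samples slack.
    """
    D = np.asarray(scores_or_dist, dtype=float)
    if not is_distance:
        D = mahalanobis_matrix(D)
    n = D.shape[0]
    if not 1 <= target <= n:
        raise ValueError(f"target must be in [1, {n}]")
    lo, hi = 0.0, float(D.max()) + 1e-9
    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        res = select_samples(D, mid, is_distance=True)
        if best is None or abs(res.n_retained - target) < abs(best[1].n_retained - target):
            best = (mid, res)
        if abs(res.n_retained - target) <= tol:
            return mid, res
        if res.n_retained > target:
            lo = mid
        else:
            hi = mid
    return best


@dataclass
class RepeatedEvaluation:
    """Per-repeat validation reports plus their arithmetic mean summary."""

    reports: list
    excluded: list
    strategy: str

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in self.reports]))

    @property
    def mean_rpd(self) -> float:
        return self.mean("rpd")

    @property
    def mean_r2_val(self) -> float:
        return self.mean("r2_val")

    @property
    def mean_rmsev(self) -> float:
        return self.mean("rmse_val")


def repeated_evaluation(ds, *, strategy: str, nh_distance=None, model_factory,
                        seed_list, n_validation: int, scores_fn,
                        n_random=None, min_calibration: int = 4,
                        warn=None) -> RepeatedEvaluation:
    """Shuffle / split / select / train / score, repeated over seeds.

    For each seed the dataset order is shuffled, the last ``n_validation``
    samples are held out, and a calibration set is drawn from the remaining
    pool either by SELECT at ``nh_distance`` or at random (size
    ``n_random``, defaulting to the size SELECT would have produced on the
    same shuffle, so the two strategies stay size-matched).

    ``scores_fn(pool_ds)`` must return the PC scores used for selection;
    ``model_factory(cal_ds, val_ds, seed)`` must return a fitted results
    object exposing ``validation_report(val_ds)`` -> MetricsReport.
    """
    if strategy not in ("select", "random"):
        raise ValueError("strategy must be 'select' or 'random'")
    reports, excluded = [], []
    for rep, seed in enumerate(seed_list):
        shuffled = ds.shuffled(seed)
        pool = shuffled.subset(np.arange(shuffled.n_samples - n_validation))
        val = shuffled.subset(
            np.arange(shuffled.n_samples - n_validation, shuffled.n_samples)
        )
        sel = select_samples(scores_fn(pool), nh_distance)
        if strategy == "select":
            cal_idx = sel.retained_indices
        else:
            size = n_random if n_random is not None else sel.n_retained
            rng = np.random.default_rng(seed + 1)
            cal_idx = np.sort(rng.choice(pool.n_samples, size=size, replace=False))
        if cal_idx.size < min_calibration:
            excluded.append(rep)
            if warn is not None:
                warn(f"repeat {rep}: calibration set of {cal_idx.size} below floor "
                     f"{min_calibration}; excluded")
            continue
        cal = pool.subset(cal_idx)
        results = model_factory(cal, val, seed)
        reports.append(results.validation_report(val))
    if not reports:
        raise ValueError("every repeat was excluded; nothing to average")
    return RepeatedEvaluation(reports, excluded, strategy)
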