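"""Linear score prediction from principal-mode coordinates.

A scalar per-subject score (e.g. a 0-8 anatomical rating) is regressed on
centred, unit-variance kernel-PCA coordinates by ordinary least squares.
Model quality is summarized by R^2, the adjusted R^2
(1 - (SSE/(N-p)) / (SST/(N-1))), the F statistic
(R^2/p) / ((1-R^2)/(N-p-1)) with its F(p, N-p-1) tail probability, and
MSE = SSE/N.  Generalization is assessed by repeated random hold-out
cross-validation (a random k-subject test set per repeat), with a
classical partition k-fold available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RegressionResult", "RankDeficientError", "fit_linear", "kfold_cv", "mode_coordinates"]


class RankDeficientError(ValueError):
    """Predictor matrix is rank deficient."""


@dataclass
class RegressionResult:
    beta: np.ndarray       # (p+1,) intercept first
    r2: float
    r2_adj: float
    f_stat: float
    p_value: float
    mse: float             # SSE / N
    sse: float
    sst: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.beta[0] + X @ self.beta[1:]


def fit_linear(X: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on X (an intercept is added internally)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)} entries")
    if n <= p + 1:
        raise ValueError(f"need N > p + 1 (N={n}, p={p})")
    Xd = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < p + 1:
        # identify offending columns via QR pivoting on the design
        from scipy.linalg import qr

        _, R, piv = qr(Xd, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad = sorted(int(piv[i]) - 1 for i in range(len(diag)) if diag[i] < 1e-10 * diag.max())
        raise RankDeficientError(f"rank-deficient design; dependent predictor columns {bad}")
    resid = y - Xd @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (sse / (n - p)) / (sst / (n - 1)) if sst > 0 else 1.0
    denom = (1.0 - r2) / (n - p - 1)
    f = (r2 / p) / denom if denom > 0 else np.inf
    p_value = float(stats.f.sf(f, p, n - p - 1)) if np.isfinite(f) else 0.0
    return RegressionResult(
        beta=beta,
        r2=r2,
        r2_adj=r2_adj,
        f_stat=float(f),
        p_value=p_value,
        mse=sse / n,
        sse=sse,
        sst=sst,
    )


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    n_repeats: int = 1000,
    seed: int = 0,
    scheme: str = "subsample",
) -> tuple[float, float]:
    """Held-out MSE by repeated random k-subject hold-out.

    Each repeat draws k subjects uniformly without replacement as the test
    set and fits on the remaining N-k; returns (mean, sd) of the held-out
    MSE over repeats.  ``scheme="partition"`` instead sweeps disjoint folds
    of size k per repeat (classical k-fold), accumulating one MSE per fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if not 0 < k < n:
        raise ValueError(f"fold size k={k} must be in (0, N={n})")
    rng = np.random.default_rng(seed)
    mses: list[float] = []

    def holdout_mse(test_idx: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        fit = fit_linear(X[~mask], y[~mask])
        pred = fit.predict(X[mask])
        return float(np.mean((y[mask] - pred) ** 2))

    if scheme == "subsample":
        for _ in range(n_repeats):
            mses.append(holdout_mse(rng.choice(n, size=k, replace=False)))
    elif scheme == "partition":
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            for start in range(0, n - k + 1, k):
                mses.append(holdout_mse(perm[start : start + k]))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    arr = np.array(mses)
    return float(arr.mean()), float(arr.std(ddof=1) if len(arr) > 1 else 0.0)


def mode_coordinates(momenta_gram_scores: np.ndarray) -> np.ndarray:
    """Centre and unit-variance scale per-subject mode coordinates."""
    Z = np.atleast_2d(np.asarray(momenta_gram_scores, dtype=float))
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Z / sd
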