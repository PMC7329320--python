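"""Random-forest mean predictor importance (%IncMSE) with permutation p-values.

The importance of a predictor is the percent increase in out-of-bag mean
squared error when that predictor is shuffled, computed per tree and
averaged over the forest (500 trees by default). Significance follows the
response-permutation recipe: the forest is refit to row-permuted responses
to build each predictor's null importance distribution, and
p = (1 + #{null >= observed}) / (1 + n_perm).

Raw importances can be negative (a predictor the trees never use moves MSE
either way); a normalized percent-of-total view is also provided since the
axis convention of published MPI bar charts varies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _forest
from .errors import (DegenerateInputError, InvalidArgumentError,
                     InsufficientDataError)
from .simulate import substream


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=float)), list(X.columns)
    arr = np.ascontiguousarray(np.asarray(X, dtype=float))
    if arr.ndim != 2:
        raise InvalidArgumentError("X must be 2-dimensional")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def default_mtry(p: int) -> int:
    """Predictors tried per split: max(1, p // 3), the regression convention."""
    return max(1, p // 3)


def _check(X, y, n_trees):
    if X.shape[0] != y.size:
        raise InvalidArgumentError("X and y have different numbers of rows")
    if X.shape[0] < 10:
        raise InsufficientDataError(
            f"need >= 10 observations, got {X.shape[0]}")
    if n_trees < 100:
        raise InvalidArgumentError(f"n_trees must be >= 100, got {n_trees}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("response is constant")


def _seeds(seed: int, name: str, k: int) -> np.ndarray:
    return substream(seed, name).integers(0, 2 ** 62, size=k, dtype=np.int64)


def fit_importance(X, y, n_trees: int = 500, seed: int = 0,
                   mtry: int | None = None, min_leaf: int = 5) -> pd.Series:
    """Mean predictor importance (%IncMSE) per predictor.

    Returns a Series indexed by predictor name; identical (data, seed,
    n_trees) give an identical vector.
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    _check(Xm, yv, n_trees)
    mtry = mtry or default_mtry(Xm.shape[1])
    s_fit, s_imp = _seeds(seed, "rf", 2)
    store = _forest.forest_fit(Xm, yv, n_trees, mtry, min_leaf, s_fit)
    mpi, _ = _forest.oob_importance(Xm, yv, *store, s_imp)
    return pd.Series(mpi, index=names, name="mpi")


def normalize_importance(mpi: pd.Series) -> pd.Series:
    """Nonnegative percent-of-total view of an importance vector."""
    clipped = mpi.clip(lower=0.0)
    total = clipped.sum()
    if total == 0:
        return clipped
    return 100.0 * clipped / total


def permutation_significance(X, y, n_perm: int = 99, n_trees: int = 500,
                             seed: int = 0, mtry: int | None = None,
                             min_leaf: int = 5, alpha: float = 0.05,
                             refit: bool = True) -> pd.DataFrame:
    """Response-permutation significance of each predictor's importance.

    ``refit=True`` (default) refits the forest to each permuted response —
    the exact test. ``refit=False`` is a labelled fast approximation that
    keeps the fitted trees and only re-scores OOB error against the
    permuted response.

    Returns a frame with columns predictor, mpi, mpi_normalized, p,
    significant.
    """
    if n_perm < 99:
        raise InvalidArgumentError(f"n_perm must be >= 99, got {n_perm}")
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    _check(Xm, yv, n_trees)
    mtry = mtry or default_mtry(Xm.shape[1])
    s_fit, s_imp = _seeds(seed, "rf", 2)
    store = _forest.forest_fit(Xm, yv, n_trees, mtry, min_leaf, s_fit)
    observed, _ = _forest.oob_importance(Xm, yv, *store, s_imp)
    perm_seeds = _seeds(seed, "rf-perm", 3 * n_perm).reshape(n_perm, 3)
    count = np.zeros(Xm.shape[1])
    yperm = yv.copy()
    for b in range(n_perm):
        _forest.shuffle_inplace(yperm, perm_seeds[b, 0])
        if refit:
            store_b = _forest.forest_fit(Xm, yperm, n_trees, mtry, min_leaf,
                                         perm_seeds[b, 1])
        else:
            store_b = store
        null_mpi, _ = _forest.oob_importance(Xm, yperm, *store_b,
                                             perm_seeds[b, 2])
        count += null_mpi >= observed
    p = (1.0 + count) / (1.0 + n_perm)
    mpi = pd.Series(observed, index=names)
    return pd.DataFrame({
        "predictor": names,
        "mpi": observed,
        "mpi_normalized": normalize_importance(mpi).to_numpy(),
        "p": p,
        "significant": p < alpha,
    })
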