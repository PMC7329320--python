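"""Hellinger-transform variance partitioning between climate and stoichiometry.

The multivariate gene-abundance matrix is Hellinger-transformed (square
root of row proportions) and regressed on two predictor sets — climate
(MAT, MAP) and soil C:N:P stoichiometry (total C, N, P and their ratios) —
by redundancy analysis, i.e. multivariate least squares summarized by the
trace R^2. Adjusted R^2 (Ezekiel) is decomposed by inclusion-exclusion
into the fraction unique to each set, the shared fraction, and the
residual. Significance of each unique fraction comes from a permutation
test on the residualized predictors; negative adjusted fractions are
reported as computed and flagged, never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (CollinearityError, DegenerateInputError,
                     InsufficientDataError, InvalidArgumentError,
                     InvalidInputError)

CLIMATE_SET = ("mat", "map")
STOICH_SET = ("total_c", "total_n", "total_p", "cn", "cp", "np")


def hellinger(matrix):
    """Hellinger transform: sqrt of row-proportion abundances.

    entry(i, j) = sqrt(value(i, j) / row_sum(i)); each output row then has
    unit sum of squares. Input must be nonnegative with no all-zero row.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    arr = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, float)
    if arr.ndim != 2:
        raise InvalidInputError("expected a samples x genes matrix")
    if np.any(arr < 0):
        raise InvalidInputError("Hellinger transform requires nonnegative values")
    row_sums = arr.sum(axis=1)
    zero = np.nonzero(row_sums == 0)[0]
    if zero.size:
        rows = (list(matrix.index[zero]) if is_df else zero.tolist())
        raise DegenerateInputError(f"all-zero row(s): {rows}")
    out = np.sqrt(arr / row_sums[:, None])
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0)


def _names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return list(X.columns)
    return [f"x{j}" for j in range(np.asarray(X).shape[1])]


def _check_rank(Xc: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        dependent = []
        for j in range(1, Xc.shape[1] + 1):
            if np.linalg.matrix_rank(Xc[:, :j]) < j:
                dependent.append(names[j - 1])
        raise CollinearityError(
            f"predictor matrix is rank deficient; dependent column(s): "
            f"{dependent}", columns=dependent)


def _explained(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Explained fraction of total sum of squares (trace R^2)."""
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    sst = float((Yc ** 2).sum())
    if sst == 0:
        raise DegenerateInputError("response matrix has zero total variance")
    return float((fitted ** 2).sum()) / sst


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment: 1 - (1 - r2) (n - 1) / (n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_adjusted_r2(Y, X, allow_rank_deficient: bool = False) -> tuple[float, float]:
    """Trace R^2 and adjusted R^2 of multivariate least squares of Y on X.

    With ``allow_rank_deficient=True`` redundant columns are tolerated and
    the adjustment uses the matrix rank as the predictor count (needed for
    the union of two overlapping predictor sets); otherwise rank deficiency
    raises a :class:`CollinearityError` naming the dependent columns.
    """
    Yv = np.asarray(Y, dtype=float)
    Xv = np.asarray(X, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n, p = Xv.shape
    Xc = _center(Xv)
    if allow_rank_deficient:
        p = int(np.linalg.matrix_rank(Xc))
    else:
        _check_rank(Xc, _names(X))
    if n <= p + 1:
        raise InsufficientDataError(
            f"need samples > predictors + 1 (n={n}, p={p})")
    r2 = _explained(_center(Yv), Xc)
    return r2, adjusted_r2(r2, n, p)


@dataclass
class VarpartResult:
    """Two-set variance partition of adjusted R^2."""

    group: str
    frac_unique_M: float
    frac_unique_S: float
    frac_shared: float
    frac_residual: float
    adj_r2_M: float
    adj_r2_S: float
    adj_r2_MS: float
    p_M: float | None = None
    p_S: float | None = None
    negative_fractions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "frac_unique_M": self.frac_unique_M,
            "frac_shared": self.frac_shared,
            "frac_unique_S": self.frac_unique_S,
            "frac_residual": self.frac_residual,
            "p_M": self.p_M,
            "p_S": self.p_S,
        }


def varpart2(Y, X_M, X_S, group: str = "") -> VarpartResult:
    """Partition adjusted R^2 of Y between predictor sets M and S.

    unique(M) = adjR2(M union S) - adjR2(S); unique(S) symmetric;
    shared = adjR2(M) + adjR2(S) - adjR2(M union S);
    residual = 1 - adjR2(M union S). The four fractions sum to 1.
    """
    Xm = np.asarray(X_M, dtype=float)
    Xs = np.asarray(X_S, dtype=float)
    _, adj_m = rda_adjusted_r2(Y, X_M)
    _, adj_s = rda_adjusted_r2(Y, X_S)
    union = np.column_stack([Xm, Xs])
    union_names = _names(X_M) + _names(X_S)
    union_df = pd.DataFrame(union, columns=union_names)
    _, adj_ms = rda_adjusted_r2(Y, union_df, allow_rank_deficient=True)
    a = adj_ms - adj_s
    c = adj_ms - adj_m
    b = adj_m + adj_s - adj_ms
    resid = 1.0 - adj_ms
    fractions = {"frac_unique_M": a, "frac_unique_S": c,
                 "frac_shared": b, "frac_residual": resid}
    negative = [k for k, v in fractions.items() if v < 0]
    return VarpartResult(group=group, frac_unique_M=a, frac_unique_S=c,
                         frac_shared=b, frac_residual=resid,
                         adj_r2_M=adj_m, adj_r2_S=adj_s, adj_r2_MS=adj_ms,
                         negative_fractions=negative)


def _residualize(A: np.ndarray, B1: np.ndarray) -> np.ndarray:
    """Residuals of each column of A on the column space of B1 (with intercept)."""
    coef, *_ = np.linalg.lstsq(B1, A, rcond=None)
    return A - B1 @ coef


def permutation_test_fraction(Y, X_M, X_S, which: str, n_perm: int = 999,
                              seed: int = 0) -> float:
    """Permutation p-value for one set's unique (partial) fraction.

    The tested set's predictors are residualized on the other set; their
    rows are permuted and re-residualized, and the test statistic is the
    extra explained sum of squares of the (other-set-residualized) response
    on the permuted residual predictors. p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise InvalidArgumentError(f"n_perm must be >= 99, got {n_perm}")
    if which not in ("M", "S"):
        raise InvalidArgumentError("which must be 'M' or 'S'")
    Yv = np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    A = np.asarray(X_M if which == "M" else X_S, dtype=float)
    B = np.asarray(X_S if which == "M" else X_M, dtype=float)
    n = Yv.shape[0]
    B1 = np.column_stack([np.ones(n), B])
    Yres = _residualize(_center(Yv), B1)
    Ares = _residualize(A, B1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7061]))

    def stat(A_cand: np.ndarray) -> float:
        A_orth = _residualize(A_cand, B1)
        coef, *_ = np.linalg.lstsq(A_orth, Yres, rcond=None)
        return float(((A_orth @ coef) ** 2).sum())

    observed = stat(Ares)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(Ares[perm]) >= observed:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for(p: float) -> str:
    for cut, mark in STAR_LEVELS:
        if p < cut:
            return mark
    return ""


def correlation_heatmap_stats(site_vars: pd.DataFrame,
                              gene_abundances: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for every (site variable, gene) pair.

    Cells with p >= 0.05 get an empty star string (drawn blank in the heat
    map convention); constant columns yield an ``undefined`` flag rather
    than an error.
    """
    n = len(site_vars)
    if len(gene_abundances) != n:
        raise InvalidInputError("site_vars and gene_abundances row counts differ")
    if n < 4:
        raise InsufficientDataError("need >= 4 paired observations")
    rows = []
    for var in site_vars.columns:
        x = site_vars[var].to_numpy(float)
        for gene in gene_abundances.columns:
            y = gene_abundances[gene].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({"predictor": var, "gene": gene, "r": np.nan,
                             "p": np.nan, "stars": "", "undefined": True})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"predictor": var, "gene": gene, "r": float(r),
                         "p": float(p), "stars": stars_for(float(p)),
                         "undefined": False})
    return pd.DataFrame(rows)
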