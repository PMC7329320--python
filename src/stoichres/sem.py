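"""Recursive path analysis: climate -> stoichiometry -> resistance.

Observed-variable structural equation models are fit as recursive path
models: every variable is standardized, each endogenous variable is
regressed (OLS) on its parents — for recursive models with uncorrelated
errors this is the maximum-likelihood solution — and the model-implied
correlation matrix is assembled from the path coefficients, with residual
variances chosen so implied variances are exactly 1 (the standardized
solution). Covariances among exogenous variables are fixed at their
observed values; residual correlations are absent.

Fit indices follow the covariance-structure conventions:

    chi^2 = (n - 1) * [ln|Sigma| - ln|S| + tr(S Sigma^-1) - p]
    df    = p(p + 1)/2 - (free parameters)
    RMSEA = sqrt(max(chi^2 - df, 0) / (df (n - 1)))   (0 when df = 0)
    AIC   = chi^2 + 2 * (free parameters)

A good fit requires low RMSEA (< 0.05) and a chi-square P in (0.05, 1].
The a-priori model is pruned to an optimal model by backward elimination
of the least significant edge until all retained edges have p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InvalidModelError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathModel:
    """A directed acyclic path model over observed variables."""

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self):
        declared = set(self.variables)
        for src, tgt in self.edges:
            if src not in declared or tgt not in declared:
                raise InvalidModelError(
                    f"edge ({src} -> {tgt}) references undeclared variable")
        if len(set(self.edges)) != len(self.edges):
            raise InvalidModelError("duplicate edge in model")
        self.topological_order()  # raises on cycles

    def parents(self, var: str) -> list[str]:
        return [s for s, t in self.edges if t == var]

    @property
    def endogenous(self) -> list[str]:
        targets = {t for _, t in self.edges}
        return [v for v in self.variables if v in targets]

    @property
    def exogenous(self) -> list[str]:
        targets = {t for _, t in self.edges}
        return [v for v in self.variables if v not in targets]

    def topological_order(self) -> list[str]:
        indeg = {v: 0 for v in self.variables}
        for _, t in self.edges:
            indeg[t] += 1
        queue = [v for v in self.variables if indeg[v] == 0]
        order = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for s, t in self.edges:
                if s == v:
                    indeg[t] -= 1
                    if indeg[t] == 0:
                        queue.append(t)
        if len(order) != len(self.variables):
            raise InvalidModelError("path model contains a cycle")
        return order

    def without_edge(self, edge: tuple[str, str]) -> "PathModel":
        return PathModel(self.variables,
                         tuple(e for e in self.edges if e != edge))


def parse_model(text: str) -> PathModel:
    """Parse a plain-text edge list: one ``source -> target`` per line.

    Lines starting with '#' (and inline '#' comments) are ignored.
    Variables are declared implicitly by appearing in an edge.
    """
    edges = []
    variables: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise InvalidModelError(
                f"line {lineno}: expected 'source -> target', got {raw!r}")
        src, tgt = (part.strip() for part in line.split("->", 1))
        if not src or not tgt:
            raise InvalidModelError(f"line {lineno}: empty endpoint in {raw!r}")
        for v in (src, tgt):
            if v not in variables:
                variables.append(v)
        edges.append((src, tgt))
    return PathModel(tuple(variables), tuple(edges))


def load_model(path) -> PathModel:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())


def saturated_model(variables) -> PathModel:
    """All pairs connected respecting the given ordering (df = 0 reference)."""
    variables = tuple(variables)
    edges = tuple((variables[i], variables[j])
                  for j in range(len(variables)) for i in range(j))
    return PathModel(variables, edges)


@dataclass
class PathFit:
    """Fitted path model: standardized coefficients and fit indices."""

    model: PathModel
    coefficients: pd.DataFrame  # source, target, beta, se, p
    r2: dict[str, float]
    chi2: float
    df: int
    p_fit: float
    rmsea: float
    aic: float
    n: int
    n_free_params: int
    saturated: bool
    implied: pd.DataFrame = field(repr=False, default=None)

    def coefficient(self, src: str, tgt: str) -> float:
        m = self.coefficients
        row = m[(m["source"] == src) & (m["target"] == tgt)]
        if row.empty:
            raise KeyError(f"no edge {src} -> {tgt} in fitted model")
        return float(row["beta"].iloc[0])


def _standardize(data: pd.DataFrame, variables) -> pd.DataFrame:
    sub = data[list(variables)].astype(float)
    sd = sub.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise CollinearityError(f"constant model variable(s): {bad}", columns=bad)
    return (sub - sub.mean()) / sd


def fit_path_model(model: PathModel, data: pd.DataFrame) -> PathFit:
    """Fit a recursive path model by per-equation standardized OLS."""
    variables = list(model.variables)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise InvalidModelError(f"data lacks model variable(s): {missing}")
    n = len(data)
    max_parents = max((len(model.parents(v)) for v in variables), default=0)
    if n <= max_parents + 1:
        raise InvalidModelError(
            f"need n > max parent count + 1 (n={n}, parents={max_parents})")
    Z = _standardize(data, variables)
    S = Z.cov().to_numpy()  # correlation matrix of the standardized data
    pos = {v: i for i, v in enumerate(variables)}
    p = len(variables)

    order = model.topological_order()
    coef_rows = []
    r2: dict[str, float] = {}
    B = np.zeros((p, p))
    for v in model.endogenous:
        parents = model.parents(v)
        Xp = Z[parents].to_numpy()
        yv = Z[v].to_numpy()
        k = len(parents)
        gram = Xp.T @ Xp
        if np.linalg.matrix_rank(gram) < k:
            raise CollinearityError(
                f"singular parent set for {v!r}: {parents}", columns=parents)
        beta = np.linalg.solve(gram, Xp.T @ yv)
        resid = yv - Xp @ beta
        dof = n - k - 1
        sigma2 = float(resid @ resid) / dof
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(gram)))
        tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        sst = float(yv @ yv)
        r2[v] = 1.0 - float(resid @ resid) / sst
        for parent, b, s_, pv in zip(parents, beta, se, pvals):
            B[pos[v], pos[parent]] = b
            coef_rows.append({"source": parent, "target": v, "beta": float(b),
                              "se": float(s_), "p": float(pv)})

    # model-implied correlation matrix, standardized solution
    implied = np.zeros((p, p))
    exo = model.exogenous
    for a in exo:
        for b_ in exo:
            implied[pos[a], pos[b_]] = S[pos[a], pos[b_]]
    for v in order:
        if v in exo:
            continue
        iv = model.parents(v)
        bvec = np.array([B[pos[v], pos[u]] for u in iv])
        pidx = [pos[u] for u in iv]
        for w in order:
            if w == v:
                break
            cov_vw = float(bvec @ implied[pidx, pos[w]])
            implied[pos[v], pos[w]] = cov_vw
            implied[pos[w], pos[v]] = cov_vw
        explained = float(bvec @ implied[np.ix_(pidx, pidx)] @ bvec)
        # residual variance absorbs the rest (standardized solution); clamp
        # to keep the implied matrix positive definite when a regression
        # explains (numerically) everything
        if explained > 1.0 - 1e-8:
            log.warning("implied explained variance of %r is >= 1 (%.4f); "
                        "residual variance clamped", v, explained)
            implied[pos[v], pos[v]] = explained + 1e-8
        else:
            implied[pos[v], pos[v]] = 1.0

    n_exo = len(exo)
    n_free = len(model.edges) + len(model.endogenous) + n_exo * (n_exo + 1) // 2
    df = p * (p + 1) // 2 - n_free
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_i, logdet_i = np.linalg.slogdet(implied)
    if sign_s <= 0 or sign_i <= 0:
        raise CollinearityError("singular observed or implied covariance matrix")
    discrepancy = logdet_i - logdet_s + float(
        np.trace(S @ np.linalg.inv(implied))) - p
    chi2 = max((n - 1) * discrepancy, 0.0)
    saturated = df == 0
    p_fit = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    rmsea = (float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
             if df > 0 else 0.0)
    aic = chi2 + 2.0 * n_free
    coefficients = pd.DataFrame(
        coef_rows, columns=["source", "target", "beta", "se", "p"])
    return PathFit(model=model, coefficients=coefficients, r2=r2, chi2=chi2,
                   df=df, p_fit=p_fit, rmsea=rmsea, aic=aic, n=n,
                   n_free_params=n_free, saturated=saturated,
                   implied=pd.DataFrame(implied, index=variables,
                                        columns=variables))


@dataclass
class FitVerdict:
    """Per-criterion goodness-of-fit verdict."""

    rmsea_ok: bool
    p_ok: bool
    good: bool
    saturated: bool
    detail: dict


def evaluate_fit(fit: PathFit, rmsea_threshold: float = 0.05,
                 p_threshold: float = 0.05) -> FitVerdict:
    """Judge a fit: RMSEA < 0.05 and 0.05 < chi-square P <= 1.

    A df = 0 (saturated) model trivially satisfies both and is flagged.
    """
    rmsea_ok = fit.rmsea < rmsea_threshold
    p_ok = p_threshold < fit.p_fit <= 1.0
    return FitVerdict(rmsea_ok=rmsea_ok, p_ok=p_ok, good=rmsea_ok and p_ok,
                      saturated=fit.saturated,
                      detail={"rmsea": fit.rmsea, "p_fit": fit.p_fit,
                              "chi2": fit.chi2, "df": fit.df, "aic": fit.aic})


def prune_to_optimal(model: PathModel, data: pd.DataFrame,
                     alpha: float = 0.05) -> tuple[PathModel, PathFit, PathFit]:
    """Backward single-edge elimination to the optimal model.

    Iteratively removes the retained edge with the largest p >= alpha (ties
    broken by smaller |coefficient|, then lexicographic edge name), refits,
    and stops when every edge has p < alpha. Returns (optimal model,
    optimal fit, a-priori fit).
    """
    apriori_fit = fit_path_model(model, data)
    current = model
    fit = apriori_fit
    while current.edges:
        coefs = fit.coefficients
        weak = coefs[coefs["p"] >= alpha]
        if weak.empty:
            break
        weak = weak.sort_values(
            by=["p", "beta", "source", "target"],
            key=lambda col: col.abs() if col.name == "beta" else col,
            ascending=[False, True, True, True])
        drop = (weak.iloc[0]["source"], weak.iloc[0]["target"])
        current = current.without_edge(drop)
        if not current.edges:
            log.warning("pruning removed every edge; returning empty model")
            fit = fit_path_model(current, data)
            break
        fit = fit_path_model(current, data)
    return current, fit, apriori_fit
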