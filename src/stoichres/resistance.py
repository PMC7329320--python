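"""Disturbance resistance of functional-gene abundances.

The resistance index of Orwin & Wardle compares a treated sample against
its paired environmental control:

    RS = 1 - 2|D0| / (C0 + |D0|)

where C0 is the control value and D0 the treated-minus-control difference
at the end of the incubation. RS = +1 means complete resistance (no
change), RS = 0 a 100% change relative to control, and RS -> -1 as the
change grows without bound (the bound is never attained for C0 > 0). The
index is standardized by the control value, so it is comparable across
soils and genes.

Group-level scores use the share-normalization: for each gene, each
sample's share of the gene's total abundance across samples is computed,
and shares are averaged over the member genes of the C-, N- or P-cycling
group. Scores therefore sum to one across samples and are invariant to
rescaling any single gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (AlignmentError, DegenerateInputError, InvalidArgumentError,
                     InvalidInputError, UndefinedControlError)

log = logging.getLogger(__name__)


def resistance_index(c0, treated):
    """Orwin-Wardle resistance index RS = 1 - 2|D0|/(C0 + |D0|).

    Accepts scalars or arrays. ``c0`` must be strictly positive (the index
    is standardized by the control value) and ``treated`` nonnegative.
    """
    c0_arr = np.asarray(c0, dtype=float)
    t_arr = np.asarray(treated, dtype=float)
    if np.any(c0_arr <= 0):
        raise UndefinedControlError(
            "resistance is undefined for control value <= 0")
    if np.any(t_arr < 0):
        raise InvalidArgumentError("treated abundance must be >= 0")
    d0 = np.abs(t_arr - c0_arr)
    rs = 1.0 - 2.0 * d0 / (c0_arr + d0)
    if np.isscalar(c0) and np.isscalar(treated):
        return float(rs)
    return rs


def resistance_table(control: pd.DataFrame, treated: pd.DataFrame,
                     stressor: str) -> pd.DataFrame:
    """Per-(site, gene) resistance records for one stressor.

    Both inputs are long abundance tables; they must cover the same
    (site, gene) pairs. Pairs whose control abundance is nonpositive are
    excluded and reported in ``result.attrs['excluded']`` (the index is
    undefined there), never silently dropped.
    """
    ckeys = set(zip(control["site_id"], control["gene"]))
    tkeys = set(zip(treated["site_id"], treated["gene"]))
    if ckeys != tkeys:
        missing = sorted(ckeys ^ tkeys)
        raise AlignmentError(
            f"control/treated tables misaligned; unmatched (site, gene) "
            f"pairs: {missing[:10]}{'...' if len(missing) > 10 else ''}",
            missing=missing)
    c = control.set_index(["site_id", "gene"])["copies_per_g"]
    t = treated.set_index(["site_id", "gene"])["copies_per_g"]
    t = t.reindex(c.index)
    df = pd.DataFrame({
        "site_id": [k[0] for k in c.index],
        "gene": [k[1] for k in c.index],
        "stressor": stressor,
        "c0": c.to_numpy(float),
        "treated": t.to_numpy(float),
    })
    bad = df["c0"] <= 0
    excluded = df.loc[bad, ["site_id", "gene"]].to_records(index=False).tolist()
    if excluded:
        log.warning("excluding %d records with nonpositive control abundance "
                    "(resistance undefined): %s", len(excluded), excluded[:5])
    df = df[~bad].reset_index(drop=True)
    df["rs"] = resistance_index(df["c0"].to_numpy(), df["treated"].to_numpy())
    df.attrs["excluded"] = excluded
    return df


def normalize_group(values: pd.DataFrame, group_genes) -> pd.Series:
    """Share-normalized group abundance per sample.

    ``values`` is a samples x genes frame of nonnegative abundances. For
    each gene in ``group_genes``, each sample's share of the gene's total
    across samples is computed; the group score is the mean share over the
    member genes. Scores sum to 1 across samples.
    """
    group_genes = list(group_genes)
    if len(group_genes) == 0:
        raise InvalidArgumentError("group_genes is empty")
    missing = [g for g in group_genes if g not in values.columns]
    if missing:
        raise InvalidInputError(f"genes absent from value matrix: {missing}")
    sub = values[group_genes].to_numpy(dtype=float)
    if sub.shape[0] == 0:
        raise InvalidInputError("no samples in value matrix")
    if np.any(sub < 0):
        raise InvalidInputError("abundances must be nonnegative")
    col_sums = sub.sum(axis=0)
    zero = [g for g, s in zip(group_genes, col_sums) if s == 0]
    if zero:
        raise DegenerateInputError(f"all-zero gene column(s): {zero}")
    shares = sub / col_sums
    return pd.Series(shares.mean(axis=1), index=values.index, name="score")


def group_resistance(records: pd.DataFrame, group_genes, mode: str = "mean") -> pd.Series:
    """Aggregate per-gene resistance to a per-site group score.

    ``mode='mean'`` (default) is the arithmetic mean of member-gene RS per
    site. ``mode='eq2'`` applies the share normalization after shifting RS
    by +1 to enforce nonnegativity (RS can be negative; the share rule
    presumes nonnegative inputs).
    """
    group_genes = list(group_genes)
    wide = records.pivot(index="site_id", columns="gene", values="rs")
    missing = [g for g in group_genes if g not in wide.columns
               or wide[g].isna().any()]
    if missing:
        raise InvalidInputError(
            f"incomplete resistance coverage for gene(s): {missing}")
    if mode == "mean":
        return wide[group_genes].mean(axis=1).rename("score")
    if mode == "eq2":
        return normalize_group(wide[group_genes] + 1.0, group_genes)
    raise InvalidArgumentError(f"unknown mode {mode!r}; use 'mean' or 'eq2'")


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with tie correction."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p": 2.0 * stats.norm.sf(abs(z))})
    return pd.DataFrame(rows)


def _letters(names, mean_scores, pairwise: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Compact-letter display: groups sharing a letter do not differ."""
    differs = {(r["group_a"], r["group_b"]) for _, r in pairwise.iterrows()
               if r["p"] < alpha}
    differs |= {(b, a) for a, b in differs}
    order = sorted(names, key=lambda g: -mean_scores[g])
    letter_sets: list[set[str]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all((g, h) not in differs for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    out = {g: "" for g in names}
    for idx, s in enumerate(letter_sets):
        for g in s:
            out[g] += chr(ord("a") + idx)
    return out


def compare_stressors(records: pd.DataFrame, genes=None, alpha: float = 0.05,
                      method: str = "kruskal") -> pd.DataFrame:
    """Per-gene omnibus test of resistance across stressors with post hoc.

    ``records`` is a long resistance table with >= 2 stressors. The default
    omnibus is Kruskal-Wallis (RS is bounded and skewed) with Dunn post-hoc
    pairwise z tests; ``method='anova'`` substitutes one-way ANOVA with
    pairwise Welch t tests. Omnibus p-values are Benjamini-Hochberg
    corrected across genes; the asterisk flag uses the corrected p.
    """
    stressors = sorted(records["stressor"].unique())
    if len(stressors) < 2:
        raise InvalidInputError("need >= 2 stressors to compare")
    if method not in ("kruskal", "anova"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    genes = list(genes) if genes is not None else sorted(records["gene"].unique())
    rows = []
    for gene in genes:
        sub = records[records["gene"] == gene]
        groups = {s: sub.loc[sub["stressor"] == s, "rs"].to_numpy(float)
                  for s in stressors}
        if any(v.size < 2 for v in groups.values()):
            raise InvalidInputError(
                f"gene {gene!r}: every stressor needs >= 2 sites")
        samples = list(groups.values())
        if np.ptp(np.concatenate(samples)) == 0:
            statistic, p = 0.0, 1.0
            pairwise = pd.DataFrame(
                [{"group_a": a, "group_b": b, "z": 0.0, "p": 1.0}
                 for i, a in enumerate(stressors) for b in stressors[i + 1:]])
        elif method == "kruskal":
            statistic, p = stats.kruskal(*samples)
            pairwise = _dunn_pairwise(groups)
        else:
            statistic, p = stats.f_oneway(*samples)
            pw = []
            for i, a in enumerate(stressors):
                for b in stressors[i + 1:]:
                    t, tp = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                    pw.append({"group_a": a, "group_b": b, "z": t, "p": tp})
            pairwise = pd.DataFrame(pw)
        means = {s: float(np.mean(groups[s])) for s in stressors}
        letters = _letters(stressors, means, pairwise, alpha)
        rows.append({"gene": gene, "statistic": float(statistic), "p": float(p),
                     "pairwise": pairwise, "mean_rs": means, "letters": letters})
    out = pd.DataFrame(rows)
    out["p_adj"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    out["significant"] = out["p_adj"] < alpha
    return out
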