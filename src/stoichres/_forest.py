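"""Numba kernels for the regression random forest.

A purpose-built CART forest exposing what the importance analysis needs and
libraries do not: per-tree out-of-bag (OOB) permutation importance
(%IncMSE). Trees are grown on bootstrap samples with `mtry` candidate
features per split, variance-reduction splitting, and a minimum node size
(the regression-forest convention is 5). All randomness comes from an
explicit splitmix64 state, so results are bit-reproducible for a seed.

The forest is stored as dense per-tree node arrays so that importance can
be recomputed against a permuted response without refitting (the fast
approximation mode) as well as refit from scratch (the exact
response-permutation test).
"""

from __future__ import annotations

import numba as nb
import numpy as np

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)


@nb.njit(cache=False, inline="always")
def _mix(state):
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    z = z ^ (z >> U64(31))
    return state, z


@nb.njit(cache=False)
def _build_tree(X, y, boot, mtry, min_leaf, state,
                feature, threshold, left, right, value):
    """Grow one CART regression tree on the bootstrap index array ``boot``.

    Node arrays are filled in place; returns (node_count, state).
    """
    n = boot.size
    p = X.shape[1]
    idx = boot.copy()
    cap = feature.size
    stack_start = np.empty(cap, np.int64)
    stack_end = np.empty(cap, np.int64)
    stack_node = np.empty(cap, np.int64)
    feat_pool = np.empty(p, np.int64)
    for j in range(p):
        feat_pool[j] = j
    xbuf = np.empty(n, np.float64)
    ibuf = np.empty(n, np.int64)
    node_count = 1
    top = 0
    stack_start[0] = 0
    stack_end[0] = n
    stack_node[0] = 0
    top = 1
    while top > 0:
        top -= 1
        start = stack_start[top]
        end = stack_end[top]
        node = stack_node[top]
        m = end - start
        s = 0.0
        for i in range(start, end):
            s += y[idx[i]]
        mean = s / m
        value[node] = mean
        feature[node] = -1
        if m < 2 * min_leaf:
            continue
        ss = 0.0
        for i in range(start, end):
            d = y[idx[i]] - mean
            ss += d * d
        if ss <= 1e-12 * m:
            continue
        # sample mtry candidate features without replacement
        for k in range(mtry):
            state, z = _mix(state)
            j = k + np.int64(z % U64(p - k))
            tmp = feat_pool[k]
            feat_pool[k] = feat_pool[j]
            feat_pool[j] = tmp
        best_gain = -1e308
        best_f = -1
        best_thr = 0.0
        for k in range(mtry):
            f = feat_pool[k]
            for i in range(m):
                xbuf[i] = X[idx[start + i], f]
            order = np.argsort(xbuf[:m])
            sl = 0.0
            for i in range(m - 1):
                sl += y[idx[start + order[i]]]
                nl = i + 1
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                if xbuf[order[i]] == xbuf[order[i + 1]]:
                    continue
                sr = s - sl
                gain = sl * sl / nl + sr * sr / nr
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (xbuf[order[i]] + xbuf[order[i + 1]])
        if best_f < 0:
            continue
        nl = 0
        for i in range(start, end):
            if X[idx[i], best_f] <= best_thr:
                ibuf[nl] = idx[i]
                nl += 1
        nr = nl
        for i in range(start, end):
            if X[idx[i], best_f] > best_thr:
                ibuf[nr] = idx[i]
                nr += 1
        for i in range(m):
            idx[start + i] = ibuf[i]
        lnode = node_count
        rnode = node_count + 1
        node_count += 2
        feature[node] = best_f
        threshold[node] = best_thr
        left[node] = lnode
        right[node] = rnode
        stack_start[top] = start
        stack_end[top] = start + nl
        stack_node[top] = lnode
        top += 1
        stack_start[top] = start + nl
        stack_end[top] = end
        stack_node[top] = rnode
        top += 1
    return node_count, state


@nb.njit(cache=False, inline="always")
def _predict_row(feature, threshold, left, right, value, X, row, swap_f,
                 swap_val):
    """Predict one row, optionally overriding feature ``swap_f`` with ``swap_val``."""
    node = 0
    while feature[node] >= 0:
        f = feature[node]
        x = swap_val if f == swap_f else X[row, f]
        node = left[node] if x <= threshold[node] else right[node]
    return value[node]


@nb.njit(cache=False)
def forest_fit(X, y, n_trees, mtry, min_leaf, seed):
    """Fit the forest; returns per-tree node arrays and the in-bag matrix."""
    n, p = X.shape
    cap = 2 * n + 1
    feature = np.full((n_trees, cap), -1, np.int64)
    threshold = np.zeros((n_trees, cap), np.float64)
    left = np.full((n_trees, cap), -1, np.int64)
    right = np.full((n_trees, cap), -1, np.int64)
    value = np.zeros((n_trees, cap), np.float64)
    inbag = np.zeros((n_trees, n), np.uint8)
    state = U64(seed)
    state, _ = _mix(state)
    state, _ = _mix(state)
    boot = np.empty(n, np.int64)
    for t in range(n_trees):
        for i in range(n):
            state, z = _mix(state)
            j = np.int64(z % U64(n))
            boot[i] = j
            inbag[t, j] += 1
        _, state = _build_tree(X, y, boot, mtry, min_leaf, state,
                               feature[t], threshold[t], left[t], right[t],
                               value[t])
    return feature, threshold, left, right, value, inbag


@nb.njit(cache=False)
def forest_predict(X, feature, threshold, left, right, value):
    """Mean prediction over all trees (for diagnostics and oracles)."""
    n = X.shape[0]
    n_trees = feature.shape[0]
    out = np.zeros(n, np.float64)
    for t in range(n_trees):
        for i in range(n):
            out[i] += _predict_row(feature[t], threshold[t], left[t],
                                   right[t], value[t], X, i, -1, 0.0)
    return out / n_trees


@nb.njit(cache=False)
def oob_importance(X, y, feature, threshold, left, right, value, inbag, seed):
    """Per-tree OOB permutation importance, averaged over trees.

    For each tree: baseline OOB MSE, then for each predictor the OOB MSE
    with that predictor's OOB values permuted. The per-tree MSE increases
    are averaged over trees and expressed as a percentage of the forest's
    mean OOB MSE (a per-tree ratio would be biased upward by the noisy
    small-sample denominator). Also returns the forest OOB MSE.
    """
    n, p = X.shape
    n_trees = feature.shape[0]
    inc = np.zeros(p, np.float64)
    cnt = np.zeros(p, np.float64)
    state = U64(seed)
    state, _ = _mix(state)
    oob_idx = np.empty(n, np.int64)
    perm = np.empty(n, np.int64)
    mse_sum = 0.0
    mse_trees = 0
    for t in range(n_trees):
        noob = 0
        for i in range(n):
            if inbag[t, i] == 0:
                oob_idx[noob] = i
                noob += 1
        if noob < 2:
            continue
        base = 0.0
        for k in range(noob):
            pr = _predict_row(feature[t], threshold[t], left[t], right[t],
                              value[t], X, oob_idx[k], -1, 0.0)
            d = pr - y[oob_idx[k]]
            base += d * d
        base /= noob
        mse_sum += base
        mse_trees += 1
        if base <= 0.0:
            continue
        for f in range(p):
            for k in range(noob):
                perm[k] = k
            for k in range(noob - 1, 0, -1):
                state, z = _mix(state)
                j = np.int64(z % U64(k + 1))
                tmp = perm[k]
                perm[k] = perm[j]
                perm[j] = tmp
            mse = 0.0
            for k in range(noob):
                swap_val = X[oob_idx[perm[k]], f]
                pr = _predict_row(feature[t], threshold[t], left[t], right[t],
                                  value[t], X, oob_idx[k], f, swap_val)
                d = pr - y[oob_idx[k]]
                mse += d * d
            mse /= noob
            inc[f] += mse - base
            cnt[f] += 1.0
    oob_mse = mse_sum / mse_trees if mse_trees > 0 else np.nan
    out = np.zeros(p, np.float64)
    for f in range(p):
        if cnt[f] > 0 and oob_mse > 0:
            out[f] = 100.0 * (inc[f] / cnt[f]) / oob_mse
    return out, oob_mse


@nb.njit(cache=False)
def shuffle_inplace(arr, seed):
    """Deterministic Fisher-Yates shuffle (splitmix64 stream)."""
    state = U64(seed)
    state, _ = _mix(state)
    n = arr.size
    for k in range(n - 1, 0, -1):
        state, z = _mix(state)
        j = np.int64(z % U64(k + 1))
        tmp = arr[k]
        arr[k] = arr[j]
        arr[j] = tmp
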