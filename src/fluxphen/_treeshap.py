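"""Double-precision tree-SHAP for XGBoost regression boosters.

Path-dependent tree-SHAP (Lundberg's polynomial-time algorithm) evaluated
in float64.  The booster's native ``pred_contribs`` implements the same
algorithm in float32, whose cross-tree accumulation error (~1e-5 on
hundreds of trees) is too large to certify additivity of the attributions
at 1e-6; this module recomputes the contributions from the extracted tree
structure in double precision, so base value + sum of contributions equals
the float64 model margin to machine precision.  The native float32 output
is used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import json

import numpy as np
from numba import njit

__all__ = ["TreeEnsemble", "shap_values"]


class TreeEnsemble:
    """Flat float64 arrays for every tree of a fitted booster."""

    def __init__(self, booster):
        cfg = json.loads(booster.save_config())
        self.base_score = float(cfg["learner"]["learner_model_param"]["base_score"])
        df = booster.trees_to_dataframe()
        feature_names = booster.feature_names
        name_to_idx = {n: i for i, n in enumerate(feature_names)}

        trees = []
        for tree_id, sub in df.groupby("Tree"):
            sub = sub.sort_values("Node")
            n = len(sub)
            id_to_node = {s: i for i, s in zip(sub["Node"], sub["ID"])}
            left = np.full(n, -1, dtype=np.int64)
            right = np.full(n, -1, dtype=np.int64)
            default = np.full(n, -1, dtype=np.int64)
            feat = np.full(n, -1, dtype=np.int64)
            thresh = np.zeros(n, dtype=np.float64)
            value = np.zeros(n, dtype=np.float64)
            cover = np.zeros(n, dtype=np.float64)
            for row in sub.itertuples():
                i = row.Node
                cover[i] = row.Cover
                if row.Feature == "Leaf":
                    value[i] = np.float64(np.float32(row.Gain))
                else:
                    feat[i] = name_to_idx[row.Feature]
                    thresh[i] = np.float64(np.float32(row.Split))
                    left[i] = id_to_node[row.Yes]
                    right[i] = id_to_node[row.No]
                    default[i] = id_to_node[row.Missing]
            trees.append((left, right, default, feat, thresh, value, cover))

        self.n_features = len(feature_names)
        self.max_depth = max(_tree_depth(t[0], t[1]) for t in trees)
        # pack into ragged-flat arrays
        self._offsets = np.zeros(len(trees) + 1, dtype=np.int64)
        for i, t in enumerate(trees):
            self._offsets[i + 1] = self._offsets[i] + len(t[3])
        total = self._offsets[-1]
        self.left = np.empty(total, dtype=np.int64)
        self.right = np.empty(total, dtype=np.int64)
        self.default = np.empty(total, dtype=np.int64)
        self.feat = np.empty(total, dtype=np.int64)
        self.thresh = np.empty(total, dtype=np.float64)
        self.value = np.empty(total, dtype=np.float64)
        self.cover = np.empty(total, dtype=np.float64)
        for i, (l, r, d, f, s, v, c) in enumerate(trees):
            sl = slice(self._offsets[i], self._offsets[i + 1])
            self.left[sl], self.right[sl], self.default[sl] = l, r, d
            self.feat[sl], self.thresh[sl] = f, s
            self.value[sl], self.cover[sl] = v, c

    def predict_margin(self, x: np.ndarray) -> np.ndarray:
        """Float64 margin: base_score plus the per-tree leaf values."""
        return _predict_margin(
            np.ascontiguousarray(x, dtype=np.float64), self._offsets,
            self.left, self.right, self.default, self.feat, self.thresh,
            self.value, self.base_score,
        )

    def expected_value(self) -> float:
        """Cover-weighted mean leaf value per tree, summed, plus base score."""
        total = self.base_score
        for i in range(len(self._offsets) - 1):
            sl = slice(self._offsets[i], self._offsets[i + 1])
            leaf = self.feat[sl] < 0
            root_cover = self.cover[sl][0]
            total += float(
                np.sum(self.value[sl][leaf] * self.cover[sl][leaf]) / root_cover
            )
        return total


def _tree_depth(left, right, node=0, depth=0):
    if left[node] < 0:
        return depth
    return max(
        _tree_depth(left, right, left[node], depth + 1),
        _tree_depth(left, right, right[node], depth + 1),
    )


def shap_values(ensemble: TreeEnsemble, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-sample, per-feature SHAP values and the base (expected) value.

    ``x`` is (n_samples, n_features), NaN for missing.  Returns
    ``(phi, base)`` with ``phi.sum(axis=1) + base == predict_margin(x)``
    to float64 round-off.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    phi = _shap_all(
        x, ensemble._offsets, ensemble.left, ensemble.right, ensemble.default,
        ensemble.feat, ensemble.thresh, ensemble.value, ensemble.cover,
        ensemble.n_features, ensemble.max_depth,
    )
    return phi, ensemble.expected_value()


@njit(cache=True)
def _descend(x_row, off, left, right, default, feat, thresh, node):
    while feat[off + node] >= 0:
        v = x_row[feat[off + node]]
        if np.isnan(v):
            node = default[off + node]
        elif np.float32(v) < np.float32(thresh[off + node]):
            node = left[off + node]
        else:
            node = right[off + node]
    return node


@njit(cache=True)
def _predict_margin(x, offsets, left, right, default, feat, thresh, value, base):
    n = x.shape[0]
    out = np.full(n, base)
    for s in range(n):
        for t in range(len(offsets) - 1):
            off = offsets[t]
            leaf = _descend(x[s], off, left, right, default, feat, thresh, 0)
            out[s] += value[off + leaf]
    return out


@njit(cache=True)
def _extend(feat_path, zero_path, one_path, pweight, m, pz, po, pi):
    feat_path[m] = pi
    zero_path[m] = pz
    one_path[m] = po
    pweight[m] = 1.0 if m == 0 else 0.0
    for i in range(m - 1, -1, -1):
        pweight[i + 1] += po * pweight[i] * (i + 1.0) / (m + 1.0)
        pweight[i] = pz * pweight[i] * (m - i) / (m + 1.0)


@njit(cache=True)
def _unwind(feat_path, zero_path, one_path, pweight, m, i):
    n = pweight[m]
    o = one_path[i]
    z = zero_path[i]
    if o != 0.0:
        for j in range(m - 1, -1, -1):
            t = pweight[j]
            pweight[j] = n * (m + 1.0) / ((j + 1.0) * o)
            n = t - pweight[j] * z * (m - j) / (m + 1.0)
    else:
        for j in range(m - 1, -1, -1):
            pweight[j] = pweight[j] * (m + 1.0) / (z * (m - j))
    for j in range(i, m):
        feat_path[j] = feat_path[j + 1]
        zero_path[j] = zero_path[j + 1]
        one_path[j] = one_path[j + 1]


@njit(cache=True)
def _unwound_sum(zero_path, one_path, pweight, m, i):
    o = one_path[i]
    z = zero_path[i]
    total = 0.0
    if o != 0.0:
        n = pweight[m]
        for j in range(m - 1, -1, -1):
            tmp = n * (m + 1.0) / ((j + 1.0) * o)
            total += tmp
            n = pweight[j] - tmp * z * (m - j) / (m + 1.0)
    else:
        for j in range(m - 1, -1, -1):
            total += pweight[j] * (m + 1.0) / (z * (m - j))
    return total


@njit(cache=True)
def _tree_shap_one(
    x_row, phi_row, off, left, right, default, feat, thresh, value, cover,
    feat_buf, zero_buf, one_buf, pw_buf,
    st_node, st_depth, st_m, st_pz, st_po, st_pi,
):
    """Depth-first traversal of one tree (explicit stack).

    All path work happens on the way down (extend / unwind) and at leaves,
    so a LIFO stack with one scratch path row per depth reproduces the
    recursive algorithm: a node at depth d only writes rows >= d, and its
    sibling is processed after the whole subtree, when row d-1 is intact.
    """
    top = 0
    st_node[0] = 0
    st_depth[0] = 0
    st_m[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    while top >= 0:
        node = st_node[top]
        depth = st_depth[top]
        m = st_m[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]
        top -= 1

        fp = feat_buf[depth]
        zp = zero_buf[depth]
        op = one_buf[depth]
        pw = pw_buf[depth]
        if depth > 0:
            for j in range(m):
                fp[j] = feat_buf[depth - 1][j]
                zp[j] = zero_buf[depth - 1][j]
                op[j] = one_buf[depth - 1][j]
                pw[j] = pw_buf[depth - 1][j]
        _extend(fp, zp, op, pw, m, pz, po, pi)
        m += 1

        if feat[off + node] < 0:  # leaf
            for i in range(1, m):
                w = _unwound_sum(zp, op, pw, m - 1, i)
                phi_row[fp[i]] += w * (op[i] - zp[i]) * value[off + node]
            continue

        split = feat[off + node]
        v = x_row[split]
        if np.isnan(v):
            hot = default[off + node]
        elif np.float32(v) < np.float32(thresh[off + node]):
            hot = left[off + node]
        else:
            hot = right[off + node]
        cold = right[off + node] if hot == left[off + node] else left[off + node]

        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, m):
            if fp[i] == split:
                k = i
                break
        if k >= 0:
            iz = zp[k]
            io = op[k]
            _unwind(fp, zp, op, pw, m - 1, k)
            m -= 1

        node_cover = cover[off + node]
        # push cold first so the hot child is processed (and its subtree
        # finished) before the cold sibling reads the parent's path row
        top += 1
        st_node[top] = cold
        st_depth[top] = depth + 1
        st_m[top] = m
        st_pz[top] = iz * cover[off + cold] / node_cover
        st_po[top] = 0.0
        st_pi[top] = split
        top += 1
        st_node[top] = hot
        st_depth[top] = depth + 1
        st_m[top] = m
        st_pz[top] = iz * cover[off + hot] / node_cover
        st_po[top] = io
        st_pi[top] = split


@njit(cache=True)
def _shap_all(
    x, offsets, left, right, default, feat, thresh, value, cover,
    n_features, max_depth,
):
    n = x.shape[0]
    n_trees = len(offsets) - 1
    phi = np.zeros((n, n_features))
    size = max_depth + 2
    feat_buf = np.zeros((size, size + 1), dtype=np.int64)
    zero_buf = np.zeros((size, size + 1))
    one_buf = np.zeros((size, size + 1))
    pw_buf = np.zeros((size, size + 1))
    stack_cap = size + 2
    st_node = np.zeros(stack_cap, dtype=np.int64)
    st_depth = np.zeros(stack_cap, dtype=np.int64)
    st_m = np.zeros(stack_cap, dtype=np.int64)
    st_pz = np.zeros(stack_cap)
    st_po = np.zeros(stack_cap)
    st_pi = np.zeros(stack_cap, dtype=np.int64)
    for s in range(n):
        for t in range(n_trees):
            _tree_shap_one(
                x[s], phi[s], offsets[t], left, right, default, feat, thresh,
                value, cover, feat_buf, zero_buf, one_buf, pw_buf,
                st_node, st_depth, st_m, st_pz, st_po, st_pi,
            )
    return phi
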