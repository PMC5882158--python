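"""Gradient boosted regression trees with Poisson and softmax objectives.

This is a from-scratch, fully introspectable implementation of second-order
gradient boosting ("XGBoost-style"): each tree is grown by exact greedy
split search, every split's (feature, threshold, gain) is recorded, and the
model object exposes the complete tree structure so downstream analyses can
read tuning information and feature contributions directly out of the trees.

The regularized objective for one tree is

    O = sum_j [ G_j w_j + 1/2 (H_j + lam) w_j^2 ] + gamma * |leaves|

with G_j, H_j the summed first/second derivatives of the loss over the
samples in leaf j.  The optimal leaf weight is w*_j = -G_j / (H_j + lam)
and the gain of a split (L, R) of a parent node P is

    gain = 1/2 [ G_L^2/(H_L+lam) + G_R^2/(H_R+lam) - (G_L+G_R)^2/(H_L+H_R+lam) ] - gamma

For the Poisson objective the margin is the log-intensity:
lambda_i = exp(base_score + eta * sum_t f_t(x_i)), with per-sample
derivatives g = exp(margin) - y and h = exp(margin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "BoostParams",
    "Tree",
    "SplitRecord",
    "BoostedTrees",
    "BoostedTreesResults",
    "poisson_grad_hess",
    "softmax_grad_hess",
    "leaf_weight",
    "split_gain",
    "find_best_split",
    "grow_tree",
    "fit",
    "predict_rate",
    "extract_splits",
    "feature_gain_summary",
    "poisson_loss",
]

# margins are clipped to this magnitude before exponentiation
_MARGIN_CLIP = 30.0


@dataclass
class BoostParams:
    """Hyper-parameters of the boosted-tree model.

    gamma is the per-leaf complexity penalty, lam the L2 penalty on leaf
    weights (defaults 0.4 and 0.0), eta the shrinkage applied to each
    tree's leaf values, leaf_cap a symmetric bound on raw leaf weights that
    keeps exp(margin) well behaved for the Poisson objective.
    """

    n_trees: int = 100
    max_depth: int = 5
    gamma: float = 0.4
    lam: float = 0.0
    eta: float = 0.3
    base_score: float | None = None
    leaf_cap: float = 0.7
    objective: str = "poisson"
    n_classes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.gamma < 0 or self.lam < 0:
            raise ValueError("gamma and lam must be >= 0")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must be in (0, 1]")
        if self.objective not in ("poisson", "softmax"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "softmax" and not self.n_classes:
            raise ValueError("softmax objective requires n_classes")


@dataclass
class SplitRecord:
    tree_index: int
    depth: int
    feature_index: int
    threshold: float
    gain: float


class Tree:
    """A single regression tree stored as parallel node arrays (preorder).

    ``feature[i] == -1`` marks a leaf; internal nodes carry the split
    feature, threshold and gain, plus child indices.
    """

    __slots__ = ("feature", "threshold", "gain", "left", "right", "value", "depth")

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.gain: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.depth: list[int] = []

    def _add_leaf(self, depth: int, w: float) -> int:
        i = len(self.feature)
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.gain.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(float(w))
        self.depth.append(depth)
        return i

    def _add_split(self, depth: int, f: int, thr: float, gain: float) -> int:
        i = len(self.feature)
        self.feature.append(int(f))
        self.threshold.append(float(thr))
        self.gain.append(float(gain))
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(np.nan)
        self.depth.append(depth)
        return i

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f == -1)

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        """Raw (unshrunk) leaf value for each row of X."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        feat = np.asarray(self.feature)
        thr = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        val = np.asarray(self.value)
        active = feat[node] >= 0
        while active.any():
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, feat[nd]] <= thr[nd]
            node[idx] = np.where(go_left, left[nd], right[nd])
            active = feat[node] >= 0
        return val[node]

    def leaf_assignment(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        node = np.zeros(n, dtype=np.int64)
        feat = np.asarray(self.feature)
        thr = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        active = feat[node] >= 0
        while active.any():
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, feat[nd]] <= thr[nd]
            node[idx] = np.where(go_left, left[nd], right[nd])
            active = feat[node] >= 0
        return node

    def to_dict(self) -> dict:
        return {
            "feature": list(map(int, self.feature)),
            "threshold": [None if np.isnan(t) else float(t) for t in self.threshold],
            "gain": [None if np.isnan(g) else float(g) for g in self.gain],
            "left": list(map(int, self.left)),
            "right": list(map(int, self.right)),
            "value": [None if np.isnan(v) else float(v) for v in self.value],
            "depth": list(map(int, self.depth)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        t = cls()
        t.feature = [int(f) for f in d["feature"]]
        t.threshold = [np.nan if x is None else float(x) for x in d["threshold"]]
        t.gain = [np.nan if x is None else float(x) for x in d["gain"]]
        t.left = [int(x) for x in d["left"]]
        t.right = [int(x) for x in d["right"]]
        t.value = [np.nan if x is None else float(x) for x in d["value"]]
        t.depth = [int(x) for x in d["depth"]]
        return t


# ---------------------------------------------------------------------------
# loss derivatives


def poisson_grad_hess(margin, target):
    """First/second derivatives of the Poisson negative log-likelihood
    with respect to the log-intensity margin: g = e^margin - y, h = e^margin.
    """
    margin = np.asarray(margin, dtype=float)
    target = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(margin)):
        raise ValueError("non-finite margin")
    if np.any(target < 0):
        raise ValueError("negative spike counts")
    mu = np.exp(np.clip(margin, -_MARGIN_CLIP, _MARGIN_CLIP))
    return mu - target, mu


def softmax_grad_hess(margins, label):
    """Per-class derivatives of the multiclass log loss.

    g_k = p_k - 1{k = label},  h_k = p_k (1 - p_k)  with p = softmax(margins).
    Accepts a single margin vector + integer label, or (n, K) margins with
    n labels.
    """
    m = np.asarray(margins, dtype=float)
    single = m.ndim == 1
    if single:
        m = m[None, :]
        label = np.asarray([label])
    else:
        label = np.asarray(label)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite margins")
    p = _softmax(m)
    g = p.copy()
    g[np.arange(len(label)), label.astype(int)] -= 1.0
    h = p * (1.0 - p)
    if single:
        return g[0], h[0]
    return g, h


def _softmax(m: np.ndarray) -> np.ndarray:
    z = m - m.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def poisson_loss(y, rate):
    """Negative Poisson log-likelihood sum_i [rate_i - y_i log rate_i]
    (without the constant log y_i! term)."""
    y = np.asarray(y, dtype=float)
    rate = np.asarray(rate, dtype=float)
    return float(np.sum(rate - y * np.log(np.maximum(rate, 1e-300))))


# ---------------------------------------------------------------------------
# split machinery


def leaf_weight(G: float, H: float, lam: float, leaf_cap: float = np.inf) -> float:
    """Optimal leaf weight w* = -G/(H + lam), clipped to +-leaf_cap."""
    denom = H + lam
    if denom <= 0:
        raise ValueError("degenerate leaf: H + lam <= 0")
    w = -G / denom
    return float(np.clip(w, -leaf_cap, leaf_cap))


def split_gain(GL: float, HL: float, GR: float, HR: float, lam: float, gamma: float) -> float:
    """Objective improvement of splitting a node into (L, R)."""
    return 0.5 * (
        GL * GL / (HL + lam)
        + GR * GR / (HR + lam)
        - (GL + GR) ** 2 / (HL + HR + lam)
    ) - gamma


def find_best_split(g, h, X, lam: float = 0.0, gamma: float = 0.0):
    """Exact greedy split search over all features and all midpoints of
    consecutive sorted unique feature values.

    Returns ``(feature_index, threshold, gain)`` for the maximum-gain split,
    or ``None`` if no split has strictly positive gain.  Ties are broken by
    lowest feature index, then smallest threshold.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == g.size and X.ndim == 2:
        pass
    if X.shape[0] != g.size:
        X = X.T
    if g.size < 2:
        return None
    sorted_idx = [np.argsort(X[:, f], kind="stable") for f in range(X.shape[1])]
    best = _best_split_presorted(X, g, h, sorted_idx, lam, gamma)
    return best


def _best_split_presorted(X, g, h, sorted_idx, lam, gamma):
    """Generic exact split search; sorted_idx[f] sorts the node's samples by
    feature f.  Returns (feature, threshold, gain) or None."""
    best_gain = 0.0
    best = None
    for f, order in enumerate(sorted_idx):
        xs = X[order, f]
        cg = np.cumsum(g[order])
        ch = np.cumsum(h[order])
        Gt, Ht = cg[-1], ch[-1]
        cut = xs[1:] > xs[:-1]
        if not cut.any():
            continue
        GL = cg[:-1][cut]
        HL = ch[:-1][cut]
        GR = Gt - GL
        HR = Ht - HL
        with np.errstate(divide="ignore", invalid="ignore"):
            gains = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam)
                           - Gt**2 / (Ht + lam)) - gamma
        gains[(HL + lam <= 0) | (HR + lam <= 0)] = -np.inf
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain = float(gains[k])
            thr = 0.5 * (xs[:-1][cut][k] + xs[1:][cut][k])
            best = (f, float(thr), best_gain)
    return best


@njit(cache=True)
def _hist_best_split(XiT, idx, g, h, n_vals, lam, gamma):  # pragma: no cover
    """Exact split search for small non-negative integer features by value
    histograms (no sorting).  XiT is (d, n) C-contiguous; g, h are aligned
    with idx.  Returns (feature, threshold, gain)."""
    d = XiT.shape[0]
    best_gain = 0.0
    best_f = -1
    best_thr = 0.0
    Gv = np.empty(n_vals)
    Hv = np.empty(n_vals)
    Cv = np.empty(n_vals, dtype=np.int64)
    for f in range(d):
        Gv[:] = 0.0
        Hv[:] = 0.0
        Cv[:] = 0
        vmin = n_vals - 1
        vmax = 0
        row = XiT[f]
        for k in range(idx.size):
            v = row[idx[k]]
            Gv[v] += g[k]
            Hv[v] += h[k]
            Cv[v] += 1
            if v < vmin:
                vmin = v
            if v > vmax:
                vmax = v
        if vmin >= vmax:
            continue
        Gt = 0.0
        Ht = 0.0
        for v in range(vmin, vmax + 1):
            Gt += Gv[v]
            Ht += Hv[v]
        GL = 0.0
        HL = 0.0
        last = -1
        for v in range(vmin, vmax + 1):
            if Cv[v] == 0:
                continue
            if last >= 0:
                GR = Gt - GL
                HR = Ht - HL
                if HL + lam > 0 and HR + lam > 0 and Ht + lam > 0:
                    gn = 0.5 * (GL * GL / (HL + lam) + GR * GR / (HR + lam)
                                - Gt * Gt / (Ht + lam)) - gamma
                    if gn > best_gain:
                        best_gain = gn
                        best_f = f
                        best_thr = 0.5 * (last + v)
            GL += Gv[v]
            HL += Hv[v]
            last = v
    return best_f, best_thr, best_gain


def grow_tree(g, h, X, params: BoostParams) -> Tree:
    """Grow one regression tree by greedy recursive splitting.

    Splits are accepted only with strictly positive gain; recursion stops at
    ``params.max_depth``.  Leaves carry the optimal (clipped) weight of their
    sample set.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    X = np.atleast_2d(np.asarray(X))
    if X.shape[0] != g.size:
        X = X.T
    use_hist = np.issubdtype(X.dtype, np.integer) and X.size and X.min() >= 0 and X.max() <= 255
    if use_hist:
        XiT = np.ascontiguousarray(X.T, dtype=np.int64)
        tree = Tree()
        out = np.empty(g.size)
        _grow_hist(tree, XiT, g, h, np.arange(g.size), 0, params, out, int(XiT.max()) + 1)
        return tree
    Xf = np.ascontiguousarray(X, dtype=float)
    sorted_idx = [np.argsort(Xf[:, f], kind="stable") for f in range(Xf.shape[1])]
    tree = Tree()
    out = np.empty(g.size)
    _grow_presorted(tree, Xf, g, h, sorted_idx, 0, params, out)
    return tree


def _grow_presorted(tree, X, g, h, sorted_idx, depth, params, out):
    idx = sorted_idx[0]
    best = None
    if depth < params.max_depth and idx.size >= 2:
        best = _best_split_presorted(X, g, h, sorted_idx, params.lam, params.gamma)
    if best is None:
        w = leaf_weight(g[idx].sum(), h[idx].sum(), params.lam, params.leaf_cap)
        out[idx] = w
        return tree._add_leaf(depth, w)
    f, thr, gain = best
    node = tree._add_split(depth, f, thr, gain)
    left_sorted = []
    right_sorted = []
    for arr in sorted_idx:
        mask = X[arr, f] <= thr
        left_sorted.append(arr[mask])
        right_sorted.append(arr[~mask])
    tree.left[node] = _grow_presorted(tree, X, g, h, left_sorted, depth + 1, params, out)
    tree.right[node] = _grow_presorted(tree, X, g, h, right_sorted, depth + 1, params, out)
    return node


def _grow_hist(tree, XiT, g, h, idx, depth, params, out, n_vals, gI=None, hI=None):
    if gI is None:
        gI, hI = g[idx], h[idx]
    best_f = -1
    if depth < params.max_depth and idx.size >= 2:
        best_f, best_thr, best_gain = _hist_best_split(
            XiT, idx, gI, hI, n_vals, params.lam, params.gamma
        )
    if best_f < 0:
        w = leaf_weight(gI.sum(), hI.sum(), params.lam, params.leaf_cap)
        out[idx] = w
        return tree._add_leaf(depth, w)
    node = tree._add_split(depth, best_f, best_thr, best_gain)
    mask = XiT[best_f][idx] <= best_thr
    tree.left[node] = _grow_hist(tree, XiT, g, h, idx[mask], depth + 1, params,
                                 out, n_vals, gI[mask], hI[mask])
    tree.right[node] = _grow_hist(tree, XiT, g, h, idx[~mask], depth + 1, params,
                                  out, n_vals, gI[~mask], hI[~mask])
    return node


# ---------------------------------------------------------------------------
# model / results


class BoostedTrees:
    """Boosted-tree model for spike counts (Poisson) or class labels
    (softmax), statsmodels-style: construct from data, then :meth:`fit`.

    Parameters
    ----------
    y : array (n,)
        Non-negative spike counts (poisson) or integer class labels
        in ``[0, n_classes)`` (softmax).
    X : array (n, d)
        Feature matrix.  Small non-negative integer features (e.g. binned
        spike counts) are split with a fast exact histogram path.
    params : BoostParams, optional
    feature_names : sequence of str, optional
    """

    def __init__(self, y, X, params: BoostParams | None = None,
                 feature_names: Sequence[str] | None = None):
        X = np.atleast_2d(np.asarray(X))
        if X.shape[0] != np.asarray(y).size:
            X = X.T
        self.X = X
        self.y = np.asarray(y)
        if self.y.size == 0:
            raise ValueError("empty training data")
        self.params = params or BoostParams()
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        if len(feature_names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.feature_names = list(feature_names)

    def fit(self) -> "BoostedTreesResults":
        p = self.params
        if p.objective == "poisson":
            return self._fit_poisson()
        return self._fit_softmax()

    def _fit_poisson(self) -> "BoostedTreesResults":
        p = self.params
        y = np.asarray(self.y, dtype=float)
        if np.any(y < 0):
            raise ValueError("negative spike counts")
        base = p.base_score
        if base is None:
            base = float(np.log(y.mean() + 1e-8))
        margin = np.full(y.size, base)
        trees: list[Tree] = []
        losses = []
        X = self.X
        use_hist = (np.issubdtype(X.dtype, np.integer) and X.size
                    and X.min() >= 0 and X.max() <= 255)
        if use_hist:
            XiT = np.ascontiguousarray(X.T, dtype=np.int64)
            n_vals = int(XiT.max()) + 1
        else:
            Xf = np.ascontiguousarray(X, dtype=float)
            presort = [np.argsort(Xf[:, f], kind="stable") for f in range(Xf.shape[1])]
        for _ in range(p.n_trees):
            g, h = poisson_grad_hess(np.clip(margin, -_MARGIN_CLIP, _MARGIN_CLIP), y)
            tree = Tree()
            out = np.empty(y.size)
            if use_hist:
                _grow_hist(tree, XiT, g, h, np.arange(y.size), 0, p, out, n_vals)
            else:
                _grow_presorted(tree, Xf, g, h, presort, 0, p, out)
            if tree.n_nodes == 1 and abs(tree.value[0]) < 1e-12:
                # a null single leaf changes nothing; stop boosting
                break
            trees.append(tree)
            margin = margin + p.eta * out
            rate = np.exp(np.clip(margin, -_MARGIN_CLIP, _MARGIN_CLIP))
            losses.append(poisson_loss(y, rate))
        return BoostedTreesResults(self, trees, base, np.asarray(losses))

    def _fit_softmax(self) -> "BoostedTreesResults":
        p = self.params
        K = int(p.n_classes)
        labels = np.asarray(self.y, dtype=np.int64)
        if labels.min() < 0 or labels.max() >= K:
            raise ValueError("labels out of range")
        n = labels.size
        base = 0.0 if p.base_score is None else float(p.base_score)
        margins = np.full((n, K), base)
        X = self.X
        use_hist = (np.issubdtype(X.dtype, np.integer) and X.size
                    and X.min() >= 0 and X.max() <= 255)
        if use_hist:
            XiT = np.ascontiguousarray(X.T, dtype=np.int64)
            n_vals = int(XiT.max()) + 1
        else:
            Xf = np.ascontiguousarray(X, dtype=float)
            presort = [np.argsort(Xf[:, f], kind="stable") for f in range(Xf.shape[1])]
        rounds: list[list[Tree]] = []
        losses = []
        for _ in range(p.n_trees):
            g, h = softmax_grad_hess(margins, labels)
            round_trees = []
            for k in range(K):
                tree = Tree()
                out = np.empty(n)
                if use_hist:
                    _grow_hist(tree, XiT, g[:, k], h[:, k], np.arange(n), 0, p, out, n_vals)
                else:
                    _grow_presorted(tree, Xf, g[:, k], h[:, k], presort, 0, p, out)
                round_trees.append(tree)
                margins[:, k] += p.eta * out
            rounds.append(round_trees)
            pmat = _softmax(margins)
            losses.append(float(-np.mean(np.log(np.clip(
                pmat[np.arange(n), labels], 1e-15, 1.0)))))
        return BoostedTreesResults(self, rounds, base, np.asarray(losses))


class BoostedTreesResults:
    """Fitted boosted-tree model with full structural introspection."""

    def __init__(self, model: BoostedTrees | None, trees, base_score: float,
                 training_loss: np.ndarray, feature_names=None, params=None):
        self.model = model
        self.trees = trees
        self.base_score = float(base_score)
        self.training_loss = np.asarray(training_loss)
        self.params = params if params is not None else (
            model.params if model is not None else BoostParams())
        self.feature_names = list(feature_names) if feature_names is not None else (
            list(model.feature_names) if model is not None else [])

    # -- prediction ---------------------------------------------------------

    @property
    def objective(self) -> str:
        return self.params.objective

    def _check_X(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X))
        if X.shape[1] != len(self.feature_names):
            if X.shape[0] == len(self.feature_names):
                X = X.T
            else:
                raise ValueError(
                    f"feature count mismatch: got {X.shape[1]}, "
                    f"expected {len(self.feature_names)}")
        return X

    def predict_margin(self, X) -> np.ndarray:
        X = self._check_X(X)
        if self.objective == "poisson":
            m = np.full(X.shape[0], self.base_score)
            for tree in self.trees:
                m += self.params.eta * tree.predict_value(X)
            return m
        K = int(self.params.n_classes)
        m = np.full((X.shape[0], K), self.base_score)
        for round_trees in self.trees:
            for k, tree in enumerate(round_trees):
                m[:, k] += self.params.eta * tree.predict_value(X)
        return m

    def predict(self, X) -> np.ndarray:
        """Poisson: per-sample intensity (expected count per bin).
        Softmax: (n, K) class probabilities."""
        m = self.predict_margin(X)
        if self.objective == "poisson":
            return np.exp(np.clip(m, -_MARGIN_CLIP, _MARGIN_CLIP))
        return _softmax(m)

    # -- introspection ------------------------------------------------------

    def _flat_trees(self):
        if self.objective == "poisson":
            for t, tree in enumerate(self.trees):
                yield t, tree
        else:
            i = 0
            for round_trees in self.trees:
                for tree in round_trees:
                    yield i, tree
                    i += 1

    def split_records(self) -> list[SplitRecord]:
        """One record per internal node, ordered by (tree_index, preorder)."""
        recs = []
        for t, tree in self._flat_trees():
            for i in range(tree.n_nodes):
                if tree.feature[i] >= 0:
                    recs.append(SplitRecord(t, tree.depth[i], tree.feature[i],
                                            tree.threshold[i], tree.gain[i]))
        return recs

    def splits(self):
        """Split records as a DataFrame (adds the feature name)."""
        import pandas as pd

        recs = self.split_records()
        df = pd.DataFrame([asdict(r) for r in recs],
                          columns=["tree_index", "depth", "feature_index",
                                   "threshold", "gain"])
        df["feature"] = [self.feature_names[i] for i in df["feature_index"]] \
            if len(df) else []
        return df

    def gain_summary(self):
        """Per-feature (n_splits, total_gain, mean_gain); unused features
        report zeros.  total_gain == n_splits * mean_gain."""
        import pandas as pd

        d = len(self.feature_names)
        n_splits = np.zeros(d, dtype=int)
        total = np.zeros(d)
        for rec in self.split_records():
            n_splits[rec.feature_index] += 1
            total[rec.feature_index] += rec.gain
        mean = np.divide(total, n_splits, out=np.zeros(d), where=n_splits > 0)
        return pd.DataFrame({
            "feature": self.feature_names,
            "n_splits": n_splits,
            "total_gain": total,
            "mean_gain": mean,
        })

    def summary(self) -> str:
        lines = [
            "Boosted trees results",
            "=" * 48,
            f"objective:      {self.objective}",
            f"n_trees:        {len(self.trees)}"
            + ("" if self.objective == "poisson"
               else f" rounds x {self.params.n_classes} classes"),
            f"max_depth:      {self.params.max_depth}",
            f"gamma, lam:     {self.params.gamma}, {self.params.lam}",
            f"eta:            {self.params.eta}",
            f"base_score:     {self.base_score:.6g}",
        ]
        if self.training_loss.size:
            lines.append(f"final training loss: {self.training_loss[-1]:.6g}")
        gs = self.gain_summary()
        top = gs.sort_values("total_gain", ascending=False).head(10)
        lines.append("-" * 48)
        lines.append(f"{'feature':<20}{'n_splits':>10}{'total_gain':>14}")
        for _, row in top.iterrows():
            lines.append(f"{row['feature']:<20}{row['n_splits']:>10d}"
                         f"{row['total_gain']:>14.4f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str | None:
        d = {
            "params": asdict(self.params),
            "feature_names": self.feature_names,
            "base_score": self.base_score,
            "training_loss": [float(x) for x in self.training_loss],
        }
        if self.objective == "poisson":
            d["trees"] = [t.to_dict() for t in self.trees]
        else:
            d["trees"] = [[t.to_dict() for t in rnd] for rnd in self.trees]
        s = json.dumps(d)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
            return None
        return s

    @classmethod
    def from_json(cls, source) -> "BoostedTreesResults":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        params = BoostParams(**d["params"])
        if params.objective == "poisson":
            trees = [Tree.from_dict(t) for t in d["trees"]]
        else:
            trees = [[Tree.from_dict(t) for t in rnd] for rnd in d["trees"]]
        return cls(None, trees, d["base_score"], np.asarray(d["training_loss"]),
                   feature_names=d["feature_names"], params=params)


# ---------------------------------------------------------------------------
# functional surface


def fit(X, y, params: BoostParams | None = None, feature_names=None) -> BoostedTreesResults:
    """Fit a boosted-tree model (functional form of ``BoostedTrees(...).fit()``)."""
    return BoostedTrees(y, X, params=params, feature_names=feature_names).fit()


def predict_rate(results: BoostedTreesResults, X) -> np.ndarray:
    """Per-sample Poisson intensity of a fitted model."""
    if results.objective != "poisson":
        raise ValueError("predict_rate requires the poisson objective")
    return results.predict(X)


def extract_splits(results: BoostedTreesResults) -> list[SplitRecord]:
    return results.split_records()


def feature_gain_summary(results: BoostedTreesResults):
    return results.gain_summary()
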