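"""Exact additive Shapley attributions for tree ensembles.

Implements the polynomial-time path-dependent tree algorithm: attributions
are the Shapley values of the cover-weighted conditional-expectation value
function defined over the tree structure.  The per-node recursion maintains
a path of unique features with "zero" fractions (proportion of training
subsets flowing down when the feature is excluded), "one" fractions
(indicator when it is included) and permutation weights; leaves unwind each
path feature to accumulate its contribution.

Local accuracy holds by construction: for each tree,
``sum(phi) = tree(x) - E_cover[tree]``.

Functions are written in plain numpy-compatible Python and are JIT-compiled
with numba when available (pure-Python execution is exact but slow; unit
tests only need tiny ensembles).
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "ensemble_shap_values", "ensemble_expected_value"]


def _unwind(d, z, o, w, length, i):
    """Remove path element i in place (inverse of the extension step)."""
    ud = length - 1
    of = o[i]
    zf = z[i]
    n = w[ud]
    for j in range(ud - 1, -1, -1):
        if of != 0.0:
            t = w[j]
            w[j] = n * (ud + 1) / ((j + 1) * of)
            n = t - w[j] * zf * (ud - j) / (ud + 1)
        else:
            w[j] = w[j] * (ud + 1) / (zf * (ud - j))
    for j in range(i, ud):
        d[j] = d[j + 1]
        z[j] = z[j + 1]
        o[j] = o[j + 1]


def _unwound_sum(z, o, w, length, i):
    """Sum of path weights after removing element i, without mutating."""
    ud = length - 1
    of = o[i]
    zf = z[i]
    n = w[ud]
    total = 0.0
    if of != 0.0:
        for j in range(ud - 1, -1, -1):
            t = n * (ud + 1) / ((j + 1) * of)
            total += t
            n = w[j] - t * zf * (ud - j) / (ud + 1)
    else:
        for j in range(ud - 1, -1, -1):
            total += w[j] * (ud + 1) / (zf * (ud - j))
    return total


def _recurse(node, cl, cr, ft, th, val, cov, x, phi, d, z, o, w,
             pbase, plen, parent_f, parent_zf, parent_of):
    # copy the parent's unique path into this level's scratch slot and
    # extend it with the incoming split; slots share one flat buffer
    base = pbase + plen
    for i in range(plen):
        d[base + i] = d[pbase + i]
        z[base + i] = z[pbase + i]
        o[base + i] = o[pbase + i]
        w[base + i] = w[pbase + i]
    d[base + plen] = parent_f
    z[base + plen] = parent_zf
    o[base + plen] = parent_of
    w[base + plen] = 1.0 if plen == 0 else 0.0
    for i in range(plen - 1, -1, -1):
        w[base + i + 1] += parent_of * w[base + i] * (i + 1) / (plen + 1)
        w[base + i] = parent_zf * w[base + i] * (plen - i) / (plen + 1)
    length = plen + 1

    if cl[node] < 0:  # leaf
        leaf = val[node]
        for i in range(1, length):
            s = _unwound_sum(z[base:base + length], o[base:base + length],
                             w[base:base + length], length, i)
            phi[d[base + i]] += s * (o[base + i] - z[base + i]) * leaf
    else:
        f = ft[node]
        if x[f] <= th[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        hot_zf = cov[hot] / cov[node]
        cold_zf = cov[cold] / cov[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, length):
            if d[base + i] == f:
                k = i
                break
        if k >= 0:
            iz = z[base + k]
            io = o[base + k]
            _unwind(d[base:base + length], z[base:base + length],
                    o[base:base + length], w[base:base + length], length, k)
            length -= 1
        _recurse(hot, cl, cr, ft, th, val, cov, x, phi, d, z, o, w,
                 base, length, f, hot_zf * iz, io)
        _recurse(cold, cl, cr, ft, th, val, cov, x, phi, d, z, o, w,
                 base, length, f, cold_zf * iz, 0.0)


def _shap_tree(cl, cr, ft, th, val, cov, X, phi, maxdepth):
    size = (maxdepth + 2) * (maxdepth + 3) // 2
    d = np.empty(size, np.int64)
    z = np.empty(size, np.float64)
    o = np.empty(size, np.float64)
    w = np.empty(size, np.float64)
    for r in range(X.shape[0]):
        _recurse(0, cl, cr, ft, th, val, cov, X[r], phi[r], d, z, o, w,
                 0, 0, -1, 1.0, 1.0)


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    # note: no cache=True -- numba's on-disk cache miscompiles
    # self-recursive functions
    _unwind = njit(_unwind)
    _unwound_sum = njit(_unwound_sum)
    _recurse = njit(_recurse)
    _shap_tree = njit(_shap_tree)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def tree_shap_values(tree, X: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Shapley attributions (n_samples x n_features) for one sklearn tree.

    ``tree`` is a fitted ``sklearn.tree._tree.Tree`` (e.g. ``est.tree_``);
    ``scale`` multiplies leaf values (ensemble learning rate).
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    _shap_tree(
        tree.children_left.astype(np.int64),
        tree.children_right.astype(np.int64),
        tree.feature.astype(np.int64),
        tree.threshold.astype(np.float64),
        (tree.value[:, 0, 0] * scale).astype(np.float64),
        tree.weighted_n_node_samples.astype(np.float64),
        X,
        phi,
        int(tree.max_depth),
    )
    return phi


def _tree_expected_value(tree, scale: float = 1.0) -> float:
    """Cover-weighted mean leaf value of a tree."""
    leaves = tree.children_left < 0
    cov = tree.weighted_n_node_samples[leaves]
    vals = tree.value[leaves, 0, 0] * scale
    return float(np.sum(cov * vals) / np.sum(cov))


def _iter_trees(model):
    """Yield (tree_, scale) for a fitted GradientBoostingRegressor."""
    lr = model.learning_rate
    for est in model.estimators_[:, 0]:
        yield est.tree_, lr


def _init_value(model) -> float:
    import numpy as _np

    # DummyRegressor init ignores X
    return float(model.init_.predict(_np.zeros((1, 1)))[0])


def ensemble_expected_value(model) -> float:
    """Base value: initial prediction plus each tree's expected value."""
    return _init_value(model) + sum(
        _tree_expected_value(t, s) for t, s in _iter_trees(model)
    )


def ensemble_shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Attributions and base value for a fitted GradientBoostingRegressor.

    Returns ``(phi, base)`` with ``phi`` of shape (n_samples, n_features);
    ``base + phi.sum(axis=1)`` equals ``model.predict(X)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    phi = np.zeros((X.shape[0], X.shape[1]), dtype=np.float64)
    for tree, scale in _iter_trees(model):
        phi += tree_shap_values(tree, X, scale)
    return phi, ensemble_expected_value(model)
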