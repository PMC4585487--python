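"""Compiled inner loops for the searchlight pattern classification.

The searchlight evaluates on the order of 10^5-10^6 tiny binary classification
problems (a few dozen trials by a few dozen voxels each), a regime where
generic estimator machinery is dominated by per-call overhead.  The binary
linear max-margin classifier is therefore implemented directly as the standard
dual coordinate-descent algorithm for the L1-loss SVM dual (the liblinear
algorithm), and the k-nearest-neighbour alternative as an explicit distance
scan; both are cross-checked against reference library implementations in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dcd_svm(X, y, C, tol, max_epochs):
    """Linear SVM via dual coordinate descent (hinge loss, L2 penalty).

    ``X`` should carry a trailing all-ones column so the bias is learnt as a
    (regularised) weight, ``y`` is +/-1.  Returns the primal weight vector.
    Deterministic: coordinates are swept cyclically until the largest
    projected gradient falls below ``tol``.
    """
    n, d = X.shape
    w = np.zeros(d)
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s if s > 0.0 else 1.0
    for _ in range(max_epochs):
        max_pg = 0.0
        for i in range(n):
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            grad = y[i] * g - 1.0
            if alpha[i] <= 0.0:
                pg = grad if grad < 0.0 else 0.0
            elif alpha[i] >= C:
                pg = grad if grad > 0.0 else 0.0
            else:
                pg = grad
            apg = abs(pg)
            if apg > max_pg:
                max_pg = apg
            if apg > 1e-12:
                a_new = alpha[i] - grad / qii[i]
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > C:
                    a_new = C
                delta = (a_new - alpha[i]) * y[i]
                if delta != 0.0:
                    for j in range(d):
                        w[j] += delta * X[i, j]
                alpha[i] = a_new
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def _knn_margin(Xtr, ytr, x, k):
    """Signed k-NN vote for one test pattern; positive favours label +1."""
    n = Xtr.shape[0]
    d = Xtr.shape[1]
    dist = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            diff = Xtr[i, j] - x[j]
            s += diff * diff
        dist[i] = s
    used = np.zeros(n, np.bool_)
    vote = 0.0
    kk = k if k < n else n
    for _ in range(kk):
        best = -1
        bd = np.inf
        for i in range(n):
            if not used[i] and dist[i] < bd:
                bd = dist[i]
                best = i
        used[best] = True
        vote += ytr[best]
    return vote / kk


@njit(cache=True)
def _center_accuracy(X, y, fold_id, n_folds, n_classes, C, tol, max_epochs, knn_k):
    """Cross-validated pairwise-binary majority-vote accuracy for one
    searchlight center.

    ``X``: (n_trials, d) patterns (bias column included), ``y``: int labels
    0..n_classes-1, ``fold_id``: test-fold assignment per trial.  ``knn_k``
    <= 0 selects the linear max-margin classifier, > 0 the k-NN alternative.
    Ties in the vote are broken by the summed signed margins, then by the
    lowest class index.
    """
    n, d = X.shape
    votes = np.zeros((n, n_classes))
    marg = np.zeros((n, n_classes))
    for f in range(n_folds):
        for a in range(n_classes - 1):
            for b in range(a + 1, n_classes):
                cnt = 0
                for t in range(n):
                    if fold_id[t] != f and (y[t] == a or y[t] == b):
                        cnt += 1
                Xp = np.empty((cnt, d))
                yp = np.empty(cnt)
                m = 0
                for t in range(n):
                    if fold_id[t] != f and (y[t] == a or y[t] == b):
                        for j in range(d):
                            Xp[m, j] = X[t, j]
                        yp[m] = 1.0 if y[t] == b else -1.0
                        m += 1
                if knn_k <= 0:
                    w = _dcd_svm(Xp, yp, C, tol, max_epochs)
                for t in range(n):
                    if fold_id[t] != f:
                        continue
                    if knn_k <= 0:
                        s = 0.0
                        for j in range(d):
                            s += w[j] * X[t, j]
                    else:
                        s = _knn_margin(Xp, yp, X[t], knn_k)
                    if s >= 0.0:
                        votes[t, b] += 1.0
                    else:
                        votes[t, a] += 1.0
                    marg[t, b] += s
                    marg[t, a] -= s
    correct = 0
    for t in range(n):
        best = 0
        for c in range(1, n_classes):
            if votes[t, c] > votes[t, best] or (
                    votes[t, c] == votes[t, best] and marg[t, c] > marg[t, best]):
                best = c
        if best == y[t]:
            correct += 1
    return correct / n
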