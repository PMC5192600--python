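"""Independent reference implementations used only to check the package.

These are deliberately written in the most transparent style available —
projection-deflation PLS for the SIMPLS solver, exhaustive pairwise
enumeration for AUROC, brute-force step summation for AUPR — and share no
code with the implementations they verify.
"""

import numpy as np


def nipals_pls1_cov2(X, y, n_components):
    """Per-component squared covariance from projection-deflation PLS.

    Classic PLS1: at each step take the covariance direction of the
    *deflated* design, then deflate the design by the extracted score.
    The composite directions (mapping the original design to the scores)
    are recovered via R = W (P' W)^{-1} and normalized to unit length so
    that cov^2(X r_i, y) is comparable with a SIMPLS fit constrained to
    unit-norm directions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Xd = X.copy()
    n = X.shape[0]
    W, P = [], []
    for _ in range(n_components):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-24:
            break
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        W.append(w)
        P.append(p_load)
    if not W:
        return np.empty(0)
    W = np.column_stack(W)
    P = np.column_stack(P)
    R = W @ np.linalg.inv(P.T @ W)
    out = []
    for i in range(R.shape[1]):
        r = R[:, i] / np.linalg.norm(R[:, i])
        t = X @ r
        out.append((t @ y / (n - 1)) ** 2)
    return np.asarray(out)


def simpls_cov2(model, X, y):
    """cov^2(X v_i, y) for each fitted direction, same convention as above."""
    n = np.asarray(X).shape[0]
    return np.asarray(
        [
            ((np.asarray(X) @ model.directions[:, i]) @ np.asarray(y) / (n - 1)) ** 2
            for i in range(model.n_components)
        ]
    )


def auroc_exhaustive(scores, labels):
    """Concordant positive-negative pair fraction, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_stepwise(scores, labels):
    """Brute-force step-wise AUPR, tied scores processed as one block."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    tp = fp = 0
    for s in sorted(set(scores), reverse=True):
        block = scores == s
        tp += int((labels & block).sum())
        fp += int((~labels & block).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
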