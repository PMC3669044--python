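"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: the SVM oracle
enumerates candidate support sets and verifies the KKT conditions directly;
the PR oracle enumerates every threshold and counts from the definitions.
"""

import itertools

import numpy as np


def oracle_svm(K_aug: np.ndarray, y: np.ndarray):
    """Exhaustively find the dual optimum of the hard-margin kernel SVM.

    For every subset S of points, solve the linear system forcing
    y_i f(x_i) = 1 on S and Σ α y = 0, and accept the first solution that
    satisfies all KKT conditions (α ≥ 0 and margins ≥ 1 everywhere).  The
    strictly convex dual has a unique optimum, so the accepted subset is it.
    """
    n = len(y)
    Q = K_aug * np.outer(y, y)
    for r in range(1, n + 1):
        for S in itertools.combinations(range(n), r):
            S = list(S)
            ys = y[S]
            if not ((ys > 0).any() and (ys < 0).any()):
                continue
            k = len(S)
            A = np.zeros((k + 1, k + 1))
            A[:k, :k] = Q[np.ix_(S, S)]
            A[:k, k] = ys
            A[k, :k] = ys
            rhs = np.zeros(k + 1)
            rhs[:k] = 1.0
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            a_s, b = sol[:k], float(sol[k])
            if a_s.min() < -1e-9:
                continue
            alpha = np.zeros(n)
            alpha[S] = np.clip(a_s, 0.0, None)
            margins = Q @ alpha + y * b
            if margins.min() >= 1.0 - 1e-9:
                return alpha, b
    raise RuntimeError("no KKT point found by enumeration")


def oracle_pr(probs, labels):
    """(threshold, precision, recall) at every distinct probability value."""
    probs = list(map(float, probs))
    pos = [l > 0 for l in labels]
    n_pos = sum(pos)
    points = []
    for t in sorted(set(probs), reverse=True):
        pred = [p >= t for p in probs]
        tp = sum(1 for pr, la in zip(pred, pos) if pr and la)
        pp = sum(pred)
        points.append((t, tp / pp, tp / n_pos))
    return points


def oracle_precision_at_recall(probs, labels, r):
    """Max precision over thresholds whose recall reaches r, by enumeration."""
    return max(p for _, p, rec in oracle_pr(probs, labels) if rec >= r)


def oracle_gene_precision(p_gene, probs, labels):
    """Max precision over thresholds ≤ p_gene, by enumeration (0 if none)."""
    vals = [p for t, p, _ in oracle_pr(probs, labels) if t <= p_gene]
    return max(vals) if vals else 0.0
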