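"""Independent brute-force oracles used to verify the fast implementations.

These deliberately use explicit Python loops and scalar formulas so they share
no code path with the vectorised library routines they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_perturb(A_R: np.ndarray, dA: np.ndarray) -> np.ndarray:
    """First-order perturbed reconstruction by explicit rank-1 summation.

    Scalar route: eigendecompose A_R, cluster equal eigenvalues by scanning
    the sorted spectrum, diagonalise dA inside each degenerate cluster, then
    sum (lambda_k + shift_k) * y_k y_k^T term by term.
    """
    A_R = np.asarray(A_R, dtype=float)
    dA = np.asarray(dA, dtype=float)
    lam, X = np.linalg.eigh(A_R)
    n = len(lam)
    tol = 1e-8 * max(abs(float(v)) for v in lam) if n else 0.0

    # scan for clusters of (near-)equal eigenvalues
    clusters: list[list[int]] = []
    for k in range(n):
        if clusters and lam[k] - lam[clusters[-1][-1]] <= tol:
            clusters[-1].append(k)
        else:
            clusters.append([k])

    out = np.zeros_like(A_R)
    for cluster in clusters:
        if len(cluster) == 1:
            k = cluster[0]
            x = X[:, k]
            shift = float(x @ dA @ x) / float(x @ x)
            out += (lam[k] + shift) * np.outer(x, x)
        else:
            Xg = X[:, cluster]
            W = Xg.T @ dA @ Xg
            w, U = np.linalg.eigh((W + W.T) / 2.0)
            for m, k in enumerate(cluster):
                y = Xg @ U[:, m]
                out += (lam[k] + w[m]) * np.outer(y, y)
    return out


def naive_perturb(A_R: np.ndarray, dA: np.ndarray) -> np.ndarray:
    """Per-vector first-order formula, no degeneracy handling (scalar loops)."""
    lam, X = np.linalg.eigh(np.asarray(A_R, dtype=float))
    out = np.zeros_like(np.asarray(A_R, dtype=float))
    for k in range(len(lam)):
        x = X[:, k]
        shift = float(x @ dA @ x) / float(x @ x)
        out += (lam[k] + shift) * np.outer(x, x)
    return out


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting; ties earn 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def pearson_scalar(x, y) -> float:
    """Textbook Pearson correlation from scalar accumulations."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5
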