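"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: the aligner oracle is a
plain-Python Gotoh dynamic program, and the PCA oracle goes through the
eigendecomposition of the covariance matrix rather than the SVD.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def gotoh_local_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal affine-gap local alignment score by exhaustive DP.

    A gap of length L scores gap_open + (L-1) * gap_extend.  Score 0 means
    no positive-scoring local alignment exists.
    """
    n, m = len(a), len(b)
    H_prev = [0.0] * (m + 1)
    F_prev = [NEG_INF] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        H = [0.0] * (m + 1)
        F = [NEG_INF] * (m + 1)
        E = NEG_INF
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(H[j - 1] + gap_open, E + gap_extend)
            F[j] = max(H_prev[j] + gap_open, F_prev[j] + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            h = max(0.0, H_prev[j - 1] + s, E, F[j])
            H[j] = h
            if h > best:
                best = h
        H_prev, F_prev = H, F
    return best


def pca_by_eigh(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component coordinates and variance fractions via eigh.

    Returns (coordinates, explained_variance_fraction), components ordered
    by decreasing eigenvalue.  Signs are arbitrary (eigenvector signs are
    not fixed), so comparisons must be up to sign.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    coords = Xc @ V
    total = w.sum()
    frac = w / total if total > 0 else np.zeros_like(w)
    return coords, frac
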