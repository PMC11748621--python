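"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain nested loops / direct formula
evaluation, independent of the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def pad_same_1d(n: int, k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


def conv2d_collapse_loops(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (N,C,H,W), w (F,C,k,k): same padding, stride 1, nested loops."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    pb, pa = pad_same_1d(h, k)
    xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
    out = np.zeros((n, f, h, wd))
    for ni in range(n):
        for fi in range(f):
            for i in range(h):
                for j in range(wd):
                    acc = 0.0
                    for ci in range(c):
                        for a in range(k):
                            for bb in range(k):
                                acc += w[fi, ci, a, bb] * xp[ni, ci, i + a, j + bb]
                    out[ni, fi, i, j] = acc + b[fi]
    return out


def dsc_type1_loops(x, ws, bs, wz, bz):
    """x (N,M,H,W,D), ws (M,ks,ks), wz (F,kz); same padding, pre-ReLU."""
    n, m, h, w, d = x.shape
    _, ks, _ = ws.shape
    f, kz = wz.shape
    pb, pa = pad_same_1d(h, ks)
    xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa), (0, 0)))
    inter = np.zeros((n, h, w, d))
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                for di in range(d):
                    acc = 0.0
                    for mi in range(m):
                        for a in range(ks):
                            for bb in range(ks):
                                acc += ws[mi, a, bb] * xp[ni, mi, i + a, j + bb, di]
                    inter[ni, i, j, di] = acc + bs
    zb, za = pad_same_1d(d, kz)
    zp = np.pad(inter, ((0, 0), (0, 0), (0, 0), (zb, za)))
    out = np.zeros((n, f, h, w, d))
    for ni in range(n):
        for fi in range(f):
            for i in range(h):
                for j in range(w):
                    for di in range(d):
                        acc = 0.0
                        for e in range(kz):
                            acc += wz[fi, e] * zp[ni, i, j, di + e]
                        out[ni, fi, i, j, di] = acc + bz[fi]
    return out


def dsc_type2_loops(x, ws, bs, wz, bz):
    """x (N,M,H,W,D), ws (S,M,ks,ks), wz (S,T,kz); output sublayer-major."""
    n, m, h, w, d = x.shape
    s, _, ks, _ = ws.shape
    _, t, kz = wz.shape
    out = np.zeros((n, s * t, h, w, d))
    for si in range(s):
        sub = dsc_type1_loops(
            x, ws[si], bs[si], wz[si], bz[si]
        )  # reuse: T spectral kernels on sublayer si
        out[:, si * t : (si + 1) * t] = sub
    return out


def pbm_bruteforce(points, labels, centroids) -> float:
    """Direct evaluation of PBM = ((1/K)·(E1/EK)·DK)²."""
    points = np.asarray(points, float)
    centroids = np.atleast_2d(np.asarray(centroids, float))
    K = centroids.shape[0]
    if K == 1:
        return 0.0
    g = points.mean(axis=0)
    e1 = sum(np.sqrt(((p - g) ** 2).sum()) for p in points)
    ek = sum(np.sqrt(((p - centroids[l]) ** 2).sum()) for p, l in zip(points, labels))
    dk = max(
        np.sqrt(((centroids[i] - centroids[j]) ** 2).sum())
        for i in range(K)
        for j in range(K)
    )
    if ek == 0:
        return float("inf")
    return ((1.0 / K) * (e1 / ek) * dk) ** 2


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of positive-negative pairs ranked correctly."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def lstsq_normal_equations(design, y):
    """Coefficients via explicit normal equations (independent of pinv path)."""
    A = np.asarray(design, float)
    return np.linalg.solve(A.T @ A, A.T @ y)
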