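"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive and separate from the production
code paths: a brute-force O(n^2 m) matrix profile built on the element-wise
z-normalised distance formula, a full-table pure-Python DTW, and an
exhaustive warping-path enumerator for tiny inputs.
"""

from __future__ import annotations

import numpy as np
import pytest


def znorm_distance_oracle(a, b):
    """Element-wise z-normalisation formula, mirroring the documented
    zero-variance convention (both constant -> 0, one constant -> sqrt(m))."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m = a.size
    sa, sb = a.std(), b.std()
    ca = sa <= 1e-12 * max(1.0, abs(a.mean()))
    cb = sb <= 1e-12 * max(1.0, abs(b.mean()))
    if ca and cb:
        return 0.0
    if ca or cb:
        return float(np.sqrt(m))
    za = (a - a.mean()) / sa
    zb = (b - b.mean()) / sb
    return float(np.sqrt(np.sum((za - zb) ** 2)))


def brute_force_mp(x, m, excl):
    """O(n^2 m) double loop over all window pairs."""
    x = np.asarray(x, float)
    nw = x.size - m + 1
    values = np.empty(nw)
    indices = np.empty(nw, dtype=int)
    for i in range(nw):
        best, arg = np.inf, -1
        for j in range(nw):
            if abs(i - j) <= excl:
                continue
            d = znorm_distance_oracle(x[i : i + m], x[j : j + m])
            if d < best:
                best, arg = d, j
        values[i] = best
        indices[i] = arg
    return values, indices


def brute_force_mp_vectorised(x, m, excl):
    """All-pairs z-normalised distances via explicit window z-normalisation.

    Independent of the production sliding-dot-product recursion: every window
    is z-normalised explicitly and all pairwise Euclidean distances are
    formed directly.  Assumes no constant windows (true for the continuous
    random inputs it is used on).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    x = np.asarray(x, float)
    W = sliding_window_view(x, m)
    Z = (W - W.mean(axis=1, keepdims=True)) / W.std(axis=1, keepdims=True)
    sq = np.sum(Z**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    D = np.sqrt(np.clip(D2, 0.0, None))
    nw = D.shape[0]
    for i in range(nw):
        D[i, max(0, i - excl) : i + excl + 1] = np.inf
    return D.min(axis=1), D.argmin(axis=1)


def dtw_cost_oracle(a, b):
    """Full-table pure-Python DP, no banding, no path."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = a.size, b.size
    D = np.full((n, m), np.inf)
    D[0, 0] = abs(a[0] - b[0])
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            prev = min(
                D[i - 1, j - 1] if i > 0 and j > 0 else np.inf,
                D[i - 1, j] if i > 0 else np.inf,
                D[i, j - 1] if j > 0 else np.inf,
            )
            D[i, j] = prev + abs(a[i] - b[j])
    return float(D[-1, -1])


def enumerate_paths(n, m):
    """Every monotone warping path from (0,0) to (n-1,m-1); tiny inputs only."""
    paths = []

    def walk(i, j, acc):
        if i == n - 1 and j == m - 1:
            paths.append(list(acc))
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                acc.append((ni, nj))
                walk(ni, nj, acc)
                acc.pop()

    walk(0, 0, [(0, 0)])
    return paths


def min_cost_by_enumeration(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return min(
        sum(abs(a[i] - b[j]) for i, j in path)
        for path in enumerate_paths(a.size, b.size)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230615)
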