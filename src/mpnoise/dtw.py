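"""Dynamic time warping between matrix profiles, and the normalised dissimilarity.

Two profiles computed before and after additive corruption have different
lengths, so they are aligned with dynamic time warping before being compared.
The local cost is the absolute difference between matched values; steps are
the classic {(1,0), (0,1), (1,1)}.  Two engines share one banded DP kernel:

* ``dtw_exact`` — the full DP table (the band spans every column);
* ``fastdtw`` — the multilevel approximation of Salvador & Chan: coarsen by
  averaging adjacent pairs, solve recursively, project the coarse path up one
  resolution, widen the band by ``radius`` cells, and run the banded DP.
  With ``radius >= max(len(a), len(b))`` it degenerates to the exact DP.

The study's headline metric divides the summed absolute matched differences
by the *original* series length ``N`` and the maximum of the *original*
profile, ``y1`` — deliberately asymmetric in its two arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .matrix_profile import MatrixProfile

__all__ = [
    "DTWParams",
    "WarpingPath",
    "DissimilarityResult",
    "dtw_exact",
    "fastdtw",
    "mp_dissimilarity",
    "normalised_dissimilarity",
]


@dataclass(frozen=True)
class DTWParams:
    """FastDTW refinement half-width and engine selection."""

    radius: int = 30
    mode: str = "fast"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.mode not in ("fast", "exact"):
            raise ValueError(f"mode must be 'fast' or 'exact', got {self.mode!r}")


@dataclass
class WarpingPath:
    """Monotone sequence of matched (i, j) pairs from (0,0) to (|A|-1, |B|-1)."""

    pairs: np.ndarray  # shape (L, 2)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.pairs.shape[0])


@dataclass
class DissimilarityResult:
    """DTW summary between an original and a corrupted matrix profile.

    ``sum_abs_diffs`` is the path cost (sum of |a_i - b_j| over matched
    pairs); ``normalised = sum_abs_diffs / (x1 * y1)`` where ``x1`` is the
    original series length and ``y1`` the original profile's maximum.
    """

    sum_abs_diffs: float
    normalised: float
    x1: int
    x2: int
    y1: float
    y2: float
    path_length: int

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)

    def write_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# DP step codes: 0 = diagonal, 1 = up (advance a), 2 = left (advance b), 3 = origin.
@njit(cache=True)
def _banded_dp(a, b, lo, hi):  # pragma: no cover - exercised via wrappers
    n = a.shape[0]
    maxw = 0
    for i in range(n):
        w = hi[i] - lo[i] + 1
        if w > maxw:
            maxw = w
    D = np.full((n, maxw), np.inf)
    S = np.zeros((n, maxw), dtype=np.uint8)
    for i in range(n):
        l = lo[i]
        h = hi[i]
        for j in range(l, h + 1):
            c = abs(a[i] - b[j])
            if i == 0 and j == 0:
                D[0, 0] = c
                S[0, 0] = 3
                continue
            best = np.inf
            bs = np.uint8(0)
            if i > 0 and j > 0 and lo[i - 1] <= j - 1 <= hi[i - 1]:
                v = D[i - 1, j - 1 - lo[i - 1]]
                if v < best:
                    best = v
                    bs = np.uint8(0)
            if i > 0 and lo[i - 1] <= j <= hi[i - 1]:
                v = D[i - 1, j - lo[i - 1]]
                if v < best:
                    best = v
                    bs = np.uint8(1)
            if j - 1 >= l:
                v = D[i, j - 1 - l]
                if v < best:
                    best = v
                    bs = np.uint8(2)
            if best < np.inf:
                D[i, j - l] = best + c
                S[i, j - l] = bs
    return D, S


def _backtrack(S, lo, nb):
    n = S.shape[0]
    i, j = n - 1, nb - 1
    rev = []
    while True:
        rev.append((i, j))
        s = S[i, j - lo[i]]
        if s == 3:
            break
        if s == 0:
            i, j = i - 1, j - 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
    rev.reverse()
    return np.array(rev, dtype=np.int64)


def _run_banded(a, b, lo, hi):
    D, S = _banded_dp(a, b, lo, hi)
    cost = float(D[-1, (b.size - 1) - lo[-1]])
    if not np.isfinite(cost):
        raise RuntimeError("DTW band disconnected; this is a bug")
    path = WarpingPath(_backtrack(S, lo, b.size))
    return path, cost


def _as_array(x, name):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence")
    return x


def dtw_exact(a, b):
    """Globally optimal warping path and cost under |a_i - b_j| local cost.

    Ties between predecessor cells prefer the diagonal step, so paths are
    deterministic.
    """
    a = _as_array(a, "a")
    b = _as_array(b, "b")
    lo = np.zeros(a.size, dtype=np.int64)
    hi = np.full(a.size, b.size - 1, dtype=np.int64)
    return _run_banded(a, b, lo, hi)


def _coarsen(x):
    # mean of adjacent pairs; an odd tail element is carried down unchanged
    if x.size % 2 == 0:
        return 0.5 * (x[0::2] + x[1::2])
    return np.concatenate((0.5 * (x[0:-1:2] + x[1::2]), x[-1:]))


def _expand_window(path, na, nb, radius):
    """Project a coarse path to the fine grid and widen it by ``radius`` cells."""
    lo = np.full(na, nb, dtype=np.int64)
    hi = np.full(na, -1, dtype=np.int64)
    for ic, jc in path:
        j0, j1 = 2 * jc, min(2 * jc + 1, nb - 1)
        for if_ in (2 * ic, 2 * ic + 1):
            if if_ < na:
                if j0 < lo[if_]:
                    lo[if_] = j0
                if j1 > hi[if_]:
                    hi[if_] = j1
    # rows whose coarse parent was only reached via the shorter partner
    for i in range(na):
        if hi[i] < 0:
            lo[i], hi[i] = lo[i - 1], hi[i - 1]
    lo = np.maximum(lo - radius, 0)
    hi = np.minimum(hi + radius, nb - 1)
    # keep the band connected and monotone after clipping
    np.maximum.accumulate(hi, out=hi)
    lo = np.minimum.accumulate(lo[::-1])[::-1].copy()
    lo[0] = 0
    hi[-1] = nb - 1
    return lo, hi


def fastdtw(a, b, params: DTWParams = DTWParams()):
    """Multilevel approximate DTW (Salvador & Chan) with refinement ``radius``.

    Cost is never below the exact DTW cost and equals it whenever the radius
    reaches the longer input's length.
    """
    a = _as_array(a, "a")
    b = _as_array(b, "b")
    return _fastdtw_rec(a, b, int(params.radius))


def _fastdtw_rec(a, b, radius):
    if a.size <= radius + 2 or b.size <= radius + 2:
        return dtw_exact(a, b)
    path, _ = _fastdtw_rec(_coarsen(a), _coarsen(b), radius)
    lo, hi = _expand_window(path.pairs, a.size, b.size, radius)
    return _run_banded(a, b, lo, hi)


def normalised_dissimilarity(sum_abs_diffs: float, n_original: int, y1: float) -> float:
    """Normalise a summed absolute MP difference by ``N * y1``."""
    if y1 <= 0:
        raise ValueError("original profile maximum y1 must be positive")
    if n_original < 1:
        raise ValueError("original series length must be >= 1")
    return float(sum_abs_diffs) / (n_original * y1)


def mp_dissimilarity(
    mp_original: MatrixProfile,
    mp_corrupted: MatrixProfile,
    params: DTWParams = DTWParams(),
) -> DissimilarityResult:
    """Align two matrix profiles and report the normalised dissimilarity.

    Asymmetric by construction: the normaliser uses the original side only
    (series length ``x1 = N`` and profile maximum ``y1``).  Identical
    profiles yield 0 for both the sum and the normalised value.
    """
    a = mp_original.values
    b = mp_corrupted.values
    if a.size == 0 or b.size == 0:
        raise ValueError("profiles must be non-empty")
    y1 = float(a.max())
    y2 = float(b.max())
    if y1 <= 0:
        raise ValueError("original profile maximum y1 must be positive to normalise")
    if params.mode == "exact":
        path, cost = dtw_exact(a, b)
    else:
        path, cost = fastdtw(a, b, params)
    x1 = mp_original.source_length
    return DissimilarityResult(
        sum_abs_diffs=cost,
        normalised=normalised_dissimilarity(cost, x1, y1),
        x1=x1,
        x2=mp_corrupted.source_length,
        y1=y1,
        y2=y2,
        path_length=len(path),
    )
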