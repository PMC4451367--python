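"""Pairwise template-matching kernels for correlation sums.

Distances are maximum-coordinate (Chebyshev); a pair at distance exactly
eps counts as a match (Heaviside step with H(0) = 1).  Two entry points:

``count_pairs_joint``
    Counts, for every eps in an ascending grid, the unordered template pairs
    within eps at embedding dimensions m and m+1 *over the same template
    set* (the first N - m*L delay vectors).  Sharing the template set
    guarantees the prefix property count_{m+1} <= count_m, hence K2 >= 0.

``count_pairs_single``
    Counts pairs at a single dimension m over its full vector set of
    N - (m-1)*L delay vectors, i.e. the plain correlation integral.

Both are compiled with numba when available and fall back to a chunked
numpy implementation that produces identical counts.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _bisect_ge(grid, value):
    """Index of the first grid entry >= value (== len(grid) if none)."""
    lo, hi = 0, grid.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if grid[mid] < value:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _joint_hist_nb(x, m, L, eps_grid, theiler):
    n_t = x.shape[0] - m * L
    g = eps_grid.shape[0]
    hist_m = np.zeros(g + 1, np.int64)
    hist_m1 = np.zeros(g + 1, np.int64)
    for i in range(n_t - 1):
        for j in range(i + 1 + theiler, n_t):
            dm = 0.0
            for k in range(m):
                d = abs(x[i + k * L] - x[j + k * L])
                if d > dm:
                    dm = d
            d = abs(x[i + m * L] - x[j + m * L])
            dm1 = dm if dm > d else d
            hist_m[_bisect_ge(eps_grid, dm)] += 1
            hist_m1[_bisect_ge(eps_grid, dm1)] += 1
    return hist_m, hist_m1


@njit(cache=True)
def _single_hist_nb(x, m, L, eps_grid, theiler):
    n_v = x.shape[0] - (m - 1) * L
    g = eps_grid.shape[0]
    hist = np.zeros(g + 1, np.int64)
    for i in range(n_v - 1):
        for j in range(i + 1 + theiler, n_v):
            dm = 0.0
            for k in range(m):
                d = abs(x[i + k * L] - x[j + k * L])
                if d > dm:
                    dm = d
            hist[_bisect_ge(eps_grid, dm)] += 1
    return hist


def _chebyshev_block(x, m, L, i0, i1, n_t):
    """Chebyshev distances from templates i0..i1-1 to all templates, dim m."""
    rows = i1 - i0
    d = np.zeros((rows, n_t))
    for k in range(m):
        seg = x[k * L : k * L + n_t]
        np.maximum(d, np.abs(seg[i0:i1, None] - seg[None, :]), out=d)
    return d


def _joint_hist_np(x, m, L, eps_grid, theiler, chunk=512):
    n_t = x.shape[0] - m * L
    g = eps_grid.shape[0]
    hist_m = np.zeros(g + 1, np.int64)
    hist_m1 = np.zeros(g + 1, np.int64)
    extra = x[m * L : m * L + n_t]
    for i0 in range(0, n_t - 1, chunk):
        i1 = min(i0 + chunk, n_t - 1)
        dm = _chebyshev_block(x, m, L, i0, i1, n_t)
        dm1 = np.maximum(dm, np.abs(extra[i0:i1, None] - extra[None, :]))
        cols = np.arange(n_t)[None, :]
        rows = np.arange(i0, i1)[:, None]
        mask = cols > rows + theiler
        bm = np.searchsorted(eps_grid, dm[mask], side="left")
        bm1 = np.searchsorted(eps_grid, dm1[mask], side="left")
        hist_m += np.bincount(bm, minlength=g + 1)
        hist_m1 += np.bincount(bm1, minlength=g + 1)
    return hist_m, hist_m1


def _single_hist_np(x, m, L, eps_grid, theiler, chunk=512):
    n_v = x.shape[0] - (m - 1) * L
    g = eps_grid.shape[0]
    hist = np.zeros(g + 1, np.int64)
    for i0 in range(0, n_v - 1, chunk):
        i1 = min(i0 + chunk, n_v - 1)
        d = _chebyshev_block(x, m, L, i0, i1, n_v)
        cols = np.arange(n_v)[None, :]
        rows = np.arange(i0, i1)[:, None]
        mask = cols > rows + theiler
        b = np.searchsorted(eps_grid, d[mask], side="left")
        hist += np.bincount(b, minlength=g + 1)
    return hist


def count_pairs_joint(x, m, L, eps_grid, theiler=0):
    """Cumulative pair counts within each eps, dims m and m+1, shared templates.

    Returns ``(counts_m, counts_m1)``, each of length ``len(eps_grid)``:
    entry k is the number of unordered template pairs (j > i + theiler)
    whose Chebyshev distance is <= eps_grid[k].
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    eps_grid = np.ascontiguousarray(eps_grid, dtype=np.float64)
    if x.shape[0] - m * L < 2:
        raise ValueError(
            f"series of length {x.shape[0]} too short for m={m}, L={L} "
            f"(need at least {m * L + 2} samples)"
        )
    if np.any(np.diff(eps_grid) <= 0):
        raise ValueError("eps_grid must be strictly ascending")
    fn = _joint_hist_nb if HAVE_NUMBA else _joint_hist_np
    hist_m, hist_m1 = fn(x, m, L, eps_grid, theiler)
    return np.cumsum(hist_m)[:-1], np.cumsum(hist_m1)[:-1]


def count_pairs_single(x, m, L, eps_grid, theiler=0):
    """Cumulative pair counts within each eps at dimension m (full vector set)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    eps_grid = np.ascontiguousarray(eps_grid, dtype=np.float64)
    if x.shape[0] - (m - 1) * L < 2:
        raise ValueError(
            f"series of length {x.shape[0]} too short for m={m}, L={L}"
        )
    if np.any(np.diff(eps_grid) <= 0):
        raise ValueError("eps_grid must be strictly ascending")
    fn = _single_hist_nb if HAVE_NUMBA else _single_hist_np
    hist = fn(x, m, L, eps_grid, theiler)
    return np.cumsum(hist)[:-1]
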