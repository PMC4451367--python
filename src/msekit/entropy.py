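"""Delay embedding, correlation integrals, K2 / sample entropy, MSE surfaces.

The correlation entropy K2 at finite scale eps is estimated from
correlation integrals of delay-embedded vectors:

    K2(eps) = [ln C^(m)(eps) - ln C^(m+1)(eps)] / (L * dt)

where C^(m)(eps) is the fraction of unordered pairs of m-dimensional delay
vectors within Chebyshev distance eps.  Evaluated at a fixed eps this is
the sample entropy (self-matches excluded).  Multiscale entropy (MSE)
computes the same quantity on block-averaged copies of the signal; here
the scale eps is held fixed in ORIGINAL-data units across block sizes, so
that for fGn the surface obeys the bi-scaling law

    K2^(bs)(eps) ~ (H - 1) ln bs - ln eps.

Both correlation sums in K2 are taken over the same template set (the
first N - m*L vectors), which guarantees C^(m+1) <= C^(m) and hence
K2 >= 0 wherever defined.  An estimate is flagged undefined (NaN) when
either correlation sum has fewer than ``min_pairs`` matching pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import count_pairs_joint, count_pairs_single
from .coarsegrain import coarse_grain
from .signals import TimeSeries

__all__ = [
    "EmbeddingConfig",
    "EntropyCurve",
    "MSESurface",
    "embed",
    "correlation_integral",
    "k2_at_scale",
    "k2_curve",
    "mse_surface",
]

#: pair-count threshold below which a K2 estimate is declared undefined
DEFAULT_MIN_PAIRS = 10


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding parameters: dimension m, delay L, Theiler window."""

    m: int = 2
    L: int = 1
    theiler: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if self.theiler < 0:
            raise ValueError(f"theiler must be >= 0, got {self.theiler}")


@dataclass(frozen=True)
class EntropyCurve:
    """K2 over an ascending eps grid at fixed (m, L, block_size).

    ``eps`` is in the units given by ``eps_units`` ("sd" = fraction of the
    reference standard deviation ``sd_ref``; "absolute" = data units);
    ``eps_abs`` always holds the absolute values used for matching.  ``k2``
    is NaN wherever either pair count fell below ``min_pairs``.
    """

    eps: np.ndarray
    eps_abs: np.ndarray
    k2: np.ndarray
    pair_counts_m: np.ndarray
    pair_counts_m1: np.ndarray
    m: int
    L: int
    block_size: int = 1
    eps_units: str = "sd"
    sd_ref: float = 1.0
    min_pairs: int = DEFAULT_MIN_PAIRS

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.k2)


@dataclass(frozen=True)
class MSESurface:
    """K2^(bs)(eps) over a (block_size, eps) grid for one signal.

    Row 0 (bs = block_sizes[0]) of ``k2`` corresponds to the smallest block
    size; when that is 1 it equals the entropy curve of the raw series.
    eps is fixed in original-data units for every row.
    """

    block_sizes: np.ndarray
    eps: np.ndarray
    eps_abs: np.ndarray
    k2: np.ndarray                       # shape (n_blocks, n_eps)
    pair_counts_m: np.ndarray
    pair_counts_m1: np.ndarray
    config: EmbeddingConfig
    eps_units: str = "sd"
    sd_ref: float = 1.0
    min_pairs: int = DEFAULT_MIN_PAIRS

    def row(self, block_size: int) -> EntropyCurve:
        """The entropy curve at one block size."""
        idx = np.flatnonzero(self.block_sizes == block_size)
        if idx.size == 0:
            raise KeyError(f"block size {block_size} not in surface")
        i = int(idx[0])
        return EntropyCurve(
            eps=self.eps,
            eps_abs=self.eps_abs,
            k2=self.k2[i],
            pair_counts_m=self.pair_counts_m[i],
            pair_counts_m1=self.pair_counts_m1[i],
            m=self.config.m,
            L=self.config.L,
            block_size=block_size,
            eps_units=self.eps_units,
            sd_ref=self.sd_ref,
            min_pairs=self.min_pairs,
        )


def embed(x: TimeSeries, cfg: EmbeddingConfig) -> np.ndarray:
    """Delay-embedded vectors V_i = [x_i, x_{i+L}, ..., x_{i+(m-1)L}].

    Returns an array of shape (N - (m-1)L, m).
    """
    n_v = len(x) - (cfg.m - 1) * cfg.L
    if n_v < 2:
        raise ValueError(
            f"length {len(x)} too short to embed with m={cfg.m}, L={cfg.L}"
        )
    v = np.empty((n_v, cfg.m))
    for k in range(cfg.m):
        v[:, k] = x.values[k * cfg.L : k * cfg.L + n_v]
    return v


def correlation_integral(x: TimeSeries, cfg: EmbeddingConfig, eps: float) -> float:
    """Fraction of unordered distinct vector pairs within Chebyshev distance eps.

    Pairs at distance exactly eps count as matches; self-pairs are excluded.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    n_v = len(x) - (cfg.m - 1) * cfg.L
    if n_v < 2:
        raise ValueError(f"length {len(x)} too short for m={cfg.m}, L={cfg.L}")
    count = count_pairs_single(
        x.values, cfg.m, cfg.L, np.array([eps]), theiler=cfg.theiler
    )[0]
    n_pairs = _n_pairs(n_v, cfg.theiler)
    return float(count) / n_pairs


def _n_pairs(n_templates: int, theiler: int) -> int:
    # pairs (i, j) with j > i + theiler: C(n - theiler, 2)
    k = max(n_templates - theiler, 0)
    return k * (k - 1) // 2


def k2_at_scale(
    x: TimeSeries,
    cfg: EmbeddingConfig,
    eps: float,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    dt: float = 1.0,
) -> float:
    """Sample entropy / K2 at a single absolute scale eps.

    Returns NaN when either correlation sum has fewer than ``min_pairs``
    matching pairs (the estimate is statistically unresolvable, not zero).
    """
    curve = k2_curve(
        x, np.array([eps]), cfg, min_pairs=min_pairs, eps_units="absolute", dt=dt
    )
    return float(curve.k2[0])


def k2_curve(
    x: TimeSeries,
    eps_grid: Sequence[float],
    cfg: EmbeddingConfig = EmbeddingConfig(),
    min_pairs: int = DEFAULT_MIN_PAIRS,
    eps_units: str = "sd",
    sd_ref: Optional[float] = None,
    block_size: int = 1,
    dt: float = 1.0,
) -> EntropyCurve:
    """K2 over an eps grid.

    Parameters
    ----------
    eps_grid : ascending positive scales.
    eps_units : "sd" interprets the grid as fractions of ``sd_ref`` (default:
        the standard deviation of ``x`` itself); "absolute" uses data units.
    dt : sampling time entering the K2 denominator ``L * dt`` (default 1,
        i.e. entropy per sample).
    """
    grid = np.asarray(eps_grid, dtype=np.float64)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("eps_grid must be a non-empty 1-D sequence")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("eps_grid must be positive and strictly ascending")
    if eps_units == "sd":
        ref = x.std() if sd_ref is None else float(sd_ref)
        if ref <= 0:
            raise ValueError("zero-variance series: sd-based eps undefined")
        eps_abs = grid * ref
    elif eps_units == "absolute":
        ref = 1.0 if sd_ref is None else float(sd_ref)
        eps_abs = grid
    else:
        raise ValueError(f"unknown eps_units {eps_units!r}")

    counts_m, counts_m1 = count_pairs_joint(
        x.values, cfg.m, cfg.L, eps_abs, theiler=cfg.theiler
    )
    k2 = np.full(grid.size, np.nan)
    ok = (counts_m >= min_pairs) & (counts_m1 >= min_pairs) & (counts_m1 > 0)
    k2[ok] = (np.log(counts_m[ok]) - np.log(counts_m1[ok])) / (cfg.L * dt)
    return EntropyCurve(
        eps=grid,
        eps_abs=eps_abs,
        k2=k2,
        pair_counts_m=counts_m,
        pair_counts_m1=counts_m1,
        m=cfg.m,
        L=cfg.L,
        block_size=block_size,
        eps_units=eps_units,
        sd_ref=ref,
        min_pairs=min_pairs,
    )


def mse_surface(
    x: TimeSeries,
    block_sizes: Sequence[int] = tuple(range(1, 21)),
    eps_grid: Sequence[float] = (0.2,),
    cfg: EmbeddingConfig = EmbeddingConfig(),
    min_pairs: int = DEFAULT_MIN_PAIRS,
    eps_units: str = "sd",
    dt: float = 1.0,
) -> MSESurface:
    """K2^(bs)(eps) for every block size on a shared eps grid.

    The grid is converted to absolute units ONCE, using the original
    series' standard deviation; it is *not* re-normalized per block size.
    This is what makes the (H - 1) ln bs term of the bi-scaling law
    observable: the smoothed variance shrinks while eps stays fixed.
    """
    bs = np.asarray(sorted(set(int(b) for b in block_sizes)))
    if bs.size == 0 or bs[0] < 1:
        raise ValueError("block_sizes must be positive integers")
    grid = np.asarray(eps_grid, dtype=np.float64)
    if eps_units == "sd":
        ref = x.std()
        if ref <= 0:
            raise ValueError("zero-variance series")
        eps_abs = grid * ref
    elif eps_units == "absolute":
        ref = 1.0
        eps_abs = grid
    else:
        raise ValueError(f"unknown eps_units {eps_units!r}")

    k2 = np.full((bs.size, grid.size), np.nan)
    cm = np.zeros((bs.size, grid.size), dtype=np.int64)
    cm1 = np.zeros_like(cm)
    for i, b in enumerate(bs):
        xi = x if b == 1 else TimeSeries(coarse_grain(x, int(b)).values)
        row = k2_curve(
            xi, eps_abs, cfg, min_pairs=min_pairs, eps_units="absolute",
            block_size=int(b), dt=dt,
        )
        k2[i] = row.k2
        cm[i] = row.pair_counts_m
        cm1[i] = row.pair_counts_m1
    return MSESurface(
        block_sizes=bs,
        eps=grid,
        eps_abs=eps_abs,
        k2=k2,
        pair_counts_m=cm,
        pair_counts_m1=cm1,
        config=cfg,
        eps_units=eps_units,
        sd_ref=ref,
        min_pairs=min_pairs,
    )
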