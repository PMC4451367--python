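"""Coarse-graining (block averaging) and the variance scaling law.

The multiscale step replaces a series x_1..x_N by means over non-overlapping
blocks of size b_s:

    x_t^(bs) = (x_{(t-1)bs + 1} + ... + x_{t bs}) / bs

Trailing samples that do not fill a block are dropped.  For fGn with Hurst
parameter H the variance of the smoothed series obeys

    var(X^(bs)) = sigma^2 * bs^(2H - 2)

so the least-squares slope of ln var against ln bs estimates 2H - 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .signals import TimeSeries

__all__ = ["CoarseGrained", "coarse_grain", "VarianceScaling", "variance_scaling_exponent"]


@dataclass(frozen=True)
class CoarseGrained:
    """Block-averaged series together with its provenance."""

    values: np.ndarray
    block_size: int
    parent_length: int

    def __len__(self) -> int:
        return self.values.size

    def to_series(self, dt: float = 1.0, label: str = "") -> TimeSeries:
        return TimeSeries(self.values, dt=dt * self.block_size, label=label)


def coarse_grain(x: TimeSeries, block_size: int) -> CoarseGrained:
    """Average ``x`` over non-overlapping blocks of ``block_size`` samples."""
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    n_blocks = len(x) // block_size
    if n_blocks < 2:
        raise ValueError(
            f"block_size {block_size} leaves {n_blocks} block(s) from "
            f"{len(x)} samples; need at least 2"
        )
    v = x.values[: n_blocks * block_size].reshape(n_blocks, block_size)
    return CoarseGrained(v.mean(axis=1), block_size=block_size, parent_length=len(x))


@dataclass(frozen=True)
class VarianceScaling:
    """OLS fit of ln var(X^(bs)) on ln bs.

    ``slope`` estimates 2H - 2; ``h_hat`` = 1 + slope/2.
    """

    slope: float
    h_hat: float
    stderr: float
    block_sizes: np.ndarray
    variances: np.ndarray


def variance_scaling_exponent(
    x: TimeSeries, block_sizes: Sequence[int] = tuple(range(1, 21))
) -> VarianceScaling:
    """Estimate the aggregated-variance scaling exponent of ``x``."""
    bs = np.asarray(sorted(set(int(b) for b in block_sizes)))
    if bs.size < 3:
        raise ValueError("need at least 3 distinct block sizes")
    variances = np.array(
        [np.var(coarse_grain(x, int(b)).values) for b in bs]
    )
    if np.any(variances <= 0.0):
        raise ValueError("zero-variance coarse-grained series (degenerate input)")
    fit = stats.linregress(np.log(bs), np.log(variances))
    return VarianceScaling(
        slope=float(fit.slope),
        h_hat=1.0 + float(fit.slope) / 2.0,
        stderr=float(fit.stderr),
        block_sizes=bs,
        variances=variances,
    )
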