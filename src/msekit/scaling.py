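"""Linear fits of the bi-scaling law and derived diagnostic features.

For fractal (1/f-type) noise the correlation entropy of coarse-grained data
follows

    K2^(bs)(eps) ~ (H - 1) ln bs - ln eps

so two ordinary least-squares fits carry all the information:

* K2 against ln eps at fixed bs -- slope expected near -1;
* K2^(bs) against ln bs at fixed eps -- slope H - 1, giving the Hurst
  estimator h_hat = 1 + slope.

Two further scalar features support signal discrimination: eps*, the
smallest scale on the grid at which the entropy estimate is statistically
resolvable (both correlation sums reach the pair-count threshold), and the
relative error of a short linear fit of K2 vs ln eps starting at eps* --
clean fractal scaling gives a small error, intermittent or noisy records a
large one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .entropy import EntropyCurve, MSESurface

__all__ = [
    "ScalingFit",
    "HurstEstimate",
    "fit_eps_scaling",
    "fit_bs_scaling",
    "epsilon_star",
    "fit_error_feature",
]


@dataclass(frozen=True)
class ScalingFit:
    """OLS line on a logarithmic scale axis.

    ``fit_error_pct`` is the RMS residual divided by the mean |K2| over the
    fitted window, times 100.
    """

    slope: float
    intercept: float
    fit_error_pct: float
    stderr: float
    x_range: Tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class HurstEstimate:
    """Hurst parameter from the block-size scaling of MSE: h_hat = 1 + slope."""

    h_hat: float
    slope: float
    intercept: float
    stderr: float
    eps_used: float
    bs_range: Tuple[int, int]
    n_points: int


def _ols(x: np.ndarray, y: np.ndarray):
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    denom = float(np.mean(np.abs(y)))
    err_pct = 100.0 * rms / denom if denom > 0 else 0.0 if rms == 0 else np.inf
    return fit, err_pct


def fit_eps_scaling(
    curve: EntropyCurve,
    eps_range: Optional[Tuple[float, float]] = None,
) -> ScalingFit:
    """OLS of K2 on ln eps over the defined points in ``eps_range``.

    ``eps_range`` bounds are in the curve's own eps units (inclusive);
    ``None`` uses every defined point.  For fractal noise the slope is
    expected near -1.
    """
    mask = curve.defined
    if eps_range is not None:
        lo, hi = eps_range
        mask = mask & (curve.eps >= lo) & (curve.eps <= hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"need >= 3 defined K2 points in range, got {int(mask.sum())}"
        )
    x = np.log(curve.eps_abs[mask])
    y = curve.k2[mask]
    fit, err_pct = _ols(x, y)
    return ScalingFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        fit_error_pct=err_pct,
        stderr=float(fit.stderr),
        x_range=(float(curve.eps[mask][0]), float(curve.eps[mask][-1])),
        n_points=int(mask.sum()),
    )


def fit_bs_scaling(
    surface: MSESurface,
    eps: float,
    bs_range: Tuple[int, int] = (1, 10),
) -> HurstEstimate:
    """OLS of K2^(bs)(eps) on ln bs; h_hat = 1 + slope.

    ``eps`` is matched to the nearest grid column of the surface (in the
    surface's eps units).  Block sizes outside ``bs_range`` or with an
    undefined K2 are excluded; at least 3 defined block sizes are required.
    """
    col = int(np.argmin(np.abs(surface.eps - eps)))
    if not np.isclose(surface.eps[col], eps, rtol=1e-6, atol=1e-12):
        warnings.warn(
            f"eps={eps} not on the surface grid; using nearest {surface.eps[col]}"
        )
    lo, hi = bs_range
    in_range = (surface.block_sizes >= lo) & (surface.block_sizes <= hi)
    k2 = surface.k2[:, col]
    ok = in_range & np.isfinite(k2)
    if int(ok.sum()) < 3:
        bad = surface.block_sizes[in_range & ~np.isfinite(k2)]
        raise ValueError(
            f"only {int(ok.sum())} defined K2 values in bs range {bs_range}; "
            f"block sizes failing the pair-count threshold: {list(bad)}"
        )
    x = np.log(surface.block_sizes[ok].astype(float))
    y = k2[ok]
    fit, _ = _ols(x, y)
    return HurstEstimate(
        h_hat=1.0 + float(fit.slope),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr=float(fit.stderr),
        eps_used=float(surface.eps[col]),
        bs_range=(int(surface.block_sizes[ok][0]), int(surface.block_sizes[ok][-1])),
        n_points=int(ok.sum()),
    )


def epsilon_star(curve: EntropyCurve) -> float:
    """Smallest grid eps at which K2 is defined (in the curve's eps units).

    Operationalizes "the smallest scale resolvable by the data": both
    correlation sums must reach the curve's pair-count threshold.
    """
    idx = np.flatnonzero(curve.defined)
    if idx.size == 0:
        raise ValueError("K2 undefined on the whole grid; no resolvable scale")
    return float(curve.eps[int(idx[0])])


def fit_error_feature(curve: EntropyCurve, n_points: int = 6) -> float:
    """Relative error (%) of a linear K2-vs-ln-eps fit over ``n_points``
    consecutive defined scales starting at eps*.
    """
    if n_points < 3:
        raise ValueError(f"n_points must be >= 3, got {n_points}")
    idx = np.flatnonzero(curve.defined)
    if idx.size < n_points:
        raise ValueError(
            f"only {idx.size} defined scales from eps*, need {n_points}"
        )
    sel = idx[:n_points]
    x = np.log(curve.eps_abs[sel])
    y = curve.k2[sel]
    _, err_pct = _ols(x, y)
    return err_pct
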