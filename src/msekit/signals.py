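"""Synthetic test signals with known scaling structure.

Fractional Gaussian noise (fGn) is the workhorse: a stationary Gaussian
process whose autocovariance

    r(k) = (sigma^2 / 2) * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})

is controlled by the Hurst parameter H in (0, 1).  H = 1/2 gives white
noise, H > 1/2 persistent (long-range correlated) noise, H < 1/2
anti-persistent noise.  Simulation is exact in distribution via circulant
embedding (Davies-Harte), so the correlation structure is correct at all
lags -- a requirement for testing scaling laws rather than an aesthetic
choice.

Also provided: Gaussian white noise, 1/f^alpha noise by random-phase
spectral synthesis (covers the alpha = 1, H = 1 boundary that fGn cannot
reach), the cumulative-sum "random walk" transform and its inverse, first
differencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "FgnSpec",
    "fgn_autocovariance",
    "simulate_fgn",
    "simulate_white_noise",
    "simulate_one_over_f",
    "difference",
    "random_walk",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued sequence.

    Parameters
    ----------
    values : array-like
        The samples.  Must be finite and contain at least 2 points.
    dt : float
        Sampling interval in seconds (default 1, i.e. "per sample").
    label : str
        Free-text provenance tag.
    seed : int, optional
        Seed used to generate the series, when applicable.
    """

    values: np.ndarray
    dt: float = 1.0
    label: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError(f"TimeSeries requires a 1-D sequence, got shape {v.shape}")
        if v.size < 2:
            raise ValueError(f"TimeSeries requires length >= 2, got {v.size}")
        if not np.all(np.isfinite(v)):
            bad = int(np.flatnonzero(~np.isfinite(v))[0])
            raise ValueError(f"non-finite value at index {bad}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    def std(self) -> float:
        """Sample standard deviation (population normalization)."""
        return float(np.std(self.values))


@dataclass(frozen=True)
class FgnSpec:
    """Specification of a fractional Gaussian noise simulation."""

    hurst: float
    n: int
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must lie strictly in (0, 1), got {self.hurst}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")


def fgn_autocovariance(hurst: float, sigma2: float, lags) -> np.ndarray:
    """Closed-form autocovariance of fGn at the requested lags."""
    k = np.abs(np.asarray(lags, dtype=np.float64))
    h2 = 2.0 * hurst
    return 0.5 * sigma2 * (
        np.abs(k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2
    )


def simulate_fgn(spec: FgnSpec) -> TimeSeries:
    """Simulate fractional Gaussian noise by circulant embedding.

    The autocovariance sequence r(0..n) is embedded in a circulant matrix of
    order 2n whose eigenvalues are obtained by FFT; for fGn these are
    non-negative for every H in (0, 1), so the method is exact in
    distribution.  Tiny negative eigenvalues from floating-point roundoff
    (possible for H very close to 1) are clipped; anything beyond roundoff
    raises.
    """
    n = spec.n
    r = fgn_autocovariance(spec.hurst, spec.sigma2, np.arange(n + 1))
    # first row of the 2n circulant: r0 .. rn, r_{n-1} .. r1
    row = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.fft(row).real
    tol = 1e-9 * lam.max()
    if lam.min() < -tol:
        raise ValueError(
            "circulant embedding not positive semi-definite for "
            f"H={spec.hurst}, n={n} (min eigenvalue {lam.min():.3e})"
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(spec.seed)
    m = 2 * n
    # z has independent N(0,1) real and imaginary parts; with weights
    # sqrt(lam/m) the real part of the FFT has autocovariance exactly r.
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = np.fft.fft(np.sqrt(lam / m) * z)
    out = x.real[:n]
    return TimeSeries(out, label=f"fgn(H={spec.hurst}, sigma2={spec.sigma2})",
                      seed=spec.seed)


def simulate_white_noise(n: int, sigma2: float = 1.0, seed: int = 0) -> TimeSeries:
    """IID Gaussian noise with mean 0 and variance sigma2."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n) * np.sqrt(sigma2)
    return TimeSeries(x, label=f"white(sigma2={sigma2})", seed=seed)


def simulate_one_over_f(n: int, alpha: float = 1.0, seed: int = 0) -> TimeSeries:
    """1/f^alpha noise by random-phase spectral synthesis.

    Fourier amplitudes are set deterministically to f^(-alpha/2) with
    uniform random phases, Hermitian symmetry enforced by the real inverse
    FFT, and the DC bin zeroed so the mean is exactly 0.  The output is
    rescaled to unit variance.  alpha = 0 reduces to (phase-randomized)
    white noise; alpha = 1 is the H = 1 boundary of the fGn family.
    """
    if n < 4:
        raise ValueError(f"n must be >= 4, got {n}")
    if not 0.0 <= alpha < 3.0:
        raise ValueError(f"alpha must lie in [0, 3), got {alpha}")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)           # 0, 1/n, ..., 1/2
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phase)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1]               # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("degenerate spectral synthesis (zero variance)")
    return TimeSeries(x / sd, label=f"oneoverf(alpha={alpha})", seed=seed)


def difference(x: TimeSeries) -> TimeSeries:
    """First difference y_i = x_i - x_{i-1}; output is one sample shorter."""
    if len(x) < 3:
        raise ValueError("differencing needs length >= 3 to leave a valid series")
    return TimeSeries(np.diff(x.values), dt=x.dt,
                      label=f"diff({x.label})" if x.label else "diff", seed=x.seed)


def random_walk(x: TimeSeries) -> TimeSeries:
    """Cumulative sum y_t = sum_{i<=t} x_i (no leading zero is prepended).

    ``difference(random_walk(x))`` recovers ``x`` without its first sample.
    """
    return TimeSeries(np.cumsum(x.values), dt=x.dt,
                      label=f"walk({x.label})" if x.label else "walk", seed=x.seed)
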