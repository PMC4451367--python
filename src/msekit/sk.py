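"""Shannon-Kolmogorov (rate-distortion) entropy of stationary Gaussian processes.

For a discrete-time stationary Gaussian process with power spectral density
Phi(omega) on (-pi, pi], the rate-distortion entropy at mean-square
distortion eps^2 is given by the Kolmogorov water-filling construction:

    eps^2   = (1/2pi) Integral min[theta, Phi(omega)] domega
    h_SK(eps) = (1/4pi) Integral max{0, ln(Phi(omega)/theta)} domega

with theta the unique water level solving the first equation.  For fGn,
Phi(omega) = B(H) |omega|^(1-2H) with B(H) = sigma^2 (2-2H) pi^(2H-1)
(fixed by requiring the same variance sigma^2 for every H), and for small
eps the entropy follows the closed form

    h_SK(eps) = A(H) - ln eps,
    A(H) = (1/2) ln sigma^2 + (1/2) [ln(2-2H) - (1-2H)]

which is maximal at H = 1/2.  Power-law PSDs are handled with analytic
integrals (the omega -> 0 singularity for H > 1/2 is integrable and done
in closed form); arbitrary PSDs fall back to adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "GaussianPSD",
    "SKResult",
    "fgn_psd",
    "flat_psd",
    "water_fill_theta",
    "h_sk",
    "water_filling",
    "A_of_H",
    "h_sk_closed_form",
]

_THETA_RTOL = 1e-12


@dataclass(frozen=True)
class GaussianPSD:
    """Symmetric power spectral density on (-pi, pi].

    ``phi`` evaluates Phi(|omega|); ``variance`` is (1/2pi) times its
    integral over (-pi, pi].  When the PSD is a pure power law
    B |omega|^p, set ``power_b`` and ``power_p`` to enable analytic
    water-filling integrals; otherwise numeric quadrature is used.
    """

    phi: Callable[[np.ndarray], np.ndarray]
    variance: float
    power_b: Optional[float] = None
    power_p: Optional[float] = None

    @property
    def is_power_law(self) -> bool:
        return self.power_b is not None and self.power_p is not None


@dataclass(frozen=True)
class SKResult:
    """Water-filling solution at one distortion level."""

    eps: float
    theta: float
    h_sk: float


def fgn_psd(hurst: float, sigma2: float = 1.0) -> GaussianPSD:
    """PSD of fGn: Phi(omega) = B(H) |omega|^(1-2H), variance sigma2.

    B(H) = sigma2 (2-2H) pi^(2H-1) makes (1/2pi) Integral Phi = sigma2 for
    every H, so fGn of different H are variance-matched.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie strictly in (0, 1), got {hurst}")
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    b = sigma2 * (2.0 - 2.0 * hurst) * math.pi ** (2.0 * hurst - 1.0)
    p = 1.0 - 2.0 * hurst

    def phi(omega):
        return b * np.abs(omega) ** p

    return GaussianPSD(phi=phi, variance=sigma2, power_b=b, power_p=p)


def flat_psd(sigma2: float = 1.0) -> GaussianPSD:
    """White-noise PSD, Phi = sigma2 everywhere."""
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    return GaussianPSD(phi=lambda w: np.full_like(np.asarray(w, float), sigma2),
                       variance=sigma2, power_b=sigma2, power_p=0.0)


def _distortion_power(b: float, p: float, theta: float) -> float:
    """(1/2pi) Integral_{-pi}^{pi} min(theta, B|w|^p) dw for a power law."""
    if theta <= 0:
        return 0.0
    if p == 0.0:
        return min(theta, b)
    phi_pi = b * math.pi ** p
    if p < 0:
        # Phi decreasing from +inf; water level below Phi everywhere?
        if theta <= phi_pi:
            return theta
        w_star = (theta / b) ** (1.0 / p)          # in (0, pi)
        tail = b * (math.pi ** (p + 1) - w_star ** (p + 1)) / (p + 1)
        return (theta * w_star + tail) / math.pi
    # p > 0: Phi increasing from 0
    if theta >= phi_pi:
        return b * math.pi ** p / (p + 1)           # = variance
    w_star = (theta / b) ** (1.0 / p)
    head = b * w_star ** (p + 1) / (p + 1)
    return (head + theta * (math.pi - w_star)) / math.pi


def _entropy_power(b: float, p: float, theta: float) -> float:
    """(1/4pi) Integral max{0, ln(Phi/theta)} dw for a power law."""
    if p == 0.0:
        return 0.5 * max(0.0, math.log(b / theta))
    if p < 0:
        w_star = (theta / b) ** (1.0 / p)
        u = min(w_star, math.pi)
        # Integral_0^u [ln(B/theta) + p ln w] dw
        val = u * math.log(b / theta) + p * (u * math.log(u) - u)
        return max(0.0, val / (2.0 * math.pi))
    phi_pi = b * math.pi ** p
    if theta >= phi_pi:
        return 0.0
    w_star = (theta / b) ** (1.0 / p)
    val = (math.pi - w_star) * math.log(b / theta) + p * (
        math.pi * math.log(math.pi) - math.pi - w_star * math.log(w_star) + w_star
    )
    return max(0.0, val / (2.0 * math.pi))


def _distortion_numeric(psd: GaussianPSD, theta: float) -> float:
    f = lambda w: np.minimum(theta, psd.phi(w))
    val, _ = integrate.quad(f, 0.0, math.pi, limit=200)
    return val / math.pi


def _entropy_numeric(psd: GaussianPSD, theta: float) -> float:
    f = lambda w: np.maximum(0.0, np.log(np.maximum(psd.phi(w), 1e-300) / theta))
    val, _ = integrate.quad(f, 0.0, math.pi, limit=200)
    return val / (2.0 * math.pi)


def distortion(psd: GaussianPSD, theta: float) -> float:
    """Mean-square distortion achieved at water level theta."""
    if psd.is_power_law:
        return _distortion_power(psd.power_b, psd.power_p, theta)
    return _distortion_numeric(psd, theta)


def water_fill_theta(psd: GaussianPSD, eps: float) -> float:
    """Water level theta solving the distortion equation for target eps.

    The distortion is strictly increasing in theta (up to the process
    variance), so the root is bracketed and found to high relative
    precision.  eps^2 > variance is an error: the distortion budget exceeds
    the signal power and h_SK is identically 0 there.
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    e2 = eps * eps
    if e2 > psd.variance * (1.0 + 1e-12):
        raise ValueError(
            f"eps^2 = {e2:.6g} exceeds the process variance {psd.variance:.6g}; "
            "h_SK = 0 in this regime"
        )
    lo = e2 * 1e-8
    hi = e2
    while distortion(psd, hi) < e2 and hi < 1e12 * psd.variance:
        hi *= 2.0
    theta = optimize.brentq(
        lambda t: distortion(psd, t) - e2, lo, hi,
        rtol=max(_THETA_RTOL, 4e-16), xtol=1e-300, maxiter=200,
    )
    return float(theta)


def h_sk(psd: GaussianPSD, eps: float) -> float:
    """Shannon-Kolmogorov entropy (nats per sample) at distortion eps."""
    return water_filling(psd, eps).h_sk


def water_filling(psd: GaussianPSD, eps: float) -> SKResult:
    """Solve the full water-filling problem, returning theta and h_SK."""
    theta = water_fill_theta(psd, eps)
    if psd.is_power_law:
        h = _entropy_power(psd.power_b, psd.power_p, theta)
    else:
        h = _entropy_numeric(psd, theta)
    return SKResult(eps=float(eps), theta=theta, h_sk=float(h))


def A_of_H(hurst: float, sigma2_half: float = 1.0) -> float:
    """Intercept A(H) of the small-eps closed form h_SK = A(H) - ln eps.

    ``sigma2_half`` is the common variance (the H = 1/2 value) shared by
    the variance-matched fGn family.  A(H) peaks at H = 1/2, where it
    equals (1/2) ln sigma2_half.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie strictly in (0, 1), got {hurst}")
    if not sigma2_half > 0:
        raise ValueError(f"sigma2_half must be positive, got {sigma2_half}")
    return 0.5 * math.log(sigma2_half) + 0.5 * (
        math.log(2.0 - 2.0 * hurst) - (1.0 - 2.0 * hurst)
    )


def h_sk_closed_form(hurst: float, eps: float, sigma2: float = 1.0) -> float:
    """Small-eps closed form A(H) - ln eps for variance-matched fGn."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    return A_of_H(hurst, sigma2) - math.log(eps)
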