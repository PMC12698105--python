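"""Analytic photon-counting noise model for measured g2 curves, and SNR.

The standard deviation of a correlator's g2 estimate is modelled following
the Koppel shot-noise analysis as adapted to diffuse correlation
spectroscopy (Zhou-style arrangement), for a single-exponential field
decorrelation g1 = exp(-Gamma tau), i.e. g2 = 1 + beta exp(-2 Gamma tau):

    sigma(tau) = sqrt(T/t) * [ beta^2 ( (1+e^{-2 Gamma T})(1+e^{-2 Gamma tau})
                                 + 2 m (1-e^{-2 Gamma T}) e^{-2 Gamma tau} )
                               / (1-e^{-2 Gamma T})
                 + 2 <n>^{-1} beta (1+e^{-2 Gamma tau})
                 + <n>^{-2} (1 + beta e^{-Gamma tau}) ]^{1/2}

with T the correlator bin width, t the integration time, m = tau/T the
delay-bin index, and <n> = I T the mean photon count per bin.  In the slow
decorrelation, low count-rate regime this reduces to

    sigma(tau) ~ (1/I) sqrt( (1 + beta e^{-Gamma tau}) / (t T) ).

For multi-tau lag grids each block applies its own widened bin width T;
pass per-lag bin widths to use that convention.

Note: the correlator bin width is named ``bin_width_T`` throughout —
"T" alone is reserved for absolute temperature elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_model import CorrelationCurve

__all__ = [
    "NoiseParams",
    "sigma_full",
    "sigma_simplified",
    "snr_curve",
    "empirical_sigma",
]


@dataclass(frozen=True)
class NoiseParams:
    """Inputs of the analytic g2 noise model.

    Parameters
    ----------
    bin_width_T : float
        Correlator bin width, s (base bin for multi-tau grids).
    integration_time_t : float
        Total measurement time, s.
    beta : float
        Coherence factor.
    Gamma : float
        Field decorrelation rate, s^-1 (g1 = exp(-Gamma tau)).
    count_rate_I : float
        Detected photon count rate, photons/s.
    """

    bin_width_T: float
    integration_time_t: float
    beta: float
    Gamma: float
    count_rate_I: float

    def __post_init__(self) -> None:
        if self.bin_width_T <= 0:
            raise ValueError("bin_width_T must be positive")
        if self.integration_time_t < self.bin_width_T:
            raise ValueError("integration time must be >= bin width")
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.Gamma < 0 or self.count_rate_I < 0:
            raise ValueError("Gamma and count rate must be non-negative")

    @property
    def mean_count_n(self) -> float:
        """Average photon count per base bin, <n> = I T."""
        return self.count_rate_I * self.bin_width_T


def sigma_full(
    tau: np.ndarray,
    params: NoiseParams,
    bin_widths: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Full analytic standard deviation of g2 at each lag.

    ``bin_widths`` optionally gives each lag its own effective bin width
    (the multi-tau convention, where block b uses the widened bin); the
    delay-bin index m is then tau over that lag's own width.  Without it
    every lag uses ``params.bin_width_T``.
    """
    tau = np.asarray(tau, dtype=float)
    if bin_widths is None:
        T = np.full_like(tau, params.bin_width_T)
    else:
        T = np.asarray(bin_widths, dtype=float)
        if T.shape != tau.shape:
            raise ValueError("bin_widths must match tau in length")
    g, b, t = params.Gamma, params.beta, params.integration_time_t
    if np.any(g * T == 0):
        raise ValueError(
            "Gamma * T = 0 makes the correlated-term denominator singular; "
            "use the small-Gamma*T series expansion (sigma_simplified) instead"
        )
    n_mean = params.count_rate_I * T
    if np.any(n_mean == 0):
        raise ValueError("zero count rate: noise is unbounded")
    m = np.round(tau / T)
    e2gT = np.exp(-2.0 * g * T)
    e2gt = np.exp(-2.0 * g * tau)
    egt = np.exp(-g * tau)
    one_minus = -np.expm1(-2.0 * g * T)  # 1 - e^{-2 Gamma T}, stable for small arg
    term_beta = b**2 * ((1.0 + e2gT) * (1.0 + e2gt) + 2.0 * m * one_minus * e2gt) / one_minus
    term_shot = 2.0 / n_mean * b * (1.0 + e2gt)
    term_floor = (1.0 + b * egt) / n_mean**2
    return np.sqrt(T / t) * np.sqrt(term_beta + term_shot + term_floor)


def sigma_simplified(tau: np.ndarray, params: NoiseParams) -> np.ndarray:
    """Simplified noise model for slow decorrelation and low count rates.

    sigma(tau) = (1/I) sqrt( (1 + beta e^{-Gamma tau}) / (t T) ); exactly
    inversely proportional to the count rate.
    """
    tau = np.asarray(tau, dtype=float)
    if params.count_rate_I == 0:
        raise ValueError("zero count rate: noise is unbounded")
    return (1.0 / params.count_rate_I) * np.sqrt(
        (1.0 + params.beta * np.exp(-params.Gamma * tau))
        / (params.integration_time_t * params.bin_width_T)
    )


def snr_curve(curve: CorrelationCurve, sigma: np.ndarray) -> np.ndarray:
    """Per-lag measurement SNR, defined as (g2(tau) - 1) / sigma(tau)."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != curve.tau.shape:
        raise ValueError("sigma must match the curve's lag grid in length")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive elementwise")
    return (curve.g2 - 1.0) / sigma


def empirical_sigma(curves: Sequence[CorrelationCurve]) -> np.ndarray:
    """Unbiased per-lag sample standard deviation across repeated curves."""
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    tau0 = curves[0].tau
    for c in curves[1:]:
        if c.tau.shape != tau0.shape or not np.allclose(c.tau, tau0):
            raise ValueError("all curves must share an identical lag grid")
    stack = np.stack([c.g2 for c in curves])
    return stack.std(axis=0, ddof=1)
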