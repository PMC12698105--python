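"""Closed-form forward models for DCS in a semi-infinite homogeneous medium.

The electric-field autocorrelation G1(rho, tau) solves the correlation
diffusion equation; for a semi-infinite medium with extrapolated-boundary
conditions the Green's function is the familiar two-source form

    G1(rho, tau) = (3 mu_s' / 4 pi) [ exp(-K r1)/r1 - exp(-K r2)/r2 ],

with K^2 = 3 mu_a mu_s' + mu_s'^2 k0^2 alpha <dr^2(tau)> and Brownian
dynamics <dr^2(tau)> = 6 D_B tau.  The intensity autocorrelation follows
from the Siegert relation g2 = 1 + beta |g1|^2.

A finite illumination spot is handled by averaging the point-source solution
over a uniform disk (the correlation diffusion equation is linear in the
source term), which slows the apparent decay at source-detector separations
comparable to the spot size.

Internal length unit is mm.  D_B is accepted in cm^2/s (the unit used for
flow indices throughout the field) and converted to mm^2/s internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

BOLTZMANN_J_PER_K = 1.380649e-23

__all__ = [
    "OpticalProperties",
    "SemiInfiniteGeometry",
    "FlowModel",
    "CorrelationCurve",
    "effective_reflection_coefficient",
    "einstein_stokes",
    "g1_point",
    "g1_disk",
    "g2_from_g1",
    "model_g2",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of the homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.
    n0 : float
        Refractive index of the medium (default 1.33, aqueous).
    n_air : float
        Refractive index of the exterior (default 1.0).
    wavelength_nm : float
        Vacuum wavelength of the source, nm (default 785).
    """

    mu_a: float
    mu_s_prime: float
    n0: float = 1.33
    n_air: float = 1.0
    wavelength_nm: float = 785.0

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("mu_a and mu_s_prime must be positive")
        if self.n0 < 1 or self.n_air < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def n_rel(self) -> float:
        """Relative refractive index n0/n_air."""
        return self.n0 / self.n_air

    @property
    def k0(self) -> float:
        """Wavenumber of light in the medium, mm^-1."""
        wavelength_mm = self.wavelength_nm * 1e-6
        return 2.0 * np.pi * self.n0 / wavelength_mm


def effective_reflection_coefficient(n: float) -> float:
    """Effective reflection coefficient of the extrapolated boundary.

    Uses the standard polynomial approximation in the relative refractive
    index ``n = n0/n_air``:

        Reff = -1.44 n^-2 + 0.71 n^-1 + 0.668 + 0.064 n

    Valid for n around 1-1.6; the caller should check 0 <= Reff < 1 before
    using it in the extrapolation length.
    """
    if n <= 0:
        raise ValueError(f"relative refractive index must be positive, got {n}")
    return -1.44 / n**2 + 0.71 / n + 0.668 + 0.064 * n


@dataclass(frozen=True)
class SemiInfiniteGeometry:
    """Source-detector geometry for the semi-infinite Green's function.

    All lengths in mm.  ``z0`` is the depth of the isotropic source,
    ``zb`` the extrapolated-boundary distance, ``r1``/``r2`` the distances
    from the detector to the true and image sources.
    """

    rho: float
    z0: float
    zb: float
    Reff: float
    r1: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("source-detector separation rho must be positive")
        if not (0 <= self.Reff < 1):
            raise ValueError(f"Reff must lie in [0, 1), got {self.Reff}")
        object.__setattr__(self, "r1", float(np.hypot(self.rho, self.z0)))
        object.__setattr__(
            self, "r2", float(np.hypot(self.rho, self.z0 + 2.0 * self.zb))
        )
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("degenerate geometry: r1 and r2 must be positive")

    @classmethod
    def from_optics(cls, rho: float, props: OpticalProperties) -> "SemiInfiniteGeometry":
        """Build the geometry implied by a separation and optical properties."""
        reff = effective_reflection_coefficient(props.n_rel)
        z0 = 1.0 / (props.mu_a + props.mu_s_prime)
        zb = 2.0 * (1.0 + reff) / (3.0 * props.mu_s_prime * (1.0 - reff))
        return cls(rho=rho, z0=z0, zb=zb, Reff=reff)


@dataclass(frozen=True)
class FlowModel:
    """Brownian scatterer dynamics.

    ``DB`` is the effective Brownian diffusion coefficient in cm^2/s and
    ``alpha`` the fraction of moving scatterers; the blood-flow index is
    BFi = alpha * DB.  Mean-square displacement: <dr^2(tau)> = 6 DB tau.
    """

    DB: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.DB < 0:
            raise ValueError("DB must be non-negative")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def BFi(self) -> float:
        return self.alpha * self.DB


@dataclass
class CorrelationCurve:
    """An intensity autocorrelation curve g2(tau).

    The central exchange object between the simulator, correlator, fitter
    and noise model.  ``tau`` in seconds, strictly increasing; ``sigma`` is
    an optional per-lag standard deviation.
    """

    tau: np.ndarray
    g2: np.ndarray
    beta: Optional[float] = None
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.shape != self.g2.shape:
            raise ValueError("tau and g2 must have the same length")
        if self.tau.size and np.any(np.diff(self.tau) <= 0):
            raise ValueError("tau must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.tau.shape:
                raise ValueError("sigma must match tau in length")
        if self.beta is not None and not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")

    def __len__(self) -> int:
        return self.tau.size


def _decay_wavenumber(
    tau: np.ndarray, props: OpticalProperties, flow: FlowModel
) -> np.ndarray:
    """K(tau) in mm^-1.  DB converted cm^2/s -> mm^2/s (x100)."""
    db_mm2 = flow.DB * 100.0
    msd = 6.0 * db_mm2 * tau  # mm^2
    k2 = 3.0 * props.mu_a * props.mu_s_prime + (
        props.mu_s_prime**2 * props.k0**2 * flow.alpha * msd
    )
    return np.sqrt(k2)


def _g1_unnormalized(rho: np.ndarray, k: np.ndarray, props: OpticalProperties,
                     z0: float, zb: float) -> np.ndarray:
    """Two-source Green's function without the 3*mu_s'/4pi prefactor.

    Broadcasts ``rho`` (source offsets) against ``k`` (lags).  ``rho`` may be
    zero (detector directly above a source element): r1 >= z0 > 0 there.
    """
    r1 = np.hypot(rho, z0)
    r2 = np.hypot(rho, z0 + 2.0 * zb)
    return np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2


def g1_point(
    geometry: SemiInfiniteGeometry,
    props: OpticalProperties,
    flow: FlowModel,
    tau: np.ndarray,
) -> np.ndarray:
    """Normalized field autocorrelation g1(tau) for a point source.

    Returns G1(rho, tau)/G1(rho, 0); the 3 mu_s'/4 pi prefactor cancels.
    Monotonically non-increasing in tau with g1(0) = 1.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lag times must be non-negative")
    k = _decay_wavenumber(tau, props, flow)
    k0 = _decay_wavenumber(np.asarray(0.0), props, flow)
    num = np.exp(-k * geometry.r1) / geometry.r1 - np.exp(-k * geometry.r2) / geometry.r2
    den = np.exp(-k0 * geometry.r1) / geometry.r1 - np.exp(-k0 * geometry.r2) / geometry.r2
    return num / den


class QuadratureError(RuntimeError):
    """Raised when the disk-source quadrature fails to converge."""


def _disk_average_g1(
    rho: float,
    source_radius: float,
    k: np.ndarray,
    props: OpticalProperties,
    z0: float,
    zb: float,
    n_radial: int,
    n_angular: int,
) -> np.ndarray:
    """Area-average of the point Green's function over a uniform disk.

    Polar quadrature: Gauss-Legendre in radius (with the Jacobian r),
    uniform midpoint rule in angle (periodic integrand, spectrally
    accurate).  Returns the unnormalized average for each k.
    """
    x, w = np.polynomial.legendre.leggauss(n_radial)
    r = 0.5 * source_radius * (x + 1.0)  # [0, a]
    wr = 0.5 * source_radius * w * r  # includes Jacobian r
    theta = (np.arange(n_angular) + 0.5) * (2.0 * np.pi / n_angular)
    wt = 2.0 * np.pi / n_angular
    # detector distance to each source element
    rr, tt = np.meshgrid(r, theta, indexing="ij")
    dist = np.sqrt(rho**2 + rr**2 - 2.0 * rho * rr * np.cos(tt))
    vals = _g1_unnormalized(dist.ravel()[None, :], k[:, None], props, z0, zb)
    weights = (wr[:, None] * wt * np.ones_like(tt)).ravel()
    area = np.pi * source_radius**2
    return (vals @ weights) / area


def g1_disk(
    geometry: SemiInfiniteGeometry,
    props: OpticalProperties,
    flow: FlowModel,
    tau: np.ndarray,
    source_radius: float,
    quadrature_tol: float = 1e-6,
    max_refinements: int = 7,
) -> np.ndarray:
    """Normalized field autocorrelation for a uniform disk source.

    Averages the point-source solution over a disk of radius
    ``source_radius`` centred at the source position, the detector sitting
    at lateral distance ``geometry.rho`` from the disk centre, and
    normalizes by the curve's own tau = 0 value.  Quadrature orders are
    refined until successive refinements agree to ``quadrature_tol``
    (relative, on the normalized curve).

    For ``source_radius`` -> 0 this converges to :func:`g1_point`; at
    separations comparable to the spot size the decay is slower than the
    point-source decay.
    """
    if source_radius < 0:
        raise ValueError("source_radius must be non-negative")
    tau = np.asarray(tau, dtype=float)
    if source_radius == 0 or source_radius < 1e-9 * max(geometry.rho, 1.0):
        return g1_point(geometry, props, flow, tau)

    k = np.atleast_1d(_decay_wavenumber(tau, props, flow))
    k_all = np.concatenate([[float(_decay_wavenumber(np.asarray(0.0), props, flow))], k])

    n_radial, n_angular = 16, 32
    prev = None
    for _ in range(max_refinements):
        vals = _disk_average_g1(
            geometry.rho, source_radius, k_all, props, geometry.z0, geometry.zb,
            n_radial, n_angular,
        )
        g1 = vals[1:] / vals[0]
        if prev is not None:
            err = np.max(np.abs(g1 - prev) / np.maximum(np.abs(prev), 1e-12))
            if err < quadrature_tol:
                return g1.reshape(tau.shape)
        prev = g1
        n_radial *= 2
        n_angular *= 2
    raise QuadratureError(
        f"disk quadrature did not converge to {quadrature_tol:g} after "
        f"{max_refinements} refinements (last orders {n_radial}x{n_angular})"
    )


def g2_from_g1(
    g1: np.ndarray, beta: float, tau: Optional[np.ndarray] = None
) -> np.ndarray | CorrelationCurve:
    """Siegert relation: g2 = 1 + beta |g1|^2.

    Returns an array, or a :class:`CorrelationCurve` when ``tau`` is given.
    """
    if not (0 < beta <= 1):
        raise ValueError(f"beta must lie in (0, 1], got {beta}")
    g1 = np.asarray(g1, dtype=float)
    if np.any(np.abs(g1) > 1 + 1e-9):
        raise ValueError("|g1| must not exceed 1")
    g2 = 1.0 + beta * np.abs(g1) ** 2
    if tau is None:
        return g2
    return CorrelationCurve(tau=np.asarray(tau, float), g2=g2, beta=beta)


def model_g2(
    rho: float,
    props: OpticalProperties,
    flow: FlowModel,
    tau: np.ndarray,
    beta: float,
    source_radius: float = 0.0,
    quadrature_tol: float = 1e-6,
) -> CorrelationCurve:
    """Forward-model g2(tau) at separation ``rho`` (mm).

    ``source_radius = 0`` selects the point-source model, otherwise the
    uniform-disk source of that radius.
    """
    geom = SemiInfiniteGeometry.from_optics(rho, props)
    if source_radius > 0:
        g1 = g1_disk(geom, props, flow, tau, source_radius, quadrature_tol)
    else:
        g1 = g1_point(geom, props, flow, tau)
    return g2_from_g1(g1, beta, tau=tau)


def einstein_stokes(
    temperature_K: float, viscosity_Pa_s: float, particle_radius_m: float
) -> float:
    """Brownian diffusion coefficient from the Einstein-Stokes relation.

    D_B = k_B T / (6 pi eta r), returned in cm^2/s.
    """
    if temperature_K <= 0 or viscosity_Pa_s <= 0 or particle_radius_m <= 0:
        raise ValueError("temperature, viscosity and particle radius must be positive")
    d_m2 = BOLTZMANN_J_PER_K * temperature_K / (
        6.0 * np.pi * viscosity_Pa_s * particle_radius_m
    )
    return d_m2 * 1e4
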