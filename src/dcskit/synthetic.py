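"""Synthetic inputs with controlled ground truth.

This module stands in for the instrument: it produces speckle photon-count
streams (laser + phantom + single-photon detector + time tagger), noisy g2
curves with the analytic noise amplitude, camera beam images, and
cuff-occlusion flow-index sequences.

Speckle streams are simulated per detected mode as a complex Gaussian field
following a first-order autoregressive process whose autocorrelation is
exp(-Gamma tau) — exact for single-rate decorrelation; the detected
intensity is the mean of |E|^2 over modes, so the intensity correlation is
g2(tau) = 1 + (1/M) exp(-2 Gamma tau), i.e. the coherence factor is
beta = 1/M for M modes.  Adding a static (uncorrelated) intensity fraction
s lowers the contrast to beta = (1-s)^2 / M, which reaches arbitrary beta.
Photon counts are Poisson draws at a rate proportional to the instantaneous
intensity, scaled to the requested mean count rate.

All generators are pure functions of (spec, seed): per-replicate generators
derive sub-streams from ``numpy``'s seed-sequence spawning of the master
seed with the replicate counter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import lfilter
from scipy.special import erf

from .core_model import CorrelationCurve, FlowModel, OpticalProperties, model_g2
from .correlator import PhotonCountSeries
from .mpe_beam import BeamProfile
from .noise import NoiseParams, sigma_full

__all__ = [
    "SpeckleStreamSpec",
    "OcclusionProtocolSpec",
    "generate_speckle_stream",
    "generate_g2_curves",
    "generate_beam_image",
    "generate_occlusion_bfi",
]


@dataclass(frozen=True)
class SpeckleStreamSpec:
    """Parameters of a synthetic single-rate speckle photon stream.

    ``n_modes_M`` detected speckle modes set the coherence factor
    beta = 1/M; ``sim_bin`` must resolve the field decay
    (sim_bin <= 0.05/Gamma).  ``static_fraction`` adds an uncorrelated
    constant intensity component (beta = (1-s)^2/M).
    """

    Gamma: float  # field decay rate, s^-1
    mean_count_rate: float  # photons/s
    duration: float  # s
    sim_bin: float  # s
    n_modes_M: int = 1
    static_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.Gamma, self.mean_count_rate, self.duration, self.sim_bin) <= 0:
            raise ValueError("Gamma, count rate, duration and sim_bin must be positive")
        if self.n_modes_M < 1:
            raise ValueError("n_modes_M must be >= 1")
        if not (0 <= self.static_fraction < 1):
            raise ValueError("static_fraction must lie in [0, 1)")
        if self.sim_bin > 0.05 / self.Gamma:
            raise ValueError(
                f"sim_bin = {self.sim_bin:g} s too coarse for Gamma = "
                f"{self.Gamma:g} s^-1 (need sim_bin <= 0.05/Gamma)"
            )

    @property
    def beta(self) -> float:
        return (1.0 - self.static_fraction) ** 2 / self.n_modes_M


def generate_speckle_stream(spec: SpeckleStreamSpec) -> PhotonCountSeries:
    """Simulate a photon-count stream with g2 = 1 + beta exp(-2 Gamma tau)."""
    rng = np.random.default_rng(spec.seed)
    n_bins = int(round(spec.duration / spec.sim_bin))
    r = np.exp(-spec.Gamma * spec.sim_bin)
    s_innov = np.sqrt(1.0 - r**2)

    intensity = np.zeros(n_bins)
    for _ in range(spec.n_modes_M):
        # stationary AR(1) complex Gaussian field, autocorrelation r^|k|
        noise = (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)) / np.sqrt(2.0)
        e0 = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2.0)
        field, _ = lfilter([s_innov], [1.0, -r], noise, zi=np.array([r * e0]))
        intensity += np.abs(field) ** 2
    intensity /= spec.n_modes_M  # E[intensity] = 1

    s = spec.static_fraction
    rate = spec.mean_count_rate * spec.sim_bin * ((1.0 - s) * intensity + s)
    counts = rng.poisson(rate)
    return PhotonCountSeries(counts=counts, bin_width=spec.sim_bin)


def generate_g2_curves(
    model_curve: CorrelationCurve,
    params: NoiseParams,
    n_replicates: int,
    seed: int = 0,
    bin_widths: Optional[np.ndarray] = None,
    sigma_scale: float = 1.0,
) -> List[CorrelationCurve]:
    """Noisy replicates of a model g2 curve.

    Each replicate adds independent zero-mean Gaussian noise whose per-lag
    standard deviation follows the full analytic noise model; replicates
    use sub-seeds spawned from the master seed so they are independent and
    reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    sigma = sigma_scale * sigma_full(model_curve.tau, params, bin_widths=bin_widths) \
        if sigma_scale != 0 else np.zeros_like(model_curve.tau)
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        noise = rng.standard_normal(model_curve.tau.size) * sigma if sigma_scale else 0.0
        out.append(
            CorrelationCurve(
                tau=model_curve.tau.copy(),
                g2=model_curve.g2 + noise,
                beta=model_curve.beta,
                sigma=sigma.copy() if sigma_scale else None,
            )
        )
    return out


def generate_beam_image(
    kind: str,
    diameter: float,
    pixel_pitch: float,
    total_power: float = 1.0,
    edge_softness: float = 0.0,
    noise_level: float = 0.0,
    margin: float = 4.0,
    seed: int = 0,
) -> BeamProfile:
    """Synthetic camera image of a flat-top or Gaussian beam.

    ``diameter`` (mm) is the disk diameter for a flat-top and the 1/e^2
    diameter for a Gaussian; the image is renormalized so the integrated
    power equals ``total_power`` exactly.  ``margin`` (mm) of dark border
    surrounds the spot so downstream aperture scans have room.
    """
    if kind not in ("gaussian", "flattop"):
        raise ValueError(f"kind must be 'gaussian' or 'flattop', got {kind!r}")
    if diameter <= 0 or pixel_pitch <= 0 or total_power <= 0:
        raise ValueError("diameter, pixel_pitch and total_power must be positive")
    if diameter / pixel_pitch < 50:
        raise ValueError("grid too coarse: the beam must span at least 50 pixels")
    half = diameter / 2.0 + margin
    n_half = int(np.ceil(half / pixel_pitch))
    idx = np.arange(-n_half, n_half + 1) * pixel_pitch
    yy, xx = np.meshgrid(idx, idx, indexing="ij")
    r = np.hypot(xx, yy)
    radius = diameter / 2.0
    if kind == "flattop":
        if edge_softness > 0:
            img = 0.5 * (1.0 - erf((r - radius) / (edge_softness / 2.0)))
        else:
            img = (r <= radius).astype(float)
    else:
        img = np.exp(-2.0 * r**2 / radius**2)  # radius = 1/e^2 radius
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + noise_level * img.max() * rng.standard_normal(img.shape), 0.0, None)
    # keep a genuinely dark margin so support detection stays meaningful
    img[r > radius + margin / 2.0] = 0.0
    profile = BeamProfile(img, pixel_pitch)
    return profile.scaled_to_power(total_power)


@dataclass(frozen=True)
class OcclusionProtocolSpec:
    """A three-phase cuff-occlusion protocol: baseline, occlusion, recovery.

    ``relative_levels`` give the flow level of each phase relative to
    baseline; on cuff release the flow overshoots to ``overshoot`` times
    baseline and relaxes exponentially (time constant ``recovery_tau``)
    to the recovery level.
    """

    phase_durations: Tuple[float, float, float] = (40.0, 40.0, 40.0)
    relative_levels: Tuple[float, float, float] = (1.0, 0.2, 1.0)
    overshoot: float = 1.5
    recovery_tau: float = 10.0  # s

    def __post_init__(self) -> None:
        if min(self.phase_durations) <= 0:
            raise ValueError("phase durations must be positive")
        if self.relative_levels[1] >= self.relative_levels[0]:
            raise ValueError("occlusion level must fall below baseline")
        if self.overshoot < self.relative_levels[2]:
            raise ValueError("overshoot must be >= the recovery level")
        if self.recovery_tau < 0:
            raise ValueError("recovery_tau must be non-negative")


def relative_flow_trace(spec: OcclusionProtocolSpec, times: np.ndarray) -> np.ndarray:
    """Programmed relative flow level at each time point."""
    t1, t2, _ = np.cumsum(spec.phase_durations)
    base, occl, rec = spec.relative_levels
    times = np.asarray(times, dtype=float)
    out = np.full_like(times, base)
    out[(times >= t1) & (times < t2)] = occl
    post = times >= t2
    if spec.recovery_tau > 0:
        out[post] = rec + (spec.overshoot - rec) * np.exp(
            -(times[post] - t2) / spec.recovery_tau
        )
    else:
        out[post] = rec  # degenerate: step recovery
    return out


def generate_occlusion_bfi(
    spec: OcclusionProtocolSpec,
    window: float,
    DB_baseline: float,
    props: OpticalProperties,
    rho: float = 20.0,
    beta: float = 0.5,
    tau: Optional[np.ndarray] = None,
    noise_params: Optional[NoiseParams] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, List[CorrelationCurve]]:
    """Per-window true BFi trace plus model g2 curves along the protocol.

    Returns (window centre times, true BFi in cm^2/s, curves).  Curves are
    noise-free by default; pass ``noise_params`` to add analytic-model
    noise (Gamma is ignored there in favour of each window's own decay).
    """
    if window <= 0 or DB_baseline <= 0:
        raise ValueError("window and DB_baseline must be positive")
    total = sum(spec.phase_durations)
    starts = np.arange(0.0, total - window / 2.0, window)
    centers = starts + window / 2.0
    rel = relative_flow_trace(spec, centers)
    bfi = DB_baseline * rel
    if tau is None:
        tau = np.logspace(-8, -2, 80)
    curves: List[CorrelationCurve] = []
    children = np.random.SeedSequence(seed).spawn(len(centers))
    for db, child in zip(bfi, children):
        curve = model_g2(rho, props, FlowModel(DB=db), tau, beta)
        if noise_params is not None:
            curve = generate_g2_curves(
                curve, noise_params, 1, seed=int(child.generate_state(1)[0] % 2**31)
            )[0]
        curves.append(curve)
    return centers, bfi, curves
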