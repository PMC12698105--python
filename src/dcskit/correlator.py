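"""Multi-tau estimation of g2(tau) from photon-count streams.

The correlator mirrors the lag layout of hardware time taggers: a base bin
width for the first block of lags, then the bin width multiplied by a fixed
factor for every subsequent block (here a 6.145 ns base tripling every 16
lags, the layout of the SPC-QC-104 tagger).  Counts entering block b are
produced by summing ``widening_factor`` adjacent bins of block b-1, which
conserves total counts exactly.

The default normalization is the symmetric estimator

    g2(tau) = <I(t) I(t+tau)> / ( <I(t)>_overlap <I(t+tau)>_overlap ),

with all averages over the overlapping support only (no wrap-around);
for stationary streams this coincides with the <I>^2 denominator, which is
available via ``normalization="mean_square"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .core_model import CorrelationCurve

__all__ = [
    "PhotonCountSeries",
    "MultiTauScheme",
    "CoverageError",
    "multi_tau_lags",
    "autocorrelate",
    "timestamps_to_counts",
]


@dataclass
class PhotonCountSeries:
    """Uniformly binned photon counts.

    ``counts`` are non-negative integers per bin, ``bin_width`` the base
    resolution in seconds.
    """

    counts: np.ndarray
    bin_width: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def duration(self) -> float:
        return self.counts.size * self.bin_width


@dataclass(frozen=True)
class MultiTauScheme:
    """Lag layout of a multi-tau correlator.

    Lag k in block b has bin width ``base_bin * widening_factor**(b-1)``.
    ``n_blocks=None`` lets :func:`autocorrelate` use as many blocks as the
    series supports.
    """

    base_bin: float = 6.145e-9
    lags_per_block: int = 16
    widening_factor: int = 3
    n_blocks: Optional[int] = 10

    def __post_init__(self) -> None:
        if self.base_bin <= 0:
            raise ValueError("base_bin must be positive")
        if self.lags_per_block < 1:
            raise ValueError("lags_per_block must be >= 1")
        if self.widening_factor < 2:
            raise ValueError("widening_factor must be >= 2")
        if self.n_blocks is not None and self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


def _lag_layout_base_units(
    lags_per_block: int, factor: int, n_blocks: int
) -> List[Tuple[int, int]]:
    """(lag, spacing) pairs in integer base-bin units."""
    out: List[Tuple[int, int]] = []
    last = 0
    for b in range(1, n_blocks + 1):
        spacing = factor ** (b - 1)
        first = (last // spacing + 1) * spacing
        for k in range(lags_per_block):
            out.append((first + k * spacing, spacing))
        last = out[-1][0]
    return out


def multi_tau_lags(scheme: MultiTauScheme) -> List[Tuple[float, float]]:
    """Return the (lag_time, bin_width) pairs of the scheme, in seconds.

    Lag times are strictly increasing; within each block consecutive lags
    differ by that block's bin width.
    """
    if scheme.n_blocks is None:
        raise ValueError("scheme.n_blocks must be set to enumerate lags")
    layout = _lag_layout_base_units(
        scheme.lags_per_block, scheme.widening_factor, scheme.n_blocks
    )
    return [(m * scheme.base_bin, s * scheme.base_bin) for m, s in layout]


class CoverageError(ValueError):
    """A requested lag has too few product terms for a stable estimate."""


def _rebin(x: np.ndarray, factor: int) -> np.ndarray:
    n = (x.size // factor) * factor
    return x[:n].reshape(-1, factor).sum(axis=1)


def autocorrelate(
    series: PhotonCountSeries,
    scheme: MultiTauScheme,
    min_overlap: int = 100,
    normalization: str = "symmetric",
) -> CorrelationCurve:
    """Estimate g2(tau) on the scheme's multi-tau lag grid.

    Parameters
    ----------
    series : PhotonCountSeries
        Counts binned at the scheme's base resolution (``series.bin_width``
        is taken as the base bin).
    scheme : MultiTauScheme
        Lag layout.  With ``n_blocks=None`` the correlator emits every
        block the series length supports.
    min_overlap : int
        Minimum number of product terms required per lag.
    normalization : str
        "symmetric" (overlap means, default) or "mean_square" (the global
        <I>^2 denominator).

    Raises
    ------
    ZeroDivisionError
        All-zero counts leave the normalization undefined.
    CoverageError
        The series is too short for a requested lag (explicit n_blocks).
    """
    if normalization not in ("symmetric", "mean_square"):
        raise ValueError(f"unknown normalization {normalization!r}")
    x0 = np.asarray(series.counts, dtype=float)
    if x0.size == 0 or x0.sum() == 0:
        raise ZeroDivisionError(
            "all-zero photon-count series: g2 normalization is undefined"
        )
    factor = scheme.widening_factor
    auto = scheme.n_blocks is None
    n_blocks = scheme.n_blocks
    if auto:
        # generous upper bound; blocks stop when coverage runs out
        n_blocks = 1
        while factor ** n_blocks * (scheme.lags_per_block + min_overlap) < x0.size:
            n_blocks += 1
    layout = _lag_layout_base_units(scheme.lags_per_block, factor, n_blocks)

    mean_sq = (x0.mean()) ** 2
    taus: List[float] = []
    g2s: List[float] = []
    x = x0
    spacing_cur = 1
    for lag, spacing in layout:
        if spacing != spacing_cur:
            x = _rebin(x, factor)
            spacing_cur = spacing
        shift = lag // spacing
        n = x.size - shift
        if n < min_overlap:
            if auto:
                break
            raise CoverageError(
                f"series too short: lag {lag * scheme.base_bin:.6g} s has only "
                f"{max(n, 0)} product terms (< {min_overlap})"
            )
        left = x[:n]
        right = x[shift:]
        num = float(left @ right) / n
        if normalization == "symmetric":
            den = left.mean() * right.mean()
        else:
            den = mean_sq * spacing**2
        if den == 0:
            raise ZeroDivisionError(
                f"zero mean in overlap at lag {lag * scheme.base_bin:.6g} s"
            )
        taus.append(lag * scheme.base_bin)
        g2s.append(num / den)
    return CorrelationCurve(tau=np.array(taus), g2=np.array(g2s))


def timestamps_to_counts(
    timestamps: np.ndarray, bin_width: float, duration: float
) -> PhotonCountSeries:
    """Histogram photon arrival times into a uniformly binned series.

    ``timestamps`` must be sorted and are expected within [0, duration);
    arrivals outside that range are dropped.  The series has
    ``floor(duration / bin_width)`` bins.
    """
    if bin_width <= 0 or duration <= 0:
        raise ValueError("bin_width and duration must be positive")
    ts = np.asarray(timestamps, dtype=float)
    if ts.size and np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be sorted ascending")
    n_bins = int(np.floor(duration / bin_width))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    idx = np.floor(ts / bin_width).astype(np.int64)
    keep = (ts >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    return PhotonCountSeries(counts=counts, bin_width=bin_width)
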