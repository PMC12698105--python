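"""File formats and run configuration.

Formats are deliberately plain: correlation curves and reports are
delimited text with headers (``tau_s,g2[,sigma]``, decimal point,
scientific notation allowed); photon timestamps are one arrival time in
seconds per line (text) or raw little-endian uint64 tick counts at the
correlator base bin (``.u64``/``.bin``); beam maps are 16-bit grayscale
TIFF or ASCII portable graymaps with a YAML sidecar carrying the pixel
pitch and power calibration.  Every writer's output is re-readable by the
corresponding reader.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core_model import CorrelationCurve
from .correlator import PhotonCountSeries, timestamps_to_counts
from .mpe_beam import BeamProfile

__all__ = [
    "write_curve",
    "read_curve",
    "write_curve_table",
    "read_curve_table",
    "read_timestamps",
    "write_timestamps",
    "write_beam_profile",
    "read_beam_profile",
    "write_noise_report",
    "load_config",
    "save_config",
    "RunConfig",
]

_TEXT_TS_SUFFIXES = {".txt", ".csv", ".dat", ".tsv"}
_RAW_TS_SUFFIXES = {".u64", ".bin"}


# ---------------------------------------------------------------- curves

def write_curve(path: Union[str, Path], curve: CorrelationCurve) -> None:
    cols = {"tau_s": curve.tau, "g2": curve.g2}
    if curve.sigma is not None:
        cols["sigma"] = curve.sigma
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_curve(path: Union[str, Path]) -> CorrelationCurve:
    df = pd.read_csv(path)
    for col in ("tau_s", "g2"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return CorrelationCurve(
        tau=df["tau_s"].to_numpy(), g2=df["g2"].to_numpy(), sigma=sigma
    )


def write_curve_table(
    path: Union[str, Path], curves: Sequence[CorrelationCurve],
    window_ids: Optional[Sequence] = None,
) -> None:
    """Long-format table (window_id, tau_s, g2) for batch fitting."""
    if window_ids is None:
        window_ids = list(range(len(curves)))
    frames = [
        pd.DataFrame({"window_id": wid, "tau_s": c.tau, "g2": c.g2})
        for wid, c in zip(window_ids, curves)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_curve_table(path: Union[str, Path]) -> List[CorrelationCurve]:
    df = pd.read_csv(path)
    curves = []
    for _, group in df.groupby("window_id", sort=True):
        curves.append(
            CorrelationCurve(tau=group["tau_s"].to_numpy(), g2=group["g2"].to_numpy())
        )
    return curves


# ------------------------------------------------------------ timestamps

def write_timestamps(
    path: Union[str, Path], timestamps_s: np.ndarray, base_bin: float = 6.145e-9
) -> None:
    path = Path(path)
    ts = np.asarray(timestamps_s, dtype=float)
    if path.suffix in _RAW_TS_SUFFIXES:
        ticks = np.round(ts / base_bin).astype("<u8")
        ticks.tofile(path)
    else:
        np.savetxt(path, ts, fmt="%.12g")


def read_timestamps(
    path: Union[str, Path],
    bin_width: float,
    duration: Optional[float] = None,
    base_bin: float = 6.145e-9,
) -> PhotonCountSeries:
    """Read arrival times and bin them into a photon-count series.

    Text files hold one arrival time in seconds per line; ``.u64``/``.bin``
    hold raw little-endian uint64 tick counts at ``base_bin`` resolution.
    """
    path = Path(path)
    if path.suffix in _RAW_TS_SUFFIXES:
        ts = np.fromfile(path, dtype="<u8").astype(float) * base_bin
    else:
        ts = np.atleast_1d(np.loadtxt(path, dtype=float, ndmin=1))
    if duration is None:
        duration = float(ts.max()) + bin_width if ts.size else bin_width
    return timestamps_to_counts(np.sort(ts), bin_width, duration)


# ------------------------------------------------------------- beam maps

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_beam_profile(path: Union[str, Path], profile: BeamProfile) -> None:
    """Write a beam map as 16-bit TIFF or ASCII PGM plus a YAML sidecar.

    The sidecar records the pixel pitch and the physical peak irradiance so
    the quantized image can be restored losslessly up to quantization.
    """
    path = Path(path)
    peak = float(profile.irradiance.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    img = np.round(profile.irradiance * scale).astype(np.uint16)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img)
    elif path.suffix == ".pgm":
        with open(path, "w") as fh:
            fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n65535\n")
            for row in img:
                fh.write(" ".join(str(v) for v in row) + "\n")
    else:
        raise ValueError(f"unsupported beam-map format {path.suffix!r}")
    meta = {
        "pixel_pitch_mm": float(profile.pixel_pitch),
        "irradiance_per_count": peak / 65535.0 if peak > 0 else 1.0,
        "units": "W/cm^2",
    }
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_beam_profile(path: Union[str, Path]) -> BeamProfile:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path).astype(float)
    elif path.suffix == ".pgm":
        with open(path) as fh:
            tokens = []
            for line in fh:
                line = line.split("#")[0]
                tokens.extend(line.split())
        if tokens[0] != "P2":
            raise ValueError(f"{path}: expected an ASCII PGM (P2) file")
        w, h = int(tokens[1]), int(tokens[2])
        img = np.array(tokens[4 : 4 + w * h], dtype=float).reshape(h, w)
    else:
        raise ValueError(f"unsupported beam-map format {path.suffix!r}")
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    return BeamProfile(img * meta["irradiance_per_count"], meta["pixel_pitch_mm"])


# --------------------------------------------------------------- reports

def write_noise_report(
    path: Union[str, Path],
    tau: np.ndarray,
    sigma_model: np.ndarray,
    sigma_empirical: Optional[np.ndarray] = None,
    snr: Optional[np.ndarray] = None,
) -> None:
    cols: Dict[str, np.ndarray] = {"tau_s": tau, "sigma_model": sigma_model}
    if sigma_empirical is not None:
        cols["sigma_empirical"] = sigma_empirical
    if snr is not None:
        cols["snr"] = snr
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------- config

@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of a pipeline run; YAML round-trippable."""

    optics: Dict = dataclasses.field(default_factory=lambda: {
        "mu_a": 0.0025, "mu_s_prime": 1.0, "n0": 1.33, "n_air": 1.0,
        "wavelength_nm": 785.0,
    })
    geometry: Dict = dataclasses.field(default_factory=lambda: {
        "rho_mm": 20.0, "source_radius_mm": 0.0,
    })
    scheme: Dict = dataclasses.field(default_factory=lambda: {
        "base_bin_s": 6.145e-9, "lags_per_block": 16, "widening_factor": 3,
        "n_blocks": None,
    })
    noise: Dict = dataclasses.field(default_factory=lambda: {
        "integration_time_s": 1.0, "beta": 0.5,
    })
    fit: Dict = dataclasses.field(default_factory=lambda: {
        "model_kind": "point", "beta_fixed": None, "DB_init": 1e-7,
    })
    safety: Dict = dataclasses.field(default_factory=lambda: {
        "standard": "iec", "wavelength_nm": 785.0, "aperture_mm": 3.5,
    })
    seed: int = 0

    _KEYS = ("optics", "geometry", "scheme", "noise", "fit", "safety", "seed")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(RunConfig._KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    for key, value in raw.items():
        if isinstance(value, dict):
            getattr(cfg, key).update(value)
        else:
            setattr(cfg, key, value)
    return cfg


def save_config(path: Union[str, Path], cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
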