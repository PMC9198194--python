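"""Spherical conversion, magnitude remapping, quantization, and the four VTIs.

A 3-vector field (the gradient, or the sorted Hessian eigenvalue triple) is
expressed per voxel as (magnitude, azimuth, polar):

    magnitude = sqrt(vx^2 + vy^2 + vz^2)
    azimuth   = acos(vx / sqrt(vx^2 + vy^2))        if vy >= 0
              = pi + acos(vx / sqrt(vx^2 + vy^2))   if vy <  0
    polar     = acos(vz / magnitude)

so azimuth lies in [0, 2*pi] and polar in [0, pi]. Degenerate voxels follow a
fixed convention: vx = vy = 0 gives azimuth 0; zero magnitude gives polar 0.

Magnitudes are heavy-tailed (edge responses dominate), so before uniform
min-max quantization they pass through a t-th root map, which compresses the
tail while preserving ranks. Angles are quantized into equal fixed bins of
their period; magnitudes are min-max scaled over ROI voxels only.

The four vector texture images (VTIs):

    GAV = (quantized azimuth, quantized polar)                 gradient domain
    TGV = (quantized magnitude, azimuth, polar)                gradient domain
    HAV = (quantized azimuth, quantized polar)                 Hessian domain
    THV = (quantized magnitude, azimuth, polar)                Hessian domain
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import ROIMask

VTI_KINDS = ("GAV", "TGV", "HAV", "THV")

#: Kinds carrying a magnitude channel.
MAGNITUDE_KINDS = ("TGV", "THV")

#: Kinds built from the gradient field (vs the Hessian eigenvalue field).
GRADIENT_KINDS = ("GAV", "TGV")

_ANGLE_TOL = 1e-9


@dataclass
class SphericalField:
    magnitude: np.ndarray
    azimuth: np.ndarray
    polar: np.ndarray


@dataclass
class QuantConfig:
    """Quantization parameters for one VTI kind.

    t_root : magnitude root exponent (1 = identity)
    q_mag, q_azimuth, q_polar : level counts per channel
    """

    t_root: int = 1
    q_mag: int = 1
    q_azimuth: int = 8
    q_polar: int = 4

    def __post_init__(self) -> None:
        for name in ("t_root", "q_mag", "q_azimuth", "q_polar"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
            setattr(self, name, int(v))

    def to_dict(self) -> dict:
        return {"t_root": self.t_root, "q_mag": self.q_mag,
                "q_azimuth": self.q_azimuth, "q_polar": self.q_polar}


#: Default quantization per kind: the best-performing settings of the
#: parameter study (GAV 10x5, TGV 2x10x4, HAV 5x8, THV 5x3x8; t=2 for the
#: gradient domain, t=4 for the Hessian domain).
DEFAULT_CONFIGS: dict[str, QuantConfig] = {
    "GAV": QuantConfig(t_root=2, q_mag=1, q_azimuth=10, q_polar=5),
    "TGV": QuantConfig(t_root=2, q_mag=2, q_azimuth=10, q_polar=4),
    "HAV": QuantConfig(t_root=4, q_mag=1, q_azimuth=5, q_polar=8),
    "THV": QuantConfig(t_root=4, q_mag=5, q_azimuth=3, q_polar=8),
}


@dataclass
class VTI:
    """A vector texture image: 2 or 3 congruent integer channel grids."""

    kind: str
    channels: list[np.ndarray]
    levels: list[int]

    def __post_init__(self) -> None:
        if self.kind not in VTI_KINDS:
            raise ValueError(f"unknown VTI kind {self.kind!r}")
        expected = 3 if self.kind in MAGNITUDE_KINDS else 2
        if len(self.channels) != expected or len(self.levels) != expected:
            raise ValueError(
                f"{self.kind} needs {expected} channels, got {len(self.channels)}"
            )
        for ch, lv in zip(self.channels, self.levels):
            if ch.min() < 0 or ch.max() >= lv:
                raise ValueError("channel values outside [0, levels-1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def n_states(self) -> int:
        return int(np.prod(self.levels))


def to_spherical(vx: np.ndarray, vy: np.ndarray, vz: np.ndarray) -> SphericalField:
    """Convert a 3-vector field to (magnitude, azimuth, polar).

    Never raises on degenerate voxels: azimuth 0 where vx = vy = 0, polar 0
    where the magnitude is 0.
    """
    vx = np.asarray(vx, dtype=np.float64)
    vy = np.asarray(vy, dtype=np.float64)
    vz = np.asarray(vz, dtype=np.float64)
    if not (vx.shape == vy.shape == vz.shape):
        raise ValueError("component grids must be congruent")

    magnitude = np.sqrt(vx * vx + vy * vy + vz * vz)
    hyp = np.hypot(vx, vy)

    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.arccos(np.clip(np.where(hyp > 0, vx / np.where(hyp > 0, hyp, 1.0),
                                          1.0), -1.0, 1.0))
        polar = np.arccos(np.clip(np.where(magnitude > 0,
                                           vz / np.where(magnitude > 0, magnitude, 1.0),
                                           1.0), -1.0, 1.0))
    azimuth = np.where(vy >= 0, base, np.pi + base)
    azimuth = np.where(hyp > 0, azimuth, 0.0)
    return SphericalField(magnitude=magnitude, azimuth=azimuth, polar=polar)


def root_remap(magnitude: np.ndarray, t_root: int) -> np.ndarray:
    """Elementwise t-th root; strictly monotone, hence rank-preserving."""
    if int(t_root) != t_root or t_root < 1:
        raise ValueError(f"t_root must be an integer >= 1, got {t_root}")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if magnitude.min() < 0:
        raise ValueError("magnitudes must be non-negative")
    if t_root == 1:
        return magnitude.copy()
    return np.power(magnitude, 1.0 / t_root)


def quantize_angle(angle: np.ndarray, levels: int, period: float) -> np.ndarray:
    """Quantize angles into ``levels`` equal bins of [0, period).

    ``angle == period`` maps to the top bin ``levels - 1`` (the boundary
    branch); values outside [0, period] beyond a 1e-9 tolerance raise.
    """
    if int(levels) != levels or levels < 1:
        raise ValueError(f"levels must be a positive integer, got {levels}")
    angle = np.asarray(angle, dtype=np.float64)
    if angle.min() < -_ANGLE_TOL or angle.max() > period + _ANGLE_TOL:
        raise ValueError(
            f"angles outside [0, {period}] (min {angle.min()}, max {angle.max()})"
        )
    clipped = np.clip(angle, 0.0, period)
    q = np.floor(levels * clipped / period).astype(np.int64)
    np.minimum(q, levels - 1, out=q)  # boundary branch: angle == period
    return q


def quantize_magnitude(remapped: np.ndarray, levels: int, roi: ROIMask) -> np.ndarray:
    """Uniform min-max quantization with statistics from ROI voxels only.

    ``v == max`` maps to ``levels - 1``; a constant ROI quantizes to all
    zeros (degenerate contract, not an error). Voxels outside the ROI are
    quantized with the same affine map and clipped into range.
    """
    if int(levels) != levels or levels < 1:
        raise ValueError(f"levels must be a positive integer, got {levels}")
    remapped = np.asarray(remapped, dtype=np.float64)
    if remapped.shape != roi.mask.shape:
        raise ValueError("grid and ROI mask must be congruent")
    inside = remapped[roi.mask]
    lo, hi = float(inside.min()), float(inside.max())
    if hi == lo:
        return np.zeros(remapped.shape, dtype=np.int64)
    q = np.floor((remapped - lo) * levels / (hi - lo)).astype(np.int64)
    np.clip(q, 0, levels - 1, out=q)
    return q


def build_vti(kind: str, spherical: SphericalField, cfg: QuantConfig,
              roi: ROIMask) -> VTI:
    """Assemble one VTI from a spherical field.

    Angle-only kinds (GAV, HAV) carry (azimuth, polar); full-vector kinds
    (TGV, THV) prepend the root-remapped, min-max quantized magnitude.
    """
    if kind not in VTI_KINDS:
        raise ValueError(f"unknown VTI kind {kind!r}")
    az = quantize_angle(spherical.azimuth, cfg.q_azimuth, 2.0 * np.pi)
    pol = quantize_angle(spherical.polar, cfg.q_polar, np.pi)
    if kind in MAGNITUDE_KINDS:
        mag = quantize_magnitude(root_remap(spherical.magnitude, cfg.t_root),
                                 cfg.q_mag, roi)
        return VTI(kind=kind, channels=[mag, az, pol],
                   levels=[cfg.q_mag, cfg.q_azimuth, cfg.q_polar])
    return VTI(kind=kind, channels=[az, pol],
               levels=[cfg.q_azimuth, cfg.q_polar])
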