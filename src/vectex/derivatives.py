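"""First- and second-order derivative fields and Hessian eigenvalues.

First-order partials use the separable 3D Sobel operator (difference kernel
[-1, 0, 1] on the derivative axis, smoothing kernel [1, 2, 1] on the two
transverse axes). Second-order partials use Deriche's exponential-family
smoothing/derivative filters at scale ``alpha``; the per-voxel 3x3 symmetric
Hessian is then diagonalised and its eigenvalues sorted descending by signed
value, lambda1 >= lambda2 >= lambda3.

Boundary handling is edge replication throughout, so a constant volume has
identically zero derivatives everywhere including the border.

Axis convention: axis 0 = x (rows r), axis 1 = y (columns c),
axis 2 = z (slices s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume


@dataclass
class GradientField:
    """Per-voxel first partial derivatives (dx, dy, dz)."""

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.dx, self.dy, self.dz


@dataclass
class HessianField:
    """Unique entries of the per-voxel symmetric second-derivative matrix."""

    ixx: np.ndarray
    iyy: np.ndarray
    izz: np.ndarray
    ixy: np.ndarray
    ixz: np.ndarray
    iyz: np.ndarray


@dataclass
class EigenField:
    """Sorted Hessian eigenvalues, l1 >= l2 >= l3 at every voxel."""

    l1: np.ndarray
    l2: np.ndarray
    l3: np.ndarray

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.l1, self.l2, self.l3


def sobel_gradient(volume: Volume) -> GradientField:
    """3D Sobel partial derivatives with edge-replication boundaries."""
    data = volume.data
    parts = [ndimage.sobel(data, axis=ax, mode="nearest") for ax in (0, 1, 2)]
    return GradientField(dx=parts[0], dy=parts[1], dz=parts[2])


# ---------------------------------------------------------------------------
# Deriche exponential filters
#
# The continuous impulse responses of the Deriche family at scale alpha:
#   smoothing          s(x)  = (1 + alpha|x|) e^{-alpha|x|}       (even)
#   first derivative   s'(x) = -alpha^2 x e^{-alpha|x|}           (odd)
#   second derivative  s''(x)= alpha^2 (alpha|x| - 1) e^{-alpha|x|} (even)
# They are sampled at integer taps out to where the envelope is < 1e-12 and
# renormalised discretely: the smoother to unit DC gain, the first derivative
# to unit response on a unit ramp, the second derivative to zero DC gain
# (exactly, via the centre tap) and exact second difference on a quadratic.
# At these truncation radii the sampled kernels agree with the recursive IIR
# realisation to machine precision.

def _deriche_kernels(alpha: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    radius = max(int(np.ceil(-np.log(1e-12) / alpha)), 4)
    n = np.arange(-radius, radius + 1, dtype=np.float64)
    env = np.exp(-alpha * np.abs(n))

    smooth = (1.0 + alpha * np.abs(n)) * env
    smooth /= smooth.sum()

    deriv1 = n * env
    deriv1 /= np.sum(n * deriv1)  # correlate response to ramp x[n]=n is 1

    deriv2 = (alpha * np.abs(n) - 1.0) * env
    deriv2[radius] -= deriv2.sum()          # exact zero DC gain
    deriv2 *= 2.0 / np.sum(n * n * deriv2)  # response to x[n]=n^2 is 2
    return smooth, deriv1, deriv2


def deriche_second_derivatives(volume: Volume, alpha: float = 1.0) -> HessianField:
    """Six second-order partials by separable Deriche filtering.

    Pure second derivatives apply the second-derivative kernel on their axis
    and smoothing on the other two; mixed partials apply the first-derivative
    kernel on each of their two axes and smoothing on the third.
    """
    smooth, d1, d2 = _deriche_kernels(alpha)
    data = volume.data

    def separable(kernels: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
        out = data
        for ax, k in enumerate(kernels):
            out = ndimage.correlate1d(out, k, axis=ax, mode="nearest")
        return out

    return HessianField(
        ixx=separable((d2, smooth, smooth)),
        iyy=separable((smooth, d2, smooth)),
        izz=separable((smooth, smooth, d2)),
        ixy=separable((d1, d1, smooth)),
        ixz=separable((d1, smooth, d1)),
        iyz=separable((smooth, d1, d1)),
    )


def hessian_eigenvalues(h: HessianField) -> EigenField:
    """Per-voxel eigenvalues of the symmetric 3x3 Hessian, sorted descending.

    Real symmetric matrices always have three real eigenvalues; sorting is by
    signed value, not magnitude.
    """
    shape = h.ixx.shape
    mats = np.empty(shape + (3, 3), dtype=np.float64)
    mats[..., 0, 0] = h.ixx
    mats[..., 1, 1] = h.iyy
    mats[..., 2, 2] = h.izz
    mats[..., 0, 1] = mats[..., 1, 0] = h.ixy
    mats[..., 0, 2] = mats[..., 2, 0] = h.ixz
    mats[..., 1, 2] = mats[..., 2, 1] = h.iyz
    vals = np.linalg.eigvalsh(mats)  # ascending
    return EigenField(l1=vals[..., 2], l2=vals[..., 1], l3=vals[..., 0])
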