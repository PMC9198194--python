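"""Volume and ROI-mask I/O plus the air-threshold preprocessing step.

Volumes are 3D scalar grids indexed ``(r, c, s)`` (row, column, slice),
0-based. CT volumes carry intensities in Hounsfield units (HU); the air
threshold removes lumen-air voxels (HU well below soft tissue) from the
region of interest before any co-occurrence statistics are accumulated,
while the full volume stays available to the derivative kernels so that
ROI-border voxels see their true neighbours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Default exclusion threshold for colonic lumen air, in HU.
DEFAULT_AIR_THRESHOLD_HU = -450.0


class DimensionError(ValueError):
    """A volume axis is too short for the 3x3x3 derivative kernels."""


class CongruenceError(ValueError):
    """Mask and volume shapes disagree."""


class EmptyROIError(ValueError):
    """An operation produced or received a mask with no true voxel."""


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray
        3D array indexed ``(r, c, s)``. Converted to float64.
    spacing : tuple of float
        Physical voxel size per axis in mm.
    intensity_units : str
        Label such as ``"HU"`` or ``"arbitrary"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    intensity_units: str = "arbitrary"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 3:
            raise DimensionError(
                f"every axis needs >= 3 voxels (derivative kernels need a "
                f"1-voxel margin); got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ROIMask:
    """Binary region-of-interest mask congruent with its volume."""

    mask: np.ndarray
    threshold_hu: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionError(f"mask must be 3D, got ndim={self.mask.ndim}")
        if not self.mask.any():
            raise EmptyROIError("ROI mask has no true voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, intensity_units="HU")


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine from its spacing."""
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))


def read_mask(path: str | Path) -> ROIMask:
    """Read a NIfTI mask; any strictly positive voxel counts as inside."""
    vol = read_volume(path)
    return ROIMask(mask=vol.data > 0.5)


def write_mask(mask: ROIMask, path: str | Path,
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(path))


def apply_air_threshold(volume: Volume, mask: ROIMask,
                        threshold: float = DEFAULT_AIR_THRESHOLD_HU) -> ROIMask:
    """Drop ROI voxels whose intensity falls below ``threshold``.

    Voxels below the threshold (lumen air, for the CT colonography use case)
    leave the ROI but remain in the volume, so derivative kernels at the ROI
    border still see the true surrounding intensities.

    Returns a new :class:`ROIMask`; the input is not modified. Idempotent,
    and the output true-set is always a subset of the input true-set.
    """
    if mask.mask.shape != volume.data.shape:
        raise CongruenceError(
            f"mask shape {mask.mask.shape} != volume shape {volume.data.shape}"
        )
    kept = mask.mask & (volume.data >= threshold)
    if not kept.any():
        raise EmptyROIError(
            f"no ROI voxel at or above threshold {threshold}"
        )
    return ROIMask(mask=kept, threshold_hu=float(threshold))


# ---------------------------------------------------------------------------
# feature-table persistence

def write_features_wide(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wide feature table (one row per lesion, named columns)."""
    table.to_csv(path, index=False, lineterminator="\n")


def write_features_long(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long format: lesion_id,direction,measure,value."""
    value_cols = [c for c in table.columns if "__" in c]
    records = []
    for _, row in table.iterrows():
        for col in value_cols:
            direction, measure = col.split("__", 1)
            records.append((row["lesion_id"], direction, measure, row[col]))
    long = pd.DataFrame(records,
                        columns=["lesion_id", "direction", "measure", "value"])
    long.to_csv(path, index=False, lineterminator="\n")


def write_sidecar(params: dict, path: str | Path) -> None:
    """Persist run parameters (quantization, seeds, ...) as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
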