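"""Synthetic phantom lesions with controllable texture statistics.

The private CT colonography cohort behind the method is not redistributable,
so testing and demonstration run on phantoms: a spherical "lesion" of
correlated Gaussian texture embedded in an air-valued background (about
-1000 HU, i.e. colonic lumen). The two classes differ in their noise
correlation length and contrast amplitude, which changes the gradient and
Hessian statistics inside the lesion — the same axis of heterogeneity the
vector textures are designed to pick up. Intensities span a CT-like range so
the -450 HU air-threshold path is exercised realistically.

Texture model per lesion: base soft-tissue value + coarse heterogeneity
(Gaussian-smoothed noise at ``heterogeneity_scale``) + fine texture
(Gaussian-smoothed noise at ``correlation_length``, scaled to
``contrast_amplitude`` HU standard deviation). Deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .vcm import CANONICAL_DIRECTIONS, canonical_directions, state_index
from .volume_io import ROIMask, Volume


@dataclass
class TextureParams:
    """Per-class texture statistics (units: voxels and HU)."""

    correlation_length: float   # smoothing sigma of the fine texture, voxels
    contrast_amplitude: float   # SD of the fine texture, HU
    heterogeneity_scale: float  # smoothing sigma of the coarse component, voxels

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.contrast_amplitude < 0 or self.heterogeneity_scale <= 0:
            raise ValueError("invalid texture parameters")


#: Default class conditions: benign lesions (label 0) with short-range,
#: lower-contrast texture; malignant (label 1) with longer-range,
#: higher-contrast texture.
CLASS_PARAMS: dict[int, TextureParams] = {
    0: TextureParams(correlation_length=1.0, contrast_amplitude=80.0,
                     heterogeneity_scale=4.0),
    1: TextureParams(correlation_length=2.2, contrast_amplitude=120.0,
                     heterogeneity_scale=6.0),
}

#: Base soft-tissue intensity of the lesion interior, HU.
TISSUE_VALUE = 30.0


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom deterministically."""

    shape: tuple[int, int, int] = (32, 32, 32)
    class_label: int = 0
    texture_params: TextureParams | None = None
    background_value: float = -1000.0
    lesion_radius: float = 11.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")
        if self.texture_params is None:
            self.texture_params = CLASS_PARAMS[self.class_label]
        margin = min(self.shape) / 2.0 - self.lesion_radius
        if margin < 2.0:
            raise ValueError(
                f"lesion radius {self.lesion_radius} leaves a margin of "
                f"{margin:.1f} voxels; need >= 2")


def make_phantom(spec: PhantomSpec) -> tuple[Volume, ROIMask]:
    """A spherical textured lesion in an air background; ROI = the sphere."""
    rng = np.random.default_rng(spec.seed)
    tp = spec.texture_params
    shape = tuple(spec.shape)

    center = (np.array(shape) - 1) / 2.0
    grids = np.indices(shape, dtype=np.float64)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    sphere = dist2 <= spec.lesion_radius ** 2

    def correlated(sigma: float) -> np.ndarray:
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
        sd = noise.std()
        return noise / sd if sd > 0 else noise

    coarse = correlated(tp.heterogeneity_scale) * (0.5 * tp.contrast_amplitude)
    fine = correlated(tp.correlation_length) * tp.contrast_amplitude
    tissue = TISSUE_VALUE + coarse + fine

    data = np.where(sphere, tissue, spec.background_value)
    return (Volume(data=data, spacing=(1.0, 1.0, 1.0), intensity_units="HU"),
            ROIMask(mask=sphere))


def make_cohort(n_per_class: int, base_spec: PhantomSpec | None = None,
                seed: int = 0, jitter: float = 0.10
                ) -> list[tuple[Volume, ROIMask, int]]:
    """A balanced cohort of 2*n_per_class phantoms with jittered parameters.

    Each lesion's correlation length and contrast amplitude are jittered
    multiplicatively by up to +/- ``jitter`` around its class values, to
    emulate within-class biological variability.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    cohort = []
    for label in (0, 1):
        params = CLASS_PARAMS[label]
        for _ in range(n_per_class):
            tp = TextureParams(
                correlation_length=params.correlation_length
                * float(rng.uniform(1 - jitter, 1 + jitter)),
                contrast_amplitude=params.contrast_amplitude
                * float(rng.uniform(1 - jitter, 1 + jitter)),
                heterogeneity_scale=params.heterogeneity_scale,
            )
            spec = replace(base_spec, class_label=label, texture_params=tp,
                           seed=int(rng.integers(0, 2 ** 31)))
            volume, roi = make_phantom(spec)
            cohort.append((volume, roi, label))
    return cohort


def make_null_cohort(n_per_class: int, seed: int = 0,
                     base_spec: PhantomSpec | None = None
                     ) -> list[tuple[Volume, ROIMask, int]]:
    """A cohort whose two label groups share identical texture statistics.

    Both classes are generated from the class-0 parameters, so any apparent
    discrimination is selection/overfitting artefact — the null condition.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    params = CLASS_PARAMS[0]
    cohort = []
    for label in (0, 1):
        for _ in range(n_per_class):
            tp = TextureParams(
                correlation_length=params.correlation_length
                * float(rng.uniform(0.9, 1.1)),
                contrast_amplitude=params.contrast_amplitude
                * float(rng.uniform(0.9, 1.1)),
                heterogeneity_scale=params.heterogeneity_scale,
            )
            spec = replace(base_spec, class_label=label, texture_params=tp,
                           seed=int(rng.integers(0, 2 ** 31)))
            volume, roi = make_phantom(spec)
            cohort.append((volume, roi, label))
    return cohort


# ---------------------------------------------------------------------------
# tiny worked-example fixtures with exhaustively enumerated expected VCMs

def _brute_force_vcm(channels: list[np.ndarray], levels: list[int],
                     roi: np.ndarray, offset: tuple[int, int, int],
                     d: int = 1) -> np.ndarray:
    """Naive triple-loop pair enumeration (pre-symmetrization)."""
    shape = channels[0].shape
    n_states = int(np.prod(levels))
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    step = tuple(d * o for o in offset)
    for r in range(shape[0]):
        for c in range(shape[1]):
            for s in range(shape[2]):
                if not roi[r, c, s]:
                    continue
                r2, c2, s2 = r + step[0], c + step[1], s + step[2]
                if not (0 <= r2 < shape[0] and 0 <= c2 < shape[1]
                        and 0 <= s2 < shape[2]):
                    continue
                if not roi[r2, c2, s2]:
                    continue
                v1 = state_index(tuple(int(ch[r, c, s]) for ch in channels),
                                 tuple(levels))
                v2 = state_index(tuple(int(ch[r2, c2, s2]) for ch in channels),
                                 tuple(levels))
                counts[v1, v2] += 1
    return counts


def worked_example_fixtures() -> dict:
    """Tiny hand-checkable VTI fixtures plus their enumerated VCMs.

    Returns a dict of named fixtures; each holds the channel grids, levels,
    full ROI, and for every canonical direction the brute-force VCM (both
    raw and symmetrized). Everything regenerates bit-identically.
    """
    fixtures: dict[str, dict] = {}

    # 2x2x1 two-state example: states [[0, 1], [1, 1]] in (r, c) layout
    grid = np.array([[0, 1], [1, 1]], dtype=np.int64).reshape(2, 2, 1)
    fixtures["two_by_two"] = _fixture([grid], [2])

    # 4x4x4 constant single-state example
    fixtures["constant_4cube"] = _fixture(
        [np.zeros((4, 4, 4), dtype=np.int64)], [1])

    # 3x3x3 deterministic two-channel example (levels 2 x 3)
    rng = np.random.default_rng(20220614)
    ch0 = rng.integers(0, 2, size=(3, 3, 3))
    ch1 = rng.integers(0, 3, size=(3, 3, 3))
    fixtures["mixed_3cube"] = _fixture([ch0, ch1], [2, 3])
    return fixtures


def _fixture(channels: list[np.ndarray], levels: list[int]) -> dict:
    roi = np.ones(channels[0].shape, dtype=bool)
    vcms = {}
    for off in CANONICAL_DIRECTIONS:
        raw = _brute_force_vcm(channels, levels, roi, off, d=1)
        vcms[off] = {"raw": raw, "symmetrized": raw + raw.T}
    return {"channels": [c.copy() for c in channels], "levels": list(levels),
            "roi": roi, "vcms": vcms}
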