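"""Vector co-occurrence matrices (VCMs) over quantized vector texture images.

A VCM generalizes the gray-level co-occurrence matrix: instead of pairing
scalar gray levels, it pairs quantized *vector states* (the 2- or 3-tuple of
VTI channel values, flattened to a single index) of voxels separated by a
displacement ``d`` along one of 13 canonical lattice directions. The 26
nearest-neighbour offsets split into 13 +/- pairs; opposite offsets give the
transposed matrix, so only one of each pair is accumulated and the matrix is
then symmetrized (counts + counts^T), the standard Haralick convention.

Both endpoints of a pair must lie inside the (post-threshold) ROI; partners
falling outside the grid are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .vector_fields import VTI
from .volume_io import ROIMask

#: The 13 canonical directions, in order. Together with their negations they
#: cover all 26 nearest-neighbour offsets; no entry is the negation of
#: another.
CANONICAL_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (1, 0, 1), (1, 1, 0),
    (-1, 1, 0), (0, 1, -1), (1, 0, -1),
    (1, 1, 1), (-1, 1, 1), (1, 1, -1), (-1, 1, -1),
)


@dataclass(frozen=True)
class Direction:
    """An integer lattice offset with components in {-1, 0, 1}."""

    offset: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.offset not in CANONICAL_DIRECTIONS:
            raise ValueError(f"{self.offset} is not a canonical direction")

    @property
    def name(self) -> str:
        return "d" + "_".join("m1" if v == -1 else str(v) for v in self.offset)


def canonical_directions() -> list[Direction]:
    """The 13 canonical VCM directions, in canonical order."""
    return [Direction(off) for off in CANONICAL_DIRECTIONS]


def state_index(values: tuple[int, ...], levels: tuple[int, ...]) -> int:
    """Mixed-radix state index, channel 0 most significant; bijective."""
    if len(values) != len(levels):
        raise ValueError("values and levels must have equal length")
    idx = 0
    for v, lv in zip(values, levels):
        if not 0 <= v < lv:
            raise ValueError(f"value {v} outside [0, {lv - 1}]")
        idx = idx * lv + v
    return idx


def state_unindex(idx: int, levels: tuple[int, ...]) -> tuple[int, ...]:
    """Inverse of :func:`state_index`."""
    out = []
    for lv in reversed(levels):
        out.append(idx % lv)
        idx //= lv
    if idx != 0:
        raise ValueError("index out of range for the given levels")
    return tuple(reversed(out))


def _state_grid(vti: VTI) -> np.ndarray:
    state = np.zeros(vti.shape, dtype=np.int64)
    for ch, lv in zip(vti.channels, vti.levels):
        state = state * lv + ch
    return state


@dataclass
class VCMatrix:
    """Co-occurrence counts over vector states for one direction.

    ``counts`` is symmetrized (raw + raw^T) unless built with
    ``symmetrize=False``; ``n_pairs`` is the number of admissible ordered
    anchor->partner pairs before symmetrization.
    """

    counts: np.ndarray
    direction: Direction
    displacement: int
    state_levels: tuple[int, ...]
    symmetrized: bool
    n_pairs: int


def _shift_slices(shape: tuple[int, int, int], step: tuple[int, int, int]):
    """Slices selecting anchors and their in-grid partners at offset step."""
    src, dst = [], []
    for size, s in zip(shape, step):
        if s >= 0:
            src.append(slice(0, size - s))
            dst.append(slice(s, size))
        else:
            src.append(slice(-s, size))
            dst.append(slice(0, size + s))
    return tuple(src), tuple(dst)


def compute_vcm(vti: VTI, roi: ROIMask, direction: Direction, d: int = 1,
                symmetrize: bool = True) -> VCMatrix:
    """Accumulate the VCM for one direction and displacement.

    For every voxel p with p and p + d*offset both inside the grid and the
    ROI, ``counts[state(p), state(p + d*offset)]`` is incremented; the matrix
    is then symmetrized by adding its transpose (unless disabled).
    """
    if d < 1:
        raise ValueError(f"displacement must be >= 1, got {d}")
    if vti.shape != roi.mask.shape:
        raise ValueError("VTI and ROI mask must be congruent")
    step = tuple(d * o for o in direction.offset)
    n_states = vti.n_states
    state = _state_grid(vti)
    src, dst = _shift_slices(vti.shape, step)

    admissible = roi.mask[src] & roi.mask[dst]
    a = state[src][admissible]
    b = state[dst][admissible]
    n_pairs = int(a.size)
    if n_pairs == 0:
        warnings.warn(
            f"no admissible voxel pair for direction {direction.offset} "
            f"at displacement {d}; VCM is all zero",
            RuntimeWarning, stacklevel=2,
        )
    counts = np.bincount(a * n_states + b,
                         minlength=n_states * n_states).reshape(n_states, n_states)
    if symmetrize:
        counts = counts + counts.T
    return VCMatrix(counts=counts.astype(np.int64), direction=direction,
                    displacement=d, state_levels=tuple(vti.levels),
                    symmetrized=symmetrize, n_pairs=n_pairs)


@dataclass
class VCMStack:
    """The 13 VCMs of one lesion, in canonical direction order."""

    matrices: list[VCMatrix]

    def __post_init__(self) -> None:
        if len(self.matrices) != len(CANONICAL_DIRECTIONS):
            raise ValueError("a VCM stack holds exactly 13 matrices")
        for m, off in zip(self.matrices, CANONICAL_DIRECTIONS):
            if m.direction.offset != off:
                raise ValueError("matrices out of canonical direction order")


def compute_vcm_stack(vti: VTI, roi: ROIMask, d: int = 1,
                      symmetrize: bool = True) -> VCMStack:
    """One VCM per canonical direction, in canonical order."""
    return VCMStack(matrices=[
        compute_vcm(vti, roi, direction, d=d, symmetrize=symmetrize)
        for direction in canonical_directions()
    ])


def write_vcm_text(m: VCMatrix, path) -> None:
    """Dump one VCM as plain text with a descriptive header."""
    header = (f"direction={m.direction.offset} d={m.displacement} "
              f"state_levels={m.state_levels} symmetrized={m.symmetrized} "
              f"n_pairs={m.n_pairs}")
    np.savetxt(path, m.counts, fmt="%d", header=header)
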