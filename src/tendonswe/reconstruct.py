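"""Forward-splatting compounding of pose-tagged 2D frames into 3D voxel volumes.

Every valid pixel of every frame is projected into world coordinates through
its frame pose and deposits ``(weight * value, weight)`` into nearby voxels,
with a Gaussian weight in pixel-to-voxel-center distance (sigma = voxel
spacing by default, truncated at ``trunc * sigma``).  A voxel's final value is
the weighted mean of its deposits; voxels that received (numerically) no
weight are undefined and stay undefined — no hole filling.

Coordinates are right-handed world mm; the voxel grid is indexed (x, y, z)
with the grid origin at the center of voxel (0, 0, 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .phantom import SweepFrame

__all__ = [
    "VoxelGridSpec",
    "VoxelVolume",
    "KernelConfig",
    "pixel_world_positions",
    "compound",
    "finalize",
]

#: Weight below which a voxel counts as undefined.
WEIGHT_EPS = 1e-12


@dataclass(frozen=True)
class VoxelGridSpec:
    """Regular 3D grid: ``center(i,j,k) = origin + (i,j,k) * spacing`` (mm)."""

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        dims = tuple(int(d) for d in self.dims)
        if origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if np.any(spacing <= 0):
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in dims):
            raise ValueError("dims must be >= 1 per axis")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "dims", dims)

    @classmethod
    def bounding(cls, points: np.ndarray, spacing: float | Sequence[float],
                 pad_mm: float = 1.0) -> "VoxelGridSpec":
        """Smallest grid (plus padding) covering the given world points."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        sp = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        lo = pts.min(axis=0) - pad_mm
        hi = pts.max(axis=0) + pad_mm
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / sp[i])) + 1 for i in range(3))
        return cls(origin=lo, spacing=sp, dims=dims)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape dims + (3,)."""
        axes = [self.origin[i] + np.arange(self.dims[i]) * self.spacing[i]
                for i in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class VoxelVolume:
    """Voxel grid with value and accumulated-weight arrays.

    Before :func:`finalize`, ``values`` holds the weighted sum of deposits;
    after, it holds the weighted mean where ``weights > WEIGHT_EPS`` and NaN
    (undefined) elsewhere.
    """

    spec: VoxelGridSpec
    values: np.ndarray
    weights: np.ndarray
    finalized: bool = False

    def __post_init__(self):
        if self.values.shape != self.spec.dims or self.weights.shape != self.spec.dims:
            raise ValueError("values/weights shape must match spec dims")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    @classmethod
    def empty(cls, spec: VoxelGridSpec) -> "VoxelVolume":
        return cls(spec=spec, values=np.zeros(spec.dims),
                   weights=np.zeros(spec.dims))

    @property
    def defined(self) -> np.ndarray:
        """Boolean grid of voxels that received weight."""
        return self.weights > WEIGHT_EPS

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(spec=self.spec, values=self.values.copy(),
                           weights=self.weights.copy(), finalized=self.finalized)


@dataclass(frozen=True)
class KernelConfig:
    """Gaussian splatting kernel: ``w = exp(-d^2 / (2 sigma^2))`` for
    pixel-to-voxel-center distance d up to ``trunc * sigma``; sigma defaults
    to the (mean) voxel spacing."""

    sigma: float | None = None
    trunc: float = 2.0

    def resolve_sigma(self, spec: VoxelGridSpec) -> float:
        s = self.sigma if self.sigma is not None else float(np.mean(spec.spacing))
        if s <= 0:
            raise ValueError("kernel sigma must be positive")
        return s


def pixel_world_positions(frame: SweepFrame) -> np.ndarray:
    """World position of every pixel center, shape (rows, cols, 3).

    Pixel (r, c) sits at frame coordinate ``(c * spacing, r * spacing, 0)``
    (pixel-center convention) and is mapped by the frame pose.
    """
    rows, cols = frame.shape
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([c * frame.pixel_spacing, r * frame.pixel_spacing,
                       np.zeros_like(c, dtype=float)], axis=-1)
    return frame.pose.apply(coords.reshape(-1, 3)).reshape(rows, cols, 3)


def _splat(points: np.ndarray, values: np.ndarray, spec: VoxelGridSpec,
           sigma: float, trunc: float,
           acc_wv: np.ndarray, acc_w: np.ndarray) -> None:
    """Deposit (w*v, w) from each point into voxels within the truncation
    radius, accumulating in-place on flattened accumulator views."""
    if points.size == 0:
        return
    radius = trunc * sigma
    f = (points - spec.origin) / spec.spacing  # fractional voxel index
    reach = np.ceil(radius / spec.spacing).astype(int)
    base = np.floor(f).astype(int)
    dims = np.array(spec.dims)
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    wv_flat = acc_wv.reshape(-1)
    w_flat = acc_w.reshape(-1)
    r2 = radius * radius
    offsets = np.stack(np.meshgrid(
        np.arange(-reach[0], reach[0] + 1),
        np.arange(-reach[1], reach[1] + 1),
        np.arange(-reach[2], reach[2] + 1), indexing="ij"), axis=-1).reshape(-1, 3)
    for off in offsets:
        idx = base + off
        inb = np.all((idx >= 0) & (idx < dims), axis=1)
        if not inb.any():
            continue
        d = (idx - f) * spec.spacing
        d2 = np.einsum("ij,ij->i", d, d)
        sel = inb & (d2 <= r2)
        if not sel.any():
            continue
        w = np.exp(-0.5 * d2[sel] / (sigma * sigma))
        flat = idx[sel] @ strides
        np.add.at(wv_flat, flat, w * values[sel])
        np.add.at(w_flat, flat, w)


def compound(frames: Iterable[SweepFrame], spec: VoxelGridSpec,
             kernel: KernelConfig | None = None,
             ) -> tuple[VoxelVolume, VoxelVolume]:
    """Compound a sweep into SWE and B-mode voxel volumes.

    Invalid SWV pixels (NaN) carry zero weight for the SWE volume but still
    contribute to the B-mode volume.  The result is invariant (up to
    floating-point associativity) to the frame order.

    Returns finalized ``(swe, bmode)`` volumes; warns ``"no overlap"`` if no
    pixel fell inside the grid.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame list")
    kernel = kernel or KernelConfig()
    sigma = kernel.resolve_sigma(spec)

    swe = VoxelVolume.empty(spec)
    bmode = VoxelVolume.empty(spec)
    for frame in frames:
        pts = pixel_world_positions(frame).reshape(-1, 3)
        swv = frame.swv.reshape(-1)
        bm = frame.bmode.reshape(-1)
        valid = np.isfinite(swv)
        _splat(pts[valid], swv[valid], spec, sigma, kernel.trunc,
               swe.values, swe.weights)
        _splat(pts, bm, spec, sigma, kernel.trunc, bmode.values, bmode.weights)
    if not bmode.defined.any():
        warnings.warn("no overlap: no pixel deposited into the voxel grid",
                      stacklevel=2)
    return finalize(swe), finalize(bmode)


def finalize(volume: VoxelVolume) -> VoxelVolume:
    """Normalize accumulated sums into weighted means; idempotent.

    Voxels with accumulated weight <= ``WEIGHT_EPS`` become NaN (undefined)
    and are excluded from all downstream statistics.
    """
    if volume.finalized:
        return volume
    defined = volume.weights > WEIGHT_EPS
    values = np.full(volume.spec.dims, np.nan)
    values[defined] = volume.values[defined] / volume.weights[defined]
    return VoxelVolume(spec=volume.spec, values=values,
                       weights=volume.weights.copy(), finalized=True)
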