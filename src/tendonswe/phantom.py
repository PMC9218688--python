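"""Digital patellar-tendon phantom and freehand pose-tracked SWE sweep simulation.

The phantom is a tendon-shaped solid — an elliptical-cross-section tube around a
straight (optionally gently bowed) centerline between the two insertion
landmarks — carrying a piecewise-constant shear-wave-velocity (SWV) field with
distinct proximal / mid-portion / distal values.  Regions are separated by cuts
at ``cut_distance`` (10 mm by default) from each insertion, the same geometry
used downstream for regional analysis.

``simulate_sweep`` emulates a tracked handheld scan: a sequence of 2D frames
(B-mode intensity + SWV map), each tagged with a rigid frame-to-world pose,
with configurable pose jitter and per-pixel measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "SWV_BOUNDS",
    "RigidPose",
    "TendonPhantom",
    "SweepConfig",
    "SweepFrame",
    "EmptySweepError",
    "swv_at",
    "region_labels_at",
    "linear_sweep_trajectory",
    "simulate_sweep",
]

#: Default physical plausibility bounds for tissue SWV, m/s.
SWV_BOUNDS = (0.5, 16.0)

_ORTHO_TOL = 1e-9


class EmptySweepError(RuntimeError):
    """Raised when no frame of a sweep intersects the tendon solid."""


@dataclass(frozen=True)
class RigidPose:
    """Frame-to-world rigid transform: ``world = R @ frame + t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max |R'R - I| = {err:.3g})")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map frame-coordinate points (…, 3) into world coordinates."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def _perpendicular_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing a right-handed basis with ``axis``."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


@dataclass(frozen=True)
class TendonPhantom:
    """Tendon solid with known regional SWV.

    Parameters
    ----------
    proximal_landmark, distal_landmark:
        Insertion points in world mm (patellar apex / tibial tuberosity).
    radii:
        Cross-section half-axes ``(width, thickness)`` in mm; the width axis
        lies perpendicular to the centerline in the u-direction of the local
        basis, the thickness axis in the v-direction.
    swv_true:
        Region → m/s map with keys ``proximal``, ``mid``, ``distal``.
    bow:
        Lateral bow (mm) of the centerline, applied as
        ``bow * sin(pi * s / L)`` along the width direction; 0 = straight.
    cut_distance:
        Axial distance (mm) of the two region cuts from each insertion.
    """

    proximal_landmark: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    distal_landmark: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 46.0]))
    radii: tuple[float, float] = (12.0, 2.0)
    swv_true: dict = field(
        default_factory=lambda: {"proximal": 9.5, "mid": 9.0, "distal": 10.0})
    background_swv: float = 2.0
    bmode_tendon_intensity: float = 1.0
    bmode_background_intensity: float = 0.1
    bow: float = 0.0
    cut_distance: float = 10.0
    swv_bounds: tuple[float, float] = SWV_BOUNDS

    def __post_init__(self):
        object.__setattr__(
            self, "proximal_landmark",
            np.asarray(self.proximal_landmark, dtype=float))
        object.__setattr__(
            self, "distal_landmark",
            np.asarray(self.distal_landmark, dtype=float))
        if self.length <= 20.0:
            raise ValueError(
                "landmark separation must exceed 20 mm (two 10 mm end regions "
                "plus a nonempty mid-portion)")
        if min(self.radii) <= 0:
            raise ValueError("radii must be positive")
        lo, hi = self.swv_bounds
        for name in ("proximal", "mid", "distal"):
            if name not in self.swv_true:
                raise ValueError(f"swv_true missing region {name!r}")
            if not lo <= self.swv_true[name] <= hi:
                raise ValueError(
                    f"swv_true[{name!r}] outside physical bounds {self.swv_bounds}")

    @property
    def length(self) -> float:
        """Tendon length: landmark-to-landmark distance, mm."""
        return float(np.linalg.norm(self.distal_landmark - self.proximal_landmark))

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from the proximal toward the distal landmark."""
        d = self.distal_landmark - self.proximal_landmark
        return d / np.linalg.norm(d)

    def local_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Width and thickness unit vectors perpendicular to the axis."""
        return _perpendicular_basis(self.axis)

    def axial_radial(self, points: np.ndarray):
        """Axial coordinate s (mm from proximal landmark) and normalized
        radial distance rho (<= 1 inside the cross-section ellipse)."""
        pts = np.asarray(points, dtype=float)
        d = pts - self.proximal_landmark
        s = d @ self.axis
        u_hat, v_hat = self.local_basis()
        u = d @ u_hat
        v = d @ v_hat
        if self.bow != 0.0:
            u = u - self.bow * np.sin(np.pi * np.clip(s, 0, self.length) / self.length)
        a, b = self.radii
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        return s, rho

    def contains(self, points: np.ndarray, inset: float = 0.0) -> np.ndarray:
        """Boolean in-solid test; ``inset`` > 0 shrinks the solid by that
        margin (mm) in every direction (used to exclude boundary voxels)."""
        pts = np.asarray(points, dtype=float)
        d = pts - self.proximal_landmark
        s = d @ self.axis
        u_hat, v_hat = self.local_basis()
        u = d @ u_hat
        v = d @ v_hat
        if self.bow != 0.0:
            u = u - self.bow * np.sin(np.pi * np.clip(s, 0, self.length) / self.length)
        a = self.radii[0] - inset
        b = self.radii[1] - inset
        if a <= 0 or b <= 0:
            return np.zeros(np.shape(s), dtype=bool)
        rho = (u / a) ** 2 + (v / b) ** 2
        return (s >= inset) & (s <= self.length - inset) & (rho <= 1.0)


def region_labels_at(phantom: TendonPhantom, points: np.ndarray) -> np.ndarray:
    """Region label per point: 0 background, 1 proximal, 2 mid, 3 distal.

    Cut planes sit perpendicular to the landmark axis at ``cut_distance`` from
    each insertion; points exactly on a cut belong to the end region.
    """
    inside = phantom.contains(points)
    s, _ = phantom.axial_radial(points)
    cut = phantom.cut_distance
    labels = np.zeros(np.shape(s), dtype=np.int8)
    labels[inside] = 2
    labels[inside & (s <= cut)] = 1
    labels[inside & (s >= phantom.length - cut)] = 3
    return labels


def swv_at(phantom: TendonPhantom, points: np.ndarray) -> np.ndarray:
    """Ground-truth SWV (m/s) at world points; background outside the solid."""
    labels = region_labels_at(phantom, points)
    lut = np.array([
        phantom.background_swv,
        phantom.swv_true["proximal"],
        phantom.swv_true["mid"],
        phantom.swv_true["distal"],
    ])
    return lut[labels]


@dataclass(frozen=True)
class SweepConfig:
    """Acquisition parameters for a simulated freehand sweep.

    ``trajectory`` is the sequence of nominal (noise-free) poses; when None a
    transverse sweep along the tendon axis is generated.  Pose noise is an
    isotropic random rotation (SD in degrees) plus i.i.d. Gaussian translation
    jitter (SD in mm) applied to every nominal pose.
    """

    n_frames: int = 96
    frame_rows: int = 24
    frame_cols: int = 64
    pixel_spacing: float = 0.5
    trajectory: Sequence[RigidPose] | None = None
    pose_noise_rot_deg: float = 0.0
    pose_noise_trans_mm: float = 0.0
    swv_noise_sd: float = 0.0
    bmode_noise_sd: float = 0.0
    invalid_fraction: float = 0.0
    margin_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_rows < 1 or self.frame_cols < 1:
            raise ValueError("frame dimensions must be >= 1")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        for name in ("pose_noise_rot_deg", "pose_noise_trans_mm",
                     "swv_noise_sd", "bmode_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.invalid_fraction < 1.0:
            raise ValueError("invalid_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SweepFrame:
    """One 2D acquisition: B-mode grid, SWV grid (NaN = invalid), pose."""

    bmode: np.ndarray
    swv: np.ndarray
    pixel_spacing: float
    pose: RigidPose

    def __post_init__(self):
        if self.bmode.shape != self.swv.shape:
            raise ValueError("bmode and swv grids must share a shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bmode.shape


def linear_sweep_trajectory(phantom: TendonPhantom, cfg: SweepConfig) -> list[RigidPose]:
    """Nominal transverse sweep: frames perpendicular to the tendon axis,
    centered on the centerline, stepping evenly from ``-margin`` to
    ``L + margin`` along the axis.

    Frame columns map to the tendon width direction, rows to the thickness
    direction, so each frame images one cross-section.
    """
    u_hat, v_hat = phantom.local_basis()
    R = np.column_stack([u_hat, v_hat, phantom.axis])
    center_frame = np.array([
        (cfg.frame_cols - 1) / 2 * cfg.pixel_spacing,
        (cfg.frame_rows - 1) / 2 * cfg.pixel_spacing,
        0.0,
    ])
    s_values = np.linspace(-cfg.margin_mm, phantom.length + cfg.margin_mm,
                           cfg.n_frames)
    poses = []
    for s in s_values:
        t = phantom.proximal_landmark + s * phantom.axis - R @ center_frame
        poses.append(RigidPose(rotation=R, translation=t))
    return poses


def _frame_pixel_coords(cfg: SweepConfig) -> np.ndarray:
    """Pixel-center frame coordinates, shape (rows, cols, 3): (c*d, r*d, 0)."""
    r, c = np.meshgrid(np.arange(cfg.frame_rows), np.arange(cfg.frame_cols),
                       indexing="ij")
    return np.stack([c * cfg.pixel_spacing, r * cfg.pixel_spacing,
                     np.zeros_like(c, dtype=float)], axis=-1)


def _perturb_pose(pose: RigidPose, cfg: SweepConfig, rng: np.random.Generator) -> RigidPose:
    # Draw noise unconditionally so the random stream does not depend on the
    # noise settings (a zero-noise run stays comparable frame-for-frame).
    rotvec = rng.normal(0.0, np.deg2rad(cfg.pose_noise_rot_deg), size=3)
    dt = rng.normal(0.0, cfg.pose_noise_trans_mm, size=3)
    if cfg.pose_noise_rot_deg == 0.0 and cfg.pose_noise_trans_mm == 0.0:
        return pose
    dR = Rotation.from_rotvec(rotvec).as_matrix()
    return RigidPose(rotation=dR @ pose.rotation,
                     translation=pose.translation + dt)


def simulate_sweep(phantom: TendonPhantom, cfg: SweepConfig,
                   rng: np.random.Generator | None = None) -> list[SweepFrame]:
    """Simulate a pose-tracked 2D SWE sweep over the phantom.

    Each frame's pose is the nominal trajectory pose perturbed by pose noise;
    each SWV pixel samples the ground-truth field at its world position plus
    additive Gaussian noise, clipped to the physical bounds; B-mode pixels get
    the tendon/background intensity plus noise.  Deterministic given the seed.

    Raises
    ------
    EmptySweepError
        If no frame contains a single in-tendon pixel.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    trajectory = (list(cfg.trajectory) if cfg.trajectory is not None
                  else linear_sweep_trajectory(phantom, cfg))
    if len(trajectory) != cfg.n_frames:
        raise ValueError("trajectory length must equal n_frames")

    frame_coords = _frame_pixel_coords(cfg)
    lo, hi = phantom.swv_bounds
    frames: list[SweepFrame] = []
    any_tendon = False
    for nominal in trajectory:
        pose = _perturb_pose(nominal, cfg, rng)
        world = pose.apply(frame_coords.reshape(-1, 3))
        inside = phantom.contains(world)
        any_tendon = any_tendon or bool(inside.any())

        swv = swv_at(phantom, world)
        swv = swv + rng.normal(0.0, cfg.swv_noise_sd, size=swv.shape) \
            if cfg.swv_noise_sd > 0 else swv
        swv = np.clip(swv, lo, hi)

        bmode = np.where(inside, phantom.bmode_tendon_intensity,
                         phantom.bmode_background_intensity)
        if cfg.bmode_noise_sd > 0:
            bmode = bmode + rng.normal(0.0, cfg.bmode_noise_sd, size=bmode.shape)
        bmode = np.maximum(bmode, 0.0)

        if cfg.invalid_fraction > 0:
            void = rng.random(swv.shape) < cfg.invalid_fraction
            swv = np.where(void, np.nan, swv)

        frames.append(SweepFrame(
            bmode=bmode.reshape(cfg.frame_rows, cfg.frame_cols),
            swv=swv.reshape(cfg.frame_rows, cfg.frame_cols),
            pixel_spacing=cfg.pixel_spacing,
            pose=pose,
        ))
    if not any_tendon:
        raise EmptySweepError("empty sweep: no frame intersects the tendon")
    return frames
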