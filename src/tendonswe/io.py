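"""File formats: NRRD volumes, frame stacks, poses CSV, cohort CSV,
landmarks JSON.

NRRD (NRRD0004, raw little-endian encoding, ``space directions`` /
``space origin`` in the header) is the canonical volume format; NIfTI export
via nibabel is optional.  All round-trips are lossless on declared fields
(values to 1e-12, metadata exactly up to float formatting at 17 significant
digits).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import RigidPose, SweepFrame
from .reconstruct import VoxelGridSpec, VoxelVolume

__all__ = [
    "ParseError",
    "write_nrrd", "read_nrrd",
    "write_volume", "read_volume", "write_nifti",
    "write_frame_stack", "read_frame_stack",
    "write_poses_csv", "read_poses_csv",
    "write_cohort_csv", "read_cohort_csv",
    "write_landmarks_json", "read_landmarks_json",
]

POSE_COLUMNS = ["frame_index",
                "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
                "tx", "ty", "tz"]


class ParseError(ValueError):
    """Malformed file content."""


# ---------------------------------------------------------------- NRRD ----

def write_nrrd(path, array: np.ndarray, spacing=None, origin=None) -> None:
    """Write a 3D array as NRRD0004, raw little-endian, Fortran pixel order
    (first index fastest, the NRRD convention)."""
    array = np.asarray(array, dtype="<f8")
    if array.ndim != 3:
        raise ValueError("only 3D arrays are written")
    spacing = np.broadcast_to(np.asarray(
        1.0 if spacing is None else spacing, dtype=float), (3,))
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)

    def vec(v):
        return "(" + ",".join(repr(float(x)) for x in v) + ")"
    directions = " ".join(vec(spacing[i] * np.eye(3)[i]) for i in range(3))
    header = [
        "NRRD0004",
        "# tendonswe volume",
        "type: double",
        "dimension: 3",
        "space: right-handed-mm",
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"space directions: {directions}",
        "endian: little",
        "encoding: raw",
        f"space origin: {vec(origin)}",
        "",  # blank line terminates the header
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode())
        fh.write(array.flatten(order="F").tobytes())


def read_nrrd(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an NRRD written by :func:`write_nrrd`.

    Returns ``(array, spacing, origin)``.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        head_end = raw.index(b"\n\n")
    except ValueError as e:
        raise ParseError("no NRRD header terminator found") from e
    lines = raw[:head_end].decode().splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ParseError("not an NRRD file")
    fields = {}
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    for req in ("type", "dimension", "sizes", "encoding"):
        if req not in fields:
            raise ParseError(f"NRRD header missing field {req!r}")
    if fields["type"] != "double" or fields["encoding"] != "raw":
        raise ParseError("only raw double NRRD is supported")
    if int(fields["dimension"]) != 3:
        raise ParseError("only 3D NRRD is supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())

    def parse_vecs(text):
        return [np.array([float(x) for x in part.strip("()").split(",")])
                for part in text.split()]

    spacing = np.ones(3)
    if "space directions" in fields:
        vecs = parse_vecs(fields["space directions"])
        spacing = np.array([np.linalg.norm(v) for v in vecs])
    origin = np.zeros(3)
    if "space origin" in fields:
        origin = parse_vecs(fields["space origin"])[0]
    data = np.frombuffer(raw[head_end + 2:], dtype="<f8")
    if data.size != int(np.prod(sizes)):
        raise ParseError("NRRD data size does not match header sizes")
    return data.reshape(sizes, order="F").copy(), spacing, origin


def write_volume(path, volume: VoxelVolume) -> None:
    """Write a finalized voxel volume (values only) as NRRD."""
    write_nrrd(path, volume.values, spacing=volume.spec.spacing,
               origin=volume.spec.origin)


def read_volume(path) -> VoxelVolume:
    """Read an NRRD volume into a finalized :class:`VoxelVolume` (weights are
    1 where defined, 0 where NaN — deposit weights are not serialized)."""
    arr, spacing, origin = read_nrrd(path)
    spec = VoxelGridSpec(origin=origin, spacing=spacing, dims=arr.shape)
    weights = np.where(np.isfinite(arr), 1.0, 0.0)
    return VoxelVolume(spec=spec, values=arr, weights=weights, finalized=True)


def write_nifti(path, volume: VoxelVolume) -> None:
    """Optional NIfTI export of a finalized volume (diagonal affine)."""
    import nibabel as nib
    affine = np.diag([*volume.spec.spacing, 1.0])
    affine[:3, 3] = volume.spec.origin
    nib.save(nib.Nifti1Image(volume.values, affine), str(path))


# --------------------------------------------------------- frame stacks ----

def write_frame_stack(prefix, frames: list[SweepFrame]) -> dict:
    """Write a sweep as two NRRD stacks (frame index = slowest axis) plus a
    poses CSV; returns the written paths."""
    prefix = Path(prefix)
    swv = np.stack([f.swv for f in frames], axis=0)
    bmode = np.stack([f.bmode for f in frames], axis=0)
    spacing = frames[0].pixel_spacing
    paths = {
        "swv": prefix.with_suffix(".swv.nrrd"),
        "bmode": prefix.with_suffix(".bmode.nrrd"),
        "poses": prefix.with_suffix(".poses.csv"),
    }
    # stack axes (frame, row, col) -> transpose so frame index is slowest in
    # the NRRD fastest-first ordering
    write_nrrd(paths["swv"], swv.T, spacing=(spacing, spacing, 1.0))
    write_nrrd(paths["bmode"], bmode.T, spacing=(spacing, spacing, 1.0))
    write_poses_csv(paths["poses"], [f.pose for f in frames])
    return paths


def read_frame_stack(prefix, pixel_spacing: float | None = None
                     ) -> list[SweepFrame]:
    """Inverse of :func:`write_frame_stack`."""
    prefix = Path(prefix)
    swv, spacing, _ = read_nrrd(prefix.with_suffix(".swv.nrrd"))
    bmode, _, _ = read_nrrd(prefix.with_suffix(".bmode.nrrd"))
    poses = read_poses_csv(prefix.with_suffix(".poses.csv"))
    swv = swv.T
    bmode = bmode.T
    if len(poses) != swv.shape[0]:
        raise ParseError("pose count does not match frame count")
    px = pixel_spacing if pixel_spacing is not None else float(spacing[0])
    return [SweepFrame(bmode=bmode[i], swv=swv[i], pixel_spacing=px,
                       pose=poses[i]) for i in range(swv.shape[0])]


# ----------------------------------------------------------- poses CSV ----

def write_poses_csv(path, poses: list[RigidPose]) -> None:
    rows = []
    for i, pose in enumerate(poses):
        rows.append([i, *pose.rotation.reshape(-1), *pose.translation])
    pd.DataFrame(rows, columns=POSE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_poses_csv(path, tol: float = 1e-6) -> list[RigidPose]:
    """Read poses; rejects non-orthonormal rotations with a tolerance report."""
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"poses CSV missing columns {missing}")
    poses = []
    for _, row in df.iterrows():
        R = row[POSE_COLUMNS[1:10]].to_numpy(dtype=float).reshape(3, 3)
        t = row[POSE_COLUMNS[10:]].to_numpy(dtype=float)
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise ParseError(
                f"non-finite pose entries at frame {int(row.frame_index)}")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > tol:
            raise ParseError(
                f"rotation of frame {int(row.frame_index)} is not orthonormal:"
                f" max |R'R - I| = {err:.3g} exceeds tolerance {tol:g}")
        poses.append(RigidPose(rotation=R, translation=t))
    return poses


# ---------------------------------------------------------- cohort CSV ----

def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    from .cohort import COHORT_COLUMNS
    cohort[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table; warns if the BMI column disagrees with
    weight / (height/100)^2 beyond 1e-6."""
    from .cohort import COHORT_COLUMNS
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"cohort CSV missing columns {missing}")
    bmi = df["weight"] / (df["height"] / 100.0) ** 2
    bad = (df["bmi"] - bmi).abs() > 1e-6
    if bad.any():
        warnings.warn(
            f"cohort CSV: {int(bad.sum())} row(s) with bmi inconsistent with "
            "weight/(height/100)^2 beyond 1e-6", stacklevel=2)
    return df


# ------------------------------------------------------ landmarks JSON ----

def write_landmarks_json(path, proximal, distal) -> None:
    with open(path, "w") as fh:
        json.dump({"proximal": list(map(float, proximal)),
                   "distal": list(map(float, distal))}, fh, indent=1)


def read_landmarks_json(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        obj = json.load(fh)
    for key in ("proximal", "distal"):
        if key not in obj or len(obj[key]) != 3:
            raise ParseError(f"landmarks JSON needs a 3-vector {key!r}")
    p = np.asarray(obj["proximal"], dtype=float)
    d = np.asarray(obj["distal"], dtype=float)
    if not (np.isfinite(p).all() and np.isfinite(d).all()):
        raise ParseError("landmarks must be finite")
    return p, d
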