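"""Point-set geometry for image-guidance QA in Leksell coordinates.

Positions are expressed in the Leksell stereotactic frame (mm), whose
radiological focus sits nominally at (100, 100, 100).  Registrations are
evaluated through labeled point sets: target registration error (TRE) between
matched anatomic landmarks after a rigid registration, recovery of known
couch/phantom offsets, and the readout accuracy of the motion-tracking
camera against micrometer-applied displacements.  No image (intensity)
registration happens here — transforms are *evaluated*, not estimated from
voxels.

Rotations are stored as 3x3 matrices and exchanged as Euler angles in
degrees with z-y-x composition (R = Rz @ Ry @ Rx), the convention clinical
systems use when reporting rotational corrections.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .budget import UncertaintyComponent

__all__ = [
    "LEKSELL_CENTER_MM",
    "FiducialSet",
    "RigidTransform",
    "TREResult",
    "radial_displacement",
    "apply_transform",
    "compute_tre",
    "registration_residual",
    "readout_accuracy",
]

#: Nominal radiological focus of the Leksell frame.
LEKSELL_CENTER_MM = np.array([100.0, 100.0, 100.0])


def radial_displacement(v: Sequence[float]) -> float:
    """Euclidean magnitude sqrt(x^2 + y^2 + z^2) of a displacement vector."""
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected a 3-vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("displacement components must be finite")
    return float(np.linalg.norm(arr))


@dataclass
class FiducialSet:
    """Labeled 3D points (mm, Leksell frame)."""

    labels: list[str]
    coords_mm: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.coords_mm = np.asarray(self.coords_mm, dtype=float).reshape(-1, 3)
        if len(self.labels) != self.coords_mm.shape[0]:
            raise ValueError("one label per point required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.coords_mm)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path) -> "FiducialSet":
        df = pd.read_csv(path)
        required = ["label", "x_mm", "y_mm", "z_mm"]
        if list(df.columns[:4]) != required:
            raise ValueError(f"fiducial CSV must have columns {required}")
        return cls(labels=df["label"].tolist(),
                   coords_mm=df[["x_mm", "y_mm", "z_mm"]].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "label": self.labels,
            "x_mm": self.coords_mm[:, 0],
            "y_mm": self.coords_mm[:, 1],
            "z_mm": self.coords_mm[:, 2],
        }).to_csv(path, index=False)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map p -> R @ p + t with a proper rotation (det +1)."""

    rotation: np.ndarray
    translation_mm: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation_mm, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not math.isclose(
                float(np.linalg.det(R)), 1.0, abs_tol=1e-8):
            raise ValueError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t_mm: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t_mm, dtype=float))

    @classmethod
    def from_euler_deg(cls, rotation_deg: Sequence[float],
                       translation_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from clinical-convention angles [rx, ry, rz] (degrees).

        Composition is z-y-x: R = Rz(rz) @ Ry(ry) @ Rx(rx).
        """
        rx, ry, rz = (float(a) for a in rotation_deg)
        R = Rotation.from_euler("zyx", [rz, ry, rx], degrees=True).as_matrix()
        return cls(R, np.asarray(translation_mm, dtype=float))

    def to_euler_deg(self) -> tuple[list[float], list[float]]:
        rz, ry, rx = Rotation.from_matrix(self.rotation).as_euler("zyx", degrees=True)
        return [float(rx), float(ry), float(rz)], [float(v) for v in self.translation_mm]

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return cls.from_euler_deg(data.get("rotation_deg", [0, 0, 0]),
                                  data.get("translation_mm", [0, 0, 0]))

    def to_json(self, path) -> None:
        rot, trans = self.to_euler_deg()
        Path(path).write_text(json.dumps({"rotation_deg": rot, "translation_mm": trans},
                                         indent=2, sort_keys=True) + "\n")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation_mm

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply *other* first, then *self*."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation_mm + self.translation_mm)


def apply_transform(points: FiducialSet, transform: RigidTransform) -> FiducialSet:
    """Transform a fiducial set, preserving labels (and pairwise distances)."""
    return FiducialSet(labels=list(points.labels),
                       coords_mm=transform.apply(points.coords_mm))


@dataclass(frozen=True)
class TREResult:
    """Target registration error over matched anatomic landmarks."""

    labels: tuple[str, ...]
    distances_mm: np.ndarray
    mean_mm: float
    sd_mm: float
    max_mm: float
    n: int


def compute_tre(fixed: FiducialSet, moving: FiducialSet,
                transform: RigidTransform) -> TREResult:
    """Per-landmark distance between fixed points and registered moving points.

    Landmarks are matched by exact label (the TG-132 anatomic-point method);
    a label mismatch is an error, never silently dropped.
    """
    if set(fixed.labels) != set(moving.labels):
        raise ValueError("fixed and moving sets must share identical labels")
    order = {lab: i for i, lab in enumerate(moving.labels)}
    moved = transform.apply(moving.coords_mm)
    moved_aligned = moved[[order[lab] for lab in fixed.labels]]
    d = np.linalg.norm(fixed.coords_mm - moved_aligned, axis=1)
    return TREResult(
        labels=tuple(fixed.labels), distances_mm=d,
        mean_mm=float(d.mean()),
        sd_mm=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        max_mm=float(d.max()), n=int(d.size),
    )


def registration_residual(known_offset_mm: Sequence[float],
                          recommended_correction_mm: Sequence[float]) -> np.ndarray:
    """Signed per-axis error of a recommended correction: correction − offset."""
    offset = np.asarray(known_offset_mm, dtype=float)
    corr = np.asarray(recommended_correction_mm, dtype=float)
    if offset.shape != (3,) or corr.shape != (3,):
        raise ValueError("expected 3-vectors")
    if not (np.all(np.isfinite(offset)) and np.all(np.isfinite(corr))):
        raise ValueError("inputs must be finite")
    return corr - offset


def readout_accuracy(applied_moves_mm: Sequence[Sequence[float]],
                     readouts_mm: Sequence[Sequence[float]],
                     name: str = "HDMM Accuracy") -> UncertaintyComponent:
    """Tracking-camera readout error against micrometer-applied displacements.

    Per-axis signed error is readout − applied; the vector statistics are the
    mean ± SD of per-measurement error magnitudes.  Returned as a systematic,
    Type A budget row.
    """
    applied = np.asarray(applied_moves_mm, dtype=float).reshape(-1, 3)
    readout = np.asarray(readouts_mm, dtype=float).reshape(-1, 3)
    if applied.shape != readout.shape:
        raise ValueError("applied and readout lists must have equal length")
    if applied.shape[0] == 0:
        raise ValueError("need at least one measurement")
    err = readout - applied
    means = tuple(float(m) for m in err.mean(axis=0))
    sds = tuple(float(s) for s in (err.std(axis=0, ddof=1) if err.shape[0] > 1
                                   else np.zeros(3)))
    norms = np.linalg.norm(err, axis=1)
    return UncertaintyComponent(
        name=name, vector_mean_mm=float(norms.mean()),
        vector_sd_mm=float(norms.std(ddof=1)) if norms.size > 1 else 0.0,
        axis_mean_mm=means, axis_sd_mm=sds, n=applied.shape[0],
        error_type="systematic", uncertainty_class="A",
    )
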