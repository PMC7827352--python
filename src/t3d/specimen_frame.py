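"""Anatomical orientation of the scanned specimen from labeled fiducials.

During scanning the specimen's orientation (anterior, posterior, left,
right, superior/mucosal, deep) is marked with needles; the scanner records
their positions in arbitrary scan coordinates. This module fits the proper
rigid transform that brings the specimen into a fixed anatomical frame:

    right-handed, millimetres;
    +x = patient-left, -x = patient-right,
    +y = anterior,     -y = posterior,
    +z = superior (mucosal surface), -z = deep.

The fit is a centroid-aligned orthogonal Procrustes on the fiducial
offsets: each fiducial's offset from the fiducial centroid is matched to
its convention direction scaled by the measured offset length, so a rigid
motion of the inputs is recovered exactly. If the best orthogonal fit is a
reflection the labels are inconsistent (e.g. left/right swapped) and an
error is raised rather than silently mirroring the specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, OrientationError
from .geometry import kabsch
from .mesh_core import SurfaceMesh

CONVENTION = {
    "left": np.array([1.0, 0.0, 0.0]),
    "right": np.array([-1.0, 0.0, 0.0]),
    "anterior": np.array([0.0, 1.0, 0.0]),
    "posterior": np.array([0.0, -1.0, 0.0]),
    "superior": np.array([0.0, 0.0, 1.0]),
    "deep": np.array([0.0, 0.0, -1.0]),
}

AXIS_INDEX = {"left-right": 0, "anterior-posterior": 1, "superior-deep": 2}


@dataclass
class Fiducial:
    """A labeled orientation marker (needle tip) in scan coordinates (mm)."""

    label: str
    position: np.ndarray

    def __post_init__(self):
        if self.label not in CONVENTION:
            raise GeometryError(
                f"unknown fiducial label {self.label!r}; expected one of "
                f"{sorted(CONVENTION)}"
            )
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class InkLinePlane:
    """A surface ink line modeled as the plane containing its stripe.

    The dorsal line runs antero-posteriorly on the dorsal (superior)
    surface; the second line is drawn perpendicular to it. Intersecting
    each stripe plane with a section plane yields the ink-line trace the
    pathologist sees on the slice face. ``direction_hint`` records the
    drawing direction, which fixes the sign of the trace direction (so a
    mirror-mounted slide is detectable).
    """

    label: str  # "dorsal_line" | "perpendicular_line"
    point: np.ndarray
    normal: np.ndarray
    direction_hint: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)
        h = np.asarray(self.direction_hint, dtype=float).reshape(3)
        self.direction_hint = h / np.linalg.norm(h)


@dataclass
class AnatomicalFrame:
    """Proper rigid map x_anatomical = R @ x_scan + t."""

    rotation: np.ndarray
    translation: np.ndarray
    convention: dict = field(default_factory=lambda: {k: v.tolist() for k, v in CONVENTION.items()})

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse_apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.translation) @ self.rotation


@dataclass
class SpecimenModel:
    """The oriented digital resection specimen.

    Mesh, fiducials, and ink lines are all expressed in the anatomical
    frame; ``frame`` maps original scan coordinates into it.
    """

    mesh: SurfaceMesh
    frame: AnatomicalFrame
    fiducials: list
    residual_mm: float
    ink_lines: dict = field(default_factory=dict)  # label -> InkLinePlane

    def axis_extent(self, axis: str) -> tuple[float, float]:
        """(min, max) mesh coordinate along a named anatomical axis pair."""
        k = AXIS_INDEX[axis]
        v = self.mesh.vertices[:, k]
        return float(v.min()), float(v.max())


def orient_specimen(
    mesh: SurfaceMesh,
    fiducials: list[Fiducial],
    ink_lines: dict | None = None,
) -> SpecimenModel:
    """Fit the anatomical frame from labeled fiducials and apply it.

    Requires at least 3 non-collinear fiducials with distinct labels.
    The anatomical origin is placed at the fiducial centroid. Ink lines,
    if given in scan coordinates, are transformed along.
    """
    labels = [f.label for f in fiducials]
    if len(set(labels)) != len(labels):
        raise GeometryError(f"duplicate fiducial labels: {labels}")
    if len(fiducials) < 3:
        raise GeometryError("at least 3 fiducials are required to fix a frame")
    P = np.array([f.position for f in fiducials])
    centroid = P.mean(axis=0)
    offsets = P - centroid
    rank = np.linalg.matrix_rank(offsets, tol=1e-9 * max(1.0, np.abs(offsets).max()))
    if rank < 2:
        raise GeometryError("fiducials are collinear; cannot fix a frame")
    lengths = np.linalg.norm(offsets, axis=1)
    targets = np.array([CONVENTION[f.label] * r for f, r in zip(fiducials, lengths)])
    R, needs_reflection = kabsch(offsets, targets)
    if needs_reflection:
        raise OrientationError(
            "best rigid fit requires a reflection: fiducial labels are "
            "inconsistent (e.g. left/right swapped)"
        )
    t = -R @ centroid
    frame = AnatomicalFrame(rotation=R, translation=t)
    residual = float(
        np.sqrt(np.mean(np.sum((offsets @ R.T - targets) ** 2, axis=1)))
    )
    new_fids = [Fiducial(f.label, frame.apply(f.position)) for f in fiducials]
    new_ink = {}
    for label, line in (ink_lines or {}).items():
        new_ink[label] = InkLinePlane(
            label=line.label,
            point=frame.apply(line.point),
            normal=R @ line.normal,
            direction_hint=R @ line.direction_hint,
        )
    return SpecimenModel(
        mesh=mesh.transformed(R, t),
        frame=frame,
        fiducials=new_fids,
        residual_mm=residual,
        ink_lines=new_ink,
    )
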