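"""Surgical margins between tumor and specimen surface, by anatomical
direction, with formalin-shrinkage correction.

The margin toward a direction d is the minimum Euclidean distance from the
tumor surface to the specimen faces "facing" d, where each specimen face
is classified by the anatomical axis most parallel to its outward normal
(six-way argmax of n·axis). The closest margin is the global minimum over
all faces; the face labeling is exported for inspection, since clinical
reports name margins by direction ("0.1 mm towards the bottom/deep",
"20 mm posteriorly") without a formal classification rule.

Specimens are scanned fresh but slides are measured after formalin
fixation, which shrinks oral soft tissue by 14–24 % depending on
orientation. When fresh and fixed measurements are mixed, lengths can be
rescaled by 1/(1−f); the correction is off by default (f = 0) because the
appropriate factor is case- and orientation-dependent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .errors import ParameterError, PreconditionError
from .geometry import points_to_triangles_distance
from .mesh_core import SurfaceMesh, mesh_volume
from .specimen_frame import CONVENTION, SpecimenModel

log = logging.getLogger(__name__)

DIRECTIONS = ("anterior", "posterior", "left", "right", "superior", "deep")
DIRECTION_AXIS = {
    "anterior": 1,
    "posterior": 1,
    "left": 0,
    "right": 0,
    "superior": 2,
    "deep": 2,
}
SHRINKAGE_LITERATURE_RANGE = (0.14, 0.24)


@dataclass
class ShrinkageFactor:
    """Formalin shrinkage fraction f with corrected length = measured/(1-f).

    ``mode`` is "isotropic" (one fraction for every axis) or "per-axis"
    (fractions for x, y, z — shrinkage is orientation dependent).
    """

    fraction: float | tuple = 0.0
    mode: str = "isotropic"

    def __post_init__(self):
        if self.mode not in ("isotropic", "per-axis"):
            raise ParameterError(f"unknown shrinkage mode {self.mode!r}")
        f = np.atleast_1d(np.asarray(self.fraction, dtype=float))
        if self.mode == "isotropic":
            if f.size != 1:
                raise ParameterError("isotropic mode takes a single fraction")
            f = np.repeat(f, 3)
        elif f.size != 3:
            raise ParameterError("per-axis mode takes three fractions (x, y, z)")
        if np.any(f < 0) or np.any(f >= 0.5):
            raise ParameterError(
                f"shrinkage fraction must lie in [0, 0.5), got {self.fraction}"
            )
        self.per_axis = f

    @property
    def scale(self) -> np.ndarray:
        """Per-axis length multiplier 1/(1-f)."""
        return 1.0 / (1.0 - self.per_axis)

    @property
    def volume_scale(self) -> float:
        return float(np.prod(self.scale))

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.per_axis == 0))


@dataclass
class MarginReport:
    """Margins (mm), tumor volume (mm^3), and shrinkage bookkeeping."""

    directional_margins_mm: dict
    closest_margin_mm: float
    closest_direction: str
    largest_margin_mm: float
    largest_direction: str
    tumor_volume_mm3: float
    absent_directions: list = field(default_factory=list)
    shrinkage: ShrinkageFactor = field(default_factory=ShrinkageFactor)
    corrected_directional_margins_mm: dict | None = None
    corrected_closest_margin_mm: float | None = None
    corrected_largest_margin_mm: float | None = None
    corrected_tumor_volume_mm3: float | None = None
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "directional_margins_mm": self.directional_margins_mm,
            "closest_margin_mm": self.closest_margin_mm,
            "closest_direction": self.closest_direction,
            "largest_margin_mm": self.largest_margin_mm,
            "largest_direction": self.largest_direction,
            "tumor_volume_mm3": self.tumor_volume_mm3,
            "absent_directions": self.absent_directions,
            "shrinkage_factor_applied": self.shrinkage.per_axis.tolist(),
            "shrinkage_mode": self.shrinkage.mode,
            "notes": self.notes,
        }
        if self.corrected_directional_margins_mm is not None:
            d["corrected_directional_margins_mm"] = self.corrected_directional_margins_mm
            d["corrected_closest_margin_mm"] = self.corrected_closest_margin_mm
            d["corrected_largest_margin_mm"] = self.corrected_largest_margin_mm
            d["corrected_tumor_volume_mm3"] = self.corrected_tumor_volume_mm3
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True, **kw)

    def to_text(self) -> str:
        lines = ["Surgical margin report", "======================"]
        for d in DIRECTIONS:
            v = self.directional_margins_mm.get(d)
            lines.append(
                f"  {d:<9s}: " + ("absent" if v is None else f"{v:8.2f} mm")
            )
        lines.append(
            f"  closest  : {self.closest_margin_mm:8.2f} mm "
            f"towards {self.closest_direction}"
        )
        lines.append(
            f"  largest  : {self.largest_margin_mm:8.2f} mm "
            f"towards {self.largest_direction}"
        )
        lines.append(f"  tumor volume: {self.tumor_volume_mm3:.1f} mm^3")
        if self.corrected_closest_margin_mm is not None:
            lines.append(
                f"  shrinkage-corrected closest margin: "
                f"{self.corrected_closest_margin_mm:.2f} mm"
            )
        for n in self.notes:
            lines.append(f"  note: {n}")
        return "\n".join(lines)


def label_faces(specimen: SpecimenModel) -> np.ndarray:
    """Anatomical direction label for every specimen face.

    A face gets the direction whose axis is most parallel to its outward
    normal; the sign of the dot product picks the side. Returns an integer
    index into :data:`DIRECTIONS`.
    """
    tm = specimen.mesh.as_trimesh()
    normals = np.asarray(tm.face_normals)
    dirs = np.array([CONVENTION[d] for d in DIRECTIONS])
    return np.argmax(normals @ dirs.T, axis=1)


def directional_margins(
    tumor: SurfaceMesh,
    specimen: SpecimenModel,
    check_containment: bool = True,
) -> MarginReport:
    """Per-direction, closest, and largest margins from tumor to specimen.

    Distances are exact point-to-triangle minima over candidate pairs found
    with a spatial index, evaluated symmetrically (tumor vertices against
    labeled specimen faces and labeled-face vertices against the tumor
    surface). A tumor protruding through the specimen surface yields a
    0 mm margin in the affected directions, with a warning.
    """
    if not tumor.is_watertight:
        raise PreconditionError("tumor mesh must be watertight")
    if not specimen.mesh.is_watertight:
        raise PreconditionError("specimen mesh must be watertight")
    labels = label_faces(specimen)
    sv = specimen.mesh.vertices
    sf = specimen.mesh.faces
    stris = sv[sf]
    ttris = tumor.vertices[tumor.faces]
    tm = specimen.mesh.as_trimesh()
    notes: list[str] = []

    protruding_dirs: set[str] = set()
    if check_containment:
        d, tri_idx, cp = points_to_triangles_distance(
            tumor.vertices, stris, return_closest=True
        )
        outward = np.asarray(tm.face_normals)[tri_idx]
        signed = np.einsum("ij,ij->i", tumor.vertices - cp, outward)
        outside = signed > 1e-9
        if outside.any():
            for ti in np.unique(tri_idx[outside]):
                protruding_dirs.add(DIRECTIONS[labels[ti]])
            warnings.warn(
                "tumor protrudes through the specimen surface towards "
                f"{sorted(protruding_dirs)}; margins there are reported as 0",
                stacklevel=2,
            )

    margins: dict[str, float | None] = {}
    absent: list[str] = []
    for di, dname in enumerate(DIRECTIONS):
        mask = labels == di
        if not mask.any():
            margins[dname] = None
            absent.append(dname)
            notes.append(f"no specimen faces toward {dname}: margin absent")
            continue
        if dname in protruding_dirs:
            margins[dname] = 0.0
            continue
        sub_tris = stris[mask]
        sub_verts = sv[np.unique(sf[mask])]
        d1 = points_to_triangles_distance(tumor.vertices, sub_tris)
        d2 = points_to_triangles_distance(sub_verts, ttris)
        margins[dname] = float(min(d1.min(), d2.min()))

    present = {k: v for k, v in margins.items() if v is not None}
    if not present:
        raise PreconditionError("no margins could be computed (no labeled faces)")
    closest_dir = min(present, key=lambda k: (present[k], DIRECTIONS.index(k)))
    largest_dir = max(present, key=lambda k: (present[k], -DIRECTIONS.index(k)))
    report = MarginReport(
        directional_margins_mm=margins,
        closest_margin_mm=present[closest_dir],
        closest_direction=closest_dir,
        largest_margin_mm=present[largest_dir],
        largest_direction=largest_dir,
        tumor_volume_mm3=mesh_volume(tumor),
        absent_directions=absent,
        notes=notes,
    )
    log.info(
        "margins: closest %.3f mm (%s), largest %.3f mm (%s)",
        report.closest_margin_mm,
        closest_dir,
        report.largest_margin_mm,
        largest_dir,
    )
    return report


def apply_shrinkage(obj, factor: ShrinkageFactor):
    """Correct a mesh or a margin report for formalin shrinkage.

    Lengths scale by 1/(1-f) per axis; volumes by the product of the axis
    scales. For a report in per-axis mode each directional margin scales by
    its own axis factor (an approximation when the closest approach is
    oblique to the axis). The uncorrected values are retained.
    """
    if factor.is_identity:
        log.info(
            "shrinkage factor 0: no correction applied (literature range for "
            "oral SCC is %.0f%%-%.0f%% depending on orientation)",
            100 * SHRINKAGE_LITERATURE_RANGE[0],
            100 * SHRINKAGE_LITERATURE_RANGE[1],
        )
    scale = factor.scale
    if isinstance(obj, SurfaceMesh):
        return dc_replace(obj, vertices=obj.vertices * scale)
    if isinstance(obj, MarginReport):
        def fix(val, dname):
            if val is None:
                return None
            return float(val * scale[DIRECTION_AXIS[dname]])

        corrected = {
            d: fix(v, d) for d, v in obj.directional_margins_mm.items()
        }
        return dc_replace(
            obj,
            shrinkage=factor,
            corrected_directional_margins_mm=corrected,
            corrected_closest_margin_mm=fix(
                obj.closest_margin_mm, obj.closest_direction
            ),
            corrected_largest_margin_mm=fix(
                obj.largest_margin_mm, obj.largest_direction
            ),
            corrected_tumor_volume_mm3=float(
                obj.tumor_volume_mm3 * factor.volume_scale
            ),
        )
    raise ParameterError(
        f"apply_shrinkage expects a SurfaceMesh or MarginReport, got {type(obj)!r}"
    )
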