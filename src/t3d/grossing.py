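"""Grossing plans: the pathologist's freely chosen cut planes and the
labeled tissue slabs between them.

Cut positions are given in millimetres measured from the specimen border
where slicing starts, along the slicing direction — exactly how the
pathologist measures grossing sites from the specimen borders at the
bench. For the default anterior→posterior axis the first slab (the most
anterior) is named A, the second B, and so on; a perpendicular secondary
family is labeled numerically (1, 2, ...).

Each slab yields one histological section, taken by convention on the
slab's *start* face (the anterior face for the default axis). Which slab
face the slide represents is the largest geometric convention the
reconstruction must fix, so it is explicit here (``section_face``) and
echoed in the report.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .errors import PlanError
from .specimen_frame import SpecimenModel

# axis name -> (coordinate index, start border label, end border label).
# The start border always lies at the +coordinate side (left/anterior/
# superior are +x/+y/+z in the anatomical convention).
AXES = {
    "left-right": (0, "left", "right"),
    "anterior-posterior": (1, "anterior", "posterior"),
    "superior-deep": (2, "superior", "deep"),
}


def slab_labels(n: int, secondary: bool = False) -> list[str]:
    """A, B, ... Z, AA, AB ... for the primary family; 1, 2, ... secondary."""
    if secondary:
        return [str(i + 1) for i in range(n)]
    letters = string.ascii_uppercase
    out = []
    for i in range(n):
        if i < 26:
            out.append(letters[i])
        else:
            out.append(letters[i // 26 - 1] + letters[i % 26])
    return out


@dataclass
class GrossingPlan:
    """Ordered cut positions (mm from the start border) along one or two axes."""

    cut_positions: list
    primary_axis: str = "anterior-posterior"
    secondary_axis: str | None = None
    secondary_cut_positions: list = field(default_factory=list)
    section_face: str = "start"  # which slab face the slide represents

    def __post_init__(self):
        if self.primary_axis not in AXES:
            raise PlanError(f"unknown axis {self.primary_axis!r}")
        self.cut_positions = [float(c) for c in self.cut_positions]
        if any(b <= a for a, b in zip(self.cut_positions, self.cut_positions[1:])):
            raise PlanError("cut positions must be strictly increasing")
        if self.secondary_axis is not None:
            if self.secondary_axis not in AXES:
                raise PlanError(f"unknown axis {self.secondary_axis!r}")
            if self.secondary_axis == self.primary_axis:
                raise PlanError("secondary axis must be perpendicular to the primary")
            self.secondary_cut_positions = [float(c) for c in self.secondary_cut_positions]
            sec = self.secondary_cut_positions
            if any(b <= a for a, b in zip(sec, sec[1:])):
                raise PlanError("secondary cut positions must be strictly increasing")
        if self.section_face not in ("start", "end"):
            raise PlanError("section_face must be 'start' or 'end'")


@dataclass
class Slab:
    """A tissue slab between two planes perpendicular to a grossing axis."""

    label: str
    axis: str
    start_mm: float  # from the start border, start_mm < end_mm
    end_mm: float
    start_coord: float  # anatomical coordinate of the start face plane
    end_coord: float
    section_face: str = "start"

    @property
    def thickness_mm(self) -> float:
        return self.end_mm - self.start_mm

    @property
    def axis_index(self) -> int:
        return AXES[self.axis][0]

    @property
    def view_normal(self) -> np.ndarray:
        """Unit normal pointing toward the start border (+axis side)."""
        n = np.zeros(3)
        n[self.axis_index] = 1.0
        return n

    @property
    def section_coord(self) -> float:
        return self.start_coord if self.section_face == "start" else self.end_coord

    def section_plane(self) -> tuple[np.ndarray, np.ndarray]:
        """(origin, normal) of the plane the histological slide lies in.

        The normal points toward the start border so that "viewed from the
        anterior side" is well defined for the default axis.
        """
        origin = np.zeros(3)
        origin[self.axis_index] = self.section_coord
        return origin, self.view_normal


def _family_slabs(specimen, axis, positions, secondary):
    k, start_label, _ = AXES[axis]
    lo, hi = specimen.axis_extent(axis)
    extent = hi - lo
    for c in positions:
        if not (0.0 < c < extent):
            raise PlanError(
                f"cut at {c:g} mm from the {start_label} border is outside the "
                f"specimen ({axis} extent {extent:.3f} mm)"
            )
    bounds = [0.0, *positions, extent]
    labels = slab_labels(len(bounds) - 1, secondary=secondary)
    slabs = []
    for lab, a, b in zip(labels, bounds, bounds[1:]):
        slabs.append(
            Slab(
                label=lab,
                axis=axis,
                start_mm=a,
                end_mm=b,
                start_coord=hi - a,  # positions run from the +coordinate border
                end_coord=hi - b,
            )
        )
    return slabs


def plan_grossing(specimen: SpecimenModel, plan: GrossingPlan) -> list[Slab]:
    """Derive labeled slabs from a grossing plan.

    n cuts produce n+1 slabs, labeled from the start border (A first for
    the default anterior→posterior axis). Secondary-family slabs follow,
    labeled numerically. Raises :class:`PlanError` for cuts outside the
    specimen extent.
    """
    slabs = _family_slabs(specimen, plan.primary_axis, plan.cut_positions, False)
    for s in slabs:
        s.section_face = plan.section_face
    if plan.secondary_axis is not None:
        sec = _family_slabs(
            specimen, plan.secondary_axis, plan.secondary_cut_positions, True
        )
        for s in sec:
            s.section_face = plan.section_face
        slabs.extend(sec)
    return slabs


def slab_for_cut(slabs: list[Slab], axis: str, cut_index: int, section_face: str) -> Slab:
    """The slab whose histological section lies on cut ``cut_index`` (0-based).

    With ``section_face='start'`` cut i is the start face of slab i+1; with
    ``'end'`` it is the end face of slab i.
    """
    family = [s for s in slabs if s.axis == axis]
    i = cut_index + 1 if section_face == "start" else cut_index
    if not (0 <= i < len(family)):
        raise PlanError(f"cut index {cut_index} has no slab with a section on it")
    return family[i]


def grossing_site_distances(specimen: SpecimenModel, plan: GrossingPlan) -> list[dict]:
    """Distance from each cut plane to the specimen border on both sides.

    Mirrors the pathologist's macroscopic bench measurements and is used to
    cross-check a supplied plan. Returns one record per cut (primary family
    first) with border labels as keys.
    """
    out = []
    families = [(plan.primary_axis, plan.cut_positions)]
    if plan.secondary_axis is not None:
        families.append((plan.secondary_axis, plan.secondary_cut_positions))
    for axis, positions in families:
        k, start_label, end_label = AXES[axis]
        lo, hi = specimen.axis_extent(axis)
        extent = hi - lo
        for i, c in enumerate(positions):
            if not (0.0 < c < extent):
                raise PlanError(f"cut at {c:g} mm is outside the specimen")
            out.append(
                {
                    "axis": axis,
                    "cut_index": i,
                    start_label: c,
                    end_label: extent - c,
                }
            )
    return out
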