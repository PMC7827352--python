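"""End-to-end case pipeline: scan STL in, margin report and print-ready
STL pair out.

Stages (each logged with its parameters and residuals):

    read -> make_watertight -> simplify -> orient -> plan grossing ->
    register contours -> reconstruct tumor -> margins -> shrinkage ->
    export

The pipeline is configured by a YAML case file and is deterministic for a
fixed config: the report JSON and exported STLs are byte-identical across
runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import grossing as gr
from . import mesh_core
from .contour_registration import load_contours, register_contour
from .errors import ExportError, FormatError, PlanError
from .margins_shrinkage import ShrinkageFactor, apply_shrinkage, directional_margins
from .mesh_core import SurfaceMesh
from .specimen_frame import Fiducial, InkLinePlane, SpecimenModel, orient_specimen
from .tumor_reconstruction import reconstruct_tumor

log = logging.getLogger(__name__)


@dataclass
class CaseConfig:
    """Validated configuration of one reconstruction case."""

    scan_stl: Path
    contours_json: Path
    fiducials_json: Path
    output_dir: Path
    facet_budget: int = mesh_core.DEFAULT_FACET_BUDGET
    grossing_plan: gr.GrossingPlan = None
    registration_residual_tol_mm: float = 1.0
    containment_tol_mm: float = 2.0
    shrinkage: ShrinkageFactor = field(default_factory=ShrinkageFactor)
    reconstruction_mode: str = "validate"
    end_cap: str = "apex"
    n_points: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "CaseConfig":
        path = Path(path)
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except FileNotFoundError:
            raise FormatError(f"config file not found: {path}") from None
        except yaml.YAMLError as exc:
            raise FormatError(f"config file {path} is not valid YAML: {exc}") from exc
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        base = path.parent

        def p(key):
            try:
                return (base / raw["paths"][key]).resolve()
            except KeyError:
                raise FormatError(f"config lacks paths.{key}") from None

        g = raw.get("grossing", {})
        plan = gr.GrossingPlan(
            cut_positions=g.get("cut_positions", []),
            primary_axis=g.get("primary_axis", "anterior-posterior"),
            secondary_axis=g.get("secondary_axis"),
            secondary_cut_positions=g.get("secondary_cut_positions", []),
            section_face=g.get("section_face", "start"),
        )
        tol = raw.get("tolerances", {})
        shr = raw.get("shrinkage", {})
        rec = raw.get("reconstruction", {})
        cfg = cls(
            scan_stl=p("scan_stl"),
            contours_json=p("contours_json"),
            fiducials_json=p("fiducials_json"),
            output_dir=(base / raw["paths"].get("output_dir", "out")).resolve(),
            facet_budget=int(raw.get("facet_budget", mesh_core.DEFAULT_FACET_BUDGET)),
            grossing_plan=plan,
            registration_residual_tol_mm=float(
                tol.get("registration_residual_mm", 1.0)
            ),
            containment_tol_mm=float(tol.get("containment_mm", 2.0)),
            shrinkage=ShrinkageFactor(
                fraction=shr.get("fraction", 0.0), mode=shr.get("mode", "isotropic")
            ),
            reconstruction_mode=rec.get("mode", "validate"),
            end_cap=rec.get("end_cap", "apex"),
            n_points=int(rec.get("n_points", 100)),
            seed=int(raw.get("seed", 0)),
        )
        for t in (cfg.registration_residual_tol_mm, cfg.containment_tol_mm):
            if t <= 0:
                raise FormatError("tolerances must be > 0")
        return cfg


def load_fiducials(path) -> tuple[list[Fiducial], dict]:
    """Read the specimen JSON: fiducials (scan coordinates) and ink lines
    (anatomical coordinates, as marked on the oriented digital model)."""
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"fiducial file not found: {path!r}") from None
    except json.JSONDecodeError as exc:
        raise FormatError(f"fiducial file {path!r} is not valid JSON: {exc}") from exc
    fids = [Fiducial(rec["label"], rec["xyz"]) for rec in data.get("fiducials", [])]
    ink = {}
    for rec in data.get("ink_lines", []):
        ink[rec["label"]] = InkLinePlane(
            rec["label"], rec["point"], rec["normal"], rec["direction_hint"]
        )
    return fids, ink


def run_pipeline(config: CaseConfig):
    """Execute a full case; returns (final MarginReport, output paths)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    mesh = mesh_core.read_surface(config.scan_stl)
    mesh = mesh_core.make_watertight(mesh)
    mesh = mesh_core.simplify(mesh, config.facet_budget)

    fids, ink = load_fiducials(config.fiducials_json)
    specimen = orient_specimen(mesh, fids)
    specimen.ink_lines = ink
    log.info("orientation residual: %.4f mm", specimen.residual_mm)

    slabs = gr.plan_grossing(specimen, config.grossing_plan)
    by_label = {s.label: s for s in slabs}

    contours = load_contours(config.contours_json)
    primary, secondary = [], []
    for c in contours:
        slab = by_label.get(c.slab_label)
        if slab is None:
            raise PlanError(f"contour names unknown slab {c.slab_label!r}")
        placed = register_contour(
            c,
            slab,
            specimen,
            residual_tol_mm=config.registration_residual_tol_mm,
            containment_tol_mm=config.containment_tol_mm,
        )
        if slab.axis == config.grossing_plan.primary_axis:
            primary.append(placed)
        else:
            secondary.append(placed)

    thickness = None
    if len(primary) == 1:
        thickness = by_label[primary[0].slab_label].thickness_mm
    tumor, recon_report = reconstruct_tumor(
        primary,
        secondary or None,
        mode=config.reconstruction_mode,
        end_cap=config.end_cap,
        n_points=config.n_points,
        slab_thickness_mm=thickness,
    )

    report = directional_margins(tumor, specimen)
    report = apply_shrinkage(report, config.shrinkage)
    report.notes.append(
        f"slides taken on the {config.grossing_plan.section_face} face of each slab"
    )
    full = {
        "margins": report.to_dict(),
        "reconstruction": recon_report,
        "registration_residuals_mm": {
            f"{p.slab_label}:{p.index}": p.residual_mm for p in primary + secondary
        },
        "orientation_residual_mm": specimen.residual_mm,
        "facet_budget": config.facet_budget,
        "specimen_faces": specimen.mesh.n_faces,
        "tumor_faces": tumor.n_faces,
        "grossing_sites": gr.grossing_site_distances(specimen, config.grossing_plan),
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(full, indent=1, sort_keys=True))
    paths = export_print_pair(specimen, tumor, out)
    paths["report"] = report_path
    log.info("pipeline complete; report at %s", report_path)
    return report, paths


def export_print_pair(specimen: SpecimenModel, tumor: SurfaceMesh, outdir) -> dict:
    """Write the aligned specimen-shell / tumor STL pair plus a manifest.

    The two binary STLs share the anatomical frame, the convention used by
    dual-material (clear shell + opaque tumor) printing; the manifest
    records frame and units.
    """
    if specimen is None or tumor is None:
        raise ExportError("both specimen and tumor are required for print export")
    if not specimen.mesh.is_watertight:
        raise ExportError("specimen shell is not watertight; repair before export")
    if not tumor.is_watertight:
        raise ExportError("tumor mesh is not watertight")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec_path = outdir / "specimen.stl"
    tumor_path = outdir / "tumor.stl"
    mesh_core.write_surface(specimen.mesh, spec_path)
    mesh_core.write_surface(tumor, tumor_path)
    manifest = {
        "units": "mm",
        "frame": "anatomical (+x left, +y anterior, +z superior)",
        "convention": specimen.frame.convention,
        "specimen_stl": spec_path.name,
        "tumor_stl": tumor_path.name,
        "specimen_faces": specimen.mesh.n_faces,
        "tumor_faces": tumor.n_faces,
        "specimen_bounds_mm": specimen.mesh.extents.tolist(),
        "tumor_bounds_mm": np.asarray(tumor.extents).tolist(),
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {"specimen": spec_path, "tumor": tumor_path, "manifest": man_path}
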