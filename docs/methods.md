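# Methods

## Problem and model

A soft-tissue resection specimen (e.g. a tongue carcinoma block) is
scanned with a structured-light table scanner before fixation, grossed
into slabs along directions the pathologist chooses freely, and each
slab's histological slide is annotated with a closed tumor outline. The
package reconstructs the tumor as a solid inside the digital specimen and
reports surgical margins. The governing approximation, stated once and
used everywhere, is piecewise linearity: between two adjacent annotated
sections the tumor boundary is interpolated linearly, exactly the
approximation a pathologist applies mentally when reading a finite set of
slides. No curvature model, no implicit surface, no branching-topology
solver; the faceted ("angular") appearance of the result is a faithful
display of what the slides support.

Because the 3D reference is the scanned outer surface rather than a stack
of mutually registered slides, the cumulative misregistration ("banana
effect") of slice-stacking reconstructions cannot occur: every slide is
registered independently to the specimen frame via its ink marks.

## Coordinate conventions

Anatomical frame: right-handed, millimetres; +x patient-left, +y
anterior, +z superior (mucosal), −z deep. The frame is fit by
centroid-aligned orthogonal Procrustes from labeled needle fiducials:
each fiducial's offset from the fiducial centroid is matched to its
convention direction scaled by the offset length. The unconstrained
orthogonal optimum is inspected first; a negative determinant means the
labels are mutually inconsistent (a physical impossibility rather than a
numerical nuisance), so a reflection is rejected with an error instead of
being silently corrected. The anatomical origin is the fiducial centroid.

Grossing positions are distances in millimetres from the border where
slicing starts (anterior, for the default anterior→posterior axis),
because that is the measurement the pathologist records at the bench.
Slab A is the most anterior; a perpendicular family is numbered 1, 2, ….
Each slab contributes one slide, by convention on its *start* (anterior)
face; the convention is configurable (`section_face`) and echoed in every
report, since the case documentation must state which face a slide
represents — this is the single largest geometric convention in the
pipeline.

## Mesh repair and simplification

Scan holes are detected as boundary-edge loops, projected onto their
best-fit plane, and ear-clipped — a deliberately *planar* patch that
mirrors what scanner software does when asked for a watertight model, and
that honestly displays the information lost at a blind spot. Loops whose
planar projection self-intersects raise a repair error rather than being
patched arbitrarily. The repair is idempotent.

Simplification is Garland–Heckbert quadric edge collapse, implemented
in-package: per-vertex quadrics accumulate face-plane squared distances;
the collapse target is the best of the two endpoints and the midpoint
(avoiding ill-conditioned optimal-placement solves); the priority queue
breaks cost ties by the lowest vertex-index pair, so the result is
deterministic. Collapses violating the link condition, inverting a face
normal, or degenerating a face are skipped; every accepted collapse on a
closed manifold removes exactly two faces, so watertightness is
preserved and an even target (the default 20,000 facets) is hit exactly.
The 20,000 default balances surface fidelity against interactive CAD
handling of the shell. Measured on an ~82k-facet phantom scan, decimation
to 20,000 changes enclosed volume by ~0.03 %.

Volumes use the divergence theorem on the oriented surface; the test
suite cross-checks with an independent column-integration oracle.

## Ink-line registration

Each ink line is modeled as the plane containing its drawn stripe
(point + normal + drawing-direction hint): the dorsal line runs
antero-posteriorly on the dorsal surface, the second line perpendicular
to it on a lateral surface. A section plane intersects each stripe plane
in a line — the trace the pathologist sees as a colored mark on the
slice face. Slide marks are *directed* segments (the drawing direction),
which is what makes a mirror-mounted slide detectable: if the signed
angle from dorsal to perpendicular mark differs in sign between slide
and specimen, a `FlippedSlideError` is raised. Otherwise the rotation is
fixed by the dorsal directions and the translation by the intersection
point of the two lines — the intersection being the most robust feature
given that tissue dyes spread. The residual (RMS perpendicular distance
of mapped mark endpoints to their trace lines) is reported per slide and
gated by a configurable tolerance (default 1.0 mm); containment of the
placed outline in the specimen cross-section is checked to 2.0 mm with a
warning. Both tolerances are engineering defaults: no empirical
registration accuracy is available to calibrate them, so they are
surfaced in the report rather than asserted.

## Lofting

Outlines are resampled to a common count (default 100) uniformly by arc
length, starting at the first vertex (making resampling idempotent).
Correspondence between consecutive rings is a cyclic shift minimizing the
summed squared inter-vertex distance; the smallest shift wins ties. This
is deliberately weaker than dynamic time warping: it keeps the
construction deterministic and matches the plane-between-outlines
approximation. Disjoint outline groups (`index`) loft to separate
components.

Terminal outlines are closed either flat in their planes or with a
pyramidal apex half an inter-slice spacing beyond the last outline. The
lofting primitive defaults to flat caps (so prisms and frusta reproduce
their closed forms exactly), but the case pipeline defaults to apex caps:
a lesion almost never ends exactly at its last positive slide, and the
half-spacing apex is the midpoint estimate of where it ends between that
slide and the first negative one. Without it, terminal truncation
dominates the volume error at routine slice spacings (for an r = 6 mm
spherical lesion at 3 mm spacing, flat caps lose ≈25 % of the volume,
apex caps ≈9 %). The same reasoning fixes the phantom's default grossing
phase: cuts are placed so the lesion center falls midway between two cuts,
the symmetric digitization a serial-slicing plan produces.

The perpendicular outline family is, by default, not merged into the
body: with no record of how two lofted families should be combined, the
honest default treats the second family as an independent check, reported
as per-plane area-overlap (IoU) between each secondary outline and the
loft's cross-section. A `union` mode exists and falls back to validation
with a warning when no mesh-boolean backend is available.

## Margins

Every specimen face is labeled with the anatomical direction whose axis
is most parallel to its outward normal (six-way argmax; the labeling is
exportable for audit). The margin toward a direction is the minimum
Euclidean distance from the tumor surface to that face class, evaluated
symmetrically: tumor vertices against class triangles and class vertices
against tumor triangles, each by exact point-to-triangle distance over
candidates from a KD-tree on triangle centroids, with an exact
lower-bound fallback (centroid distance minus circumradius) so pruning
can never change the result. The closest margin is the global minimum —
by construction identical to the minimum over classes. A tumor
protruding through the shell yields 0 mm in the affected directions with
a warning; a direction with no faces (e.g. a margin surface removed
separately at surgery) is reported absent.

One consequence of the class definition worth knowing: class boundaries
lie where face normals tip past 45°, so a margin can be attained at a
class *rim* rather than at the anatomical pole — e.g. a sphere-in-sphere
tumor displaced 0.5 mm toward deep has a deep margin of 0.5 mm but a
superior margin of ≈1.38 mm (the rim), not the 1.5 mm pole distance.
The exported face labeling makes such cases auditable.

Shrinkage: specimens are scanned fresh, slides measured after formalin
fixation; oral SCC shrinks 14–24 % depending on orientation. Corrected
length = measured/(1−f) per axis (isotropic or per-axis); volumes scale
by the product of axis factors; original and corrected values are both
retained. The default is f = 0 with a logged reminder, because the
appropriate factor is case- and orientation-specific. In per-axis mode
the margin correction scales each directional margin by its own axis
factor, an approximation when the closest approach is oblique.

## Phantom

The specimen is a superellipsoid |x/a|^p + |y/b|^p + |z/c|^p = 1
(default semi-axes 20×15×10 mm, p = 4): closed-form volume
8abc·Γ(1+1/p)³/Γ(1+3/p), analytic normals, and a shape range from
ellipsoid to box. The tumor is an ellipsoid (default semi-axes
6×4×3 mm, centered), optionally rotated/offset; plane sections are exact
conics, polygonized at 200 vertices. Simulated scans mesh the surface by
radial mapping of a subdivided icosahedron (subdivision 5 ≈ 20k facets;
6 ≈ 82k, scan-grade), then optionally add a smooth radial cosine-field
perturbation of bounded amplitude (default stand-in 0.2 mm) and punch
0–3 circular blind-spot holes of 1–5 mm at separated seeded sites.
Grossing simulation emits per-cut outlines and directed ink marks in a
seeded random slide frame, with optional knife tilt (bounded seeded
angle; downstream still assumes straight cuts) and ink jitter (bounded
endpoint displacement, default stand-ins 3° and 0.5 mm). All randomness
derives from the single phantom seed via per-stage generators, so
identical seeds give bit-identical outputs regardless of call order.

What the phantom does *not* emulate: bulk soft-tissue deformation
between scan and grossing (the unsolved fixation/handling problem —
surface noise is not a deformation model), non-elliptical or infiltrative
tumor borders, slide-processing distortion, and image-level artifacts.
Passing phantom tests therefore certifies the geometry pipeline, not the
biological fidelity of any clinical case.

Ground-truth margins are recorded from a 10⁵-sample analytic oracle
(seeded dense sampling of both analytic surfaces, labeled by analytic
normals). Note a subtlety used in the tests: margins attained on a class
rim vary to first order along the surface, so sampled-oracle and
mesh-based values agree only to ~0.1–0.2 mm there; exactness of the
distance computation itself is instead certified against a brute-force
evaluation on the same meshes (identical to first order and to 1e-6 mm
on symmetric cases).

## Numerical choices

* Vertex weld tolerance 1e-6 mm on STL read; degenerate faces dropped
  with a warning. STL carries no units; mm is fixed by convention.
* Ear clipping clips the lowest-index valid ear first (deterministic);
  intended for the small loops and sections that occur here.
* Cyclic-shift correlation is rounded to 1e-9 before the argmax so
  floating-point noise cannot flip a tie.
* Plane bases are constructed by a fixed rule (u = z×w normalized,
  v = w×u; x-based fallback for vertical normals) so 2D coordinates are
  reproducible across modules.
* Reports are serialized with sorted keys and no timestamps; STL export
  is byte-stable — two runs of one case produce identical bytes.
* Ink-line validation requires marks within 90°±15° of perpendicular;
  simulated marks are 10 mm long so bounded jitter cannot break this.

## Problem sizes in the shipped checks

The test and acceptance workloads use icosphere subdivision 4–5 meshes
(5k–20k facets), one subdivision-6 (82k) mesh for the facet-budget check,
20 seeded ellipsoid phantoms for margin recovery, and sphere-recovery
runs at 4/3/2/1 mm slice spacings — sizes chosen so the full suite
exercises every stage at scan-realistic density while remaining quick on
one CPU.

## Known limitations

* Hole patches are planar; a hole across a sharp ridge would flatten it
  (faithful to the modeled scanner behaviour, but information is lost).
* Margins are mesh-to-mesh vertex/triangle minima; the true
  surface-to-surface minimum can involve an edge-edge pair, a
  second-order effect at the mesh densities used.
* `union` reconstruction requires an external boolean engine; without
  one the pipeline always validates instead.
* Cross-section polygons treat nested section loops as solid (no holes),
  adequate for the convex-ish bodies handled here.
* Shrinkage correction rescales reported numbers; it does not model
  differential shrinkage within a specimen.
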