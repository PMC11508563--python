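# Methods

`osteoplan` implements the virtual half of a 3D-assisted corrective
osteotomy for an intra-articular tibial-plateau malunion: quantify the
deformity, plan a curved cut as a fence of depth-controlled drill
trajectories, generate the printable guides that transfer the plan to
surgery, and score the achieved reduction against the plan. This note
records the models, conventions and numerical choices, and what the
synthetic validation does and does not show.

## Coordinate and reporting conventions

All geometry lives in a right-handed, patient-like frame in mm:
x anterior(−)→posterior(+), y lateral(−)→medial(+) for a right leg
(the lateral/medial reading flips for a left leg via
`AnatomicalFrame.side`), z caudal(−)→cranial(+). Angles are degrees at
API boundaries, radians internally.

A fragment displacement is reported as six parameters: translations
(Δx, Δy, Δz) of the rotation centre projected on the frame axes, and
rotations (ζ sagittal about y, θ coronal about x, φ axial about z)
taken as **intrinsic z–x–y Euler angles**, i.e. `R = Rz(φ) Rx(θ) Ry(ζ)`
in the anatomical basis. The literature that reports these three named
angles rarely states the order; one order had to be fixed, and the
same convention is used when the phantom generator implants a
deformity, which is what makes round-trip recovery well defined. The
rotation centre is the area-weighted centroid of the *target*
(template or planned) fragment surface; translations depend on this
centre, so it is part of the convention, not an implementation detail.

## Quantification (Q3DCT) pipeline

1. **Segmentation** — threshold at ≥ 226 HU (inclusive), 26-connected
   seeded region growing, seeded split of thin bridges
   (erode–label–regrow), marching cubes at the 0.5 iso-level. Voxels at
   metal attenuation (≥ 3000 HU) are excluded with a warning; no
   artifact correction is attempted. Voxel indexing is 0-based, a
   voxel's world coordinate is its centre, volume extents are
   half-open.
2. **Mirroring** — the contralateral surface is reflected across the
   frame's mid-sagittal plane (overridable) with windings flipped.
3. **Shaft alignment** — point-to-plane ICP of the mirrored template
   onto the affected bone, restricted to the template's shaft region
   (default: faces in the distal 40 % of the proximal–distal extent, a
   reproducible surrogate for a manual pick). No trimming: the shaft is
   intact on both sides, and trimming preferentially discards the
   high-residual crest points that pin the axial rotation (observed as
   a ~1° twist bias before this choice was made). Correspondences come
   from a KD-tree over the dense target vertices; two deterministic
   starts (identity, centroid offset) are run and the better final fit
   kept, because the moving points are a sub-region whose centroid can
   be far from the whole-target centroid. Cap 100 iterations,
   convergence at 1e-6 mm rms change or a <1e-7 pose step;
   non-convergence returns best-so-far flagged.
4. **Fragment fit** — trimmed (90 % inlier) point-to-point ICP pulls
   the fragment in from large offsets, then a trimmed point-to-plane
   stage refines; point-to-plane is unbiased under surface
   re-discretisation, which the ±0.2 mm recovery contract requires.
   Overlap below 50 % flags `low_confidence`.
5. **Decomposition** — the inverse of the fitted transform (template
   pose → malunited pose) is decomposed as above. |θ| within 0.1° of
   90° sets a gimbal flag.

The postoperative assessment is the same engine without mirroring:
shaft-align the postoperative model onto the planned model, fit the
fragment, decompose; context `planned_vs_postop`.

Reports are invariant to moving patient *and frame* rigidly together
to registration numerics (~1e-3 mm in tests); exact 1e-6 invariance is
not claimed because KD-tree correspondences are not exactly
equivariant in floating point.

## Osteotomy planning

The old fracture line is supplied as a surface polyline (no automatic
detection). It is resampled finely, each point gets the approach
vector orthogonalised against the local trace tangent, directions are
smoothed (three 1-2-1 passes), and holes are picked at uniform spacing
measured **perpendicular to the drill axes** (2.5 mm default,
centre-to-centre): where the trace runs partly along the approach,
plain arc-length spacing would pinch adjacent bores together. Points
whose direction tilts more than 30° from the approach are dropped as
undrillable from that exposure. By default the fence is parallel
(`fan_scale = 0`, all drills share the mean direction) — entries on a
convex cortex give a converging fan whose focus can sit shallower than
the drill depth, and parallel tubes are also what keeps guide bores
from merging; a positive `fan_scale` restores the fanned fence and is
automatically halved until no two drill segments cross.

Depth control: per trajectory, depth = (entry → far-cortex exit along
the axis) − posterior margin (default 2.0 mm; the clinical goal —
protecting the posterior neurovascular structures — is stated in the
field, the number is this package's choice), clamped ≥ 1 mm and never
reaching the exit; shallower paths are flagged `too_shallow`. The
ordered segments rule the planned cut surface; self-intersecting
fences are rejected. Planning is deterministic: identical inputs give
bit-identical plans.

The drill diameter defaults to 1.8 mm, the drill used through this
kind of guide. Hole count/spacing in the original procedure are not
reported; 2.5 mm spacing leaves cortical bridges that the osteotome
splits, as in the procedure itself.

## Guides

Three printable solids share one set of K-wire reference trajectories
(default three wires, Ø 2.0 mm, pairwise non-parallel or ≥ 5 mm apart
so seating is unique):

* **Cutting guide** — bone-conforming shell over the drill field, an
  anterior-shaft extension distal to the tuberosity, and a conforming
  extension over the in-situ plate; one tube per trajectory with the
  Panflute length law `tube_i = working_length − depth_i − standoff`,
  so a fixed-length drill inserted to its stop reaches exactly the
  planned depth. Outer tube walls may merge (the panpipe profile);
  *bores* closer than drill diameter + 0.5 mm wall are rejected.
* **Intermediate guide** — anterolateral wrap footprint carrying drill
  channels that replicate the new plate's distal screw-hole axes, plus
  the K-wire channels.
* **Reposition guide** — negative imprint of the new plate at fit
  clearance plus a convex-hull bridge to the wire seats; seating it on
  the wires with the plate screwed to the fragment forces the fragment
  to the planned pose. Seating is verified in software as a
  Gauss-Newton pose solve on wire-line and plate-contact constraints;
  a rank-deficient constraint system (parallel wires, missing wires)
  raises `underdetermined`.

The proprietary anatomical plate is unavailable, so a parametric slab
plate swept on the bone surface stands in; old and new plates share
the proximal hole pattern so the new plate reuses the old proximal
screw holes in the fragment. Channel bores get the tool diameter +
0.1 mm print clearance; shells float 0.2 mm off bone and plate —
common FDM/SLS practice, exposed in `GuideConfig`.

### Solid modelling

No B-rep boolean kernel is assumed. Solids are composed on voxel grids
as clamped signed-distance fields (positive inside): surfaces are
sampled finer than the grid, near-surface voxels take signed heights
against the nearest sample's normal, far voxels are classified per
connected component (no border flood fill, so solids may be cropped by
the grid), booleans are per-voxel max/min, and the zero level set is
re-extracted with marching cubes. Because the field carries sub-voxel
distances, surfaces land well within one pitch (0.3 mm default) of
their true position; knife-edge contacts are avoided by offsetting the
shell half a pitch beyond the carved clearance zone, and residual
sliver bodies below 1 mm³ are dropped. Offset shells are evaluated
directly as fields on the compose grid (no intermediate mesh). Every
exported guide must be watertight, consistently wound, a single body,
with every channel an unobstructed through-path along its axis and
bone interpenetration under 1 mm³; export writes deterministic binary
STL plus a JSON manifest (tube table, wire table, SHA-256 checksums).

Degenerate ray–edge grazings during ray casting are resolved by a
deterministic 1e-6 mm origin nudge along a fixed tie-break direction,
never randomness.

## Synthetic phantom

The phantom is a *stylised* proximal tibia: a tapered shaft with the
triangular (anterior-crest) cross-section of a real tibia, a
superellipsoid plateau with posterior condylar bulge and ~7° posterior
slope, and a tuberosity bump, blended as smooth implicit solids and
meshed by marching cubes (generation pitch 0.5–0.8 mm depending on
context; the surfaces are exact to the implicit model at that scale).
It is **not** a statistical tibia — the pipeline's contracts are
geometric, so anatomical realism beyond shape character is
unnecessary. The crest, bulge and slope are load-bearing: they are
what makes shaft and fragment registration well-posed, exactly as real
cortical landmarks do.

The fracture is a cubic Bézier sheet `y = B(x, z)`, linear along x
(so straight drills can reproduce it exactly) and curved through the
coronal plane, separating a lateral plateau fragment; the true
fracture-line geometry of the study case is unknown, so this sheet is
a plausible invention and labelled as such. `induce_malunion` rejects
sheets that do not split the bone into exactly two components. The
fragment is displaced by a transform built with the morphometry
convention about the fragment-surface centroid — the implanted truth —
with an optional spherical articular depression subtracted. The
contralateral bone is the exact mirror plus optional Gaussian surface
noise along vertex normals (`asymmetry_noise_sigma`, default 0; 0.3 mm
reproduces folded-normal surface-distance statistics in [0.2, 0.3] mm).
All randomness derives from the spec seed; identical specs give
identical bytes.

Simulated CT maps interior voxels to trabecular bone (300 HU) with a
2 mm cortical shell (700 HU), a 10 mm soft-tissue envelope (40 HU),
air (−1000 HU) beyond, blurred by a fixed 0.4 mm scanner PSF; defaults
chosen so the 226 HU threshold separates bone from soft tissue.
An optional plate slab at 8000 HU adds deterministic streak-plus-noise
perturbation within 15 mm, which degrades segmentation Dice
monotonically with amplitude — the in-situ-hardware scatter problem is
simulated, not corrected.

Named fixtures transcribe the study case exactly: `study_case`
implants (5.4, −2.9, −5.9) mm and (10.2, 23, 0.8)° (posterior,
lateral, caudal displacement of a right lateral fragment, plus a
depression defect); `study_postop` implants the achieved-vs-planned
residual (0.5, −1.0, 0.6) mm, (3.8, 1.3, 0.1)°; `clean` is the
zero-deformity control; `scatter` adds plate and noise.

In closed-loop tests the random malunions draw the medial-lateral
translation lateral-only: a split fragment displaces away from the
metaphysis; a medial draw would bury it inside solid bone, which is
not a physical malunion and removes the surface the registration needs.

## What the validation shows — and does not

Recovering the implanted parameters end-to-end (CT simulation →
segmentation → mirroring → registration → decomposition, tolerance
±0.2 mm / ±0.5°) demonstrates that no stage of the *software* corrupts
the measurement at clinical CT resolution, including under 0.3 mm
bilateral asymmetry noise and simulated scatter. It does not
demonstrate accuracy on real anatomy: real bones differ bilaterally in
shape and not just by smooth noise, real fracture lines are rougher
than a Bézier sheet, segmentation of real trabecular margins is harder
than of a two-compartment phantom, and the physical execution steps
(drilling, osteotome, seating a real guide on cartilage and soft
tissue) are entirely outside scope. Region labels ("this is the
fragment") are inputs, as they are in the clinical workflow where a
human picks them; on phantoms they are transferred from ground truth
by nearest-face proximity.

Known limitations: no saw/osteotome mechanics, no soft-tissue
collision checks (the patellar-tendon interference reported
clinically is documented, not modelled), no elevation of the small
central depressed fragment as a separate body, no DICOM networking, no
FEM, no statistical shape model. Marching cubes shrinks an isolated
voxel to its inscribed octahedron (1/6 volume) — the single-voxel
discretisation floor. Problem sizes in the shipped tests (generation
pitch 0.6–0.8 mm, CT at 0.5 mm, 20-seed loops) were chosen as the
coarsest scales at which the contracts above hold with a safety
margin; the quantification error at those scales is a few hundredths
of a millimetre, an order below the acceptance tolerance.
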