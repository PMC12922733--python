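# Methods

This note documents the models, parameters and numerical choices behind
`pdmap`, and what the synthetic-data tests do and do not establish about
real microscopy data.

## The measurement problem

Plasmodesmata pit fields appear in confocal stacks as punctate marker
fluorescence lying in the cell walls. Individual plasmodesmata are below
confocal resolution; the resolvable unit is the pit field. The quantity of
interest is therefore not a count of channels but the amount, density and
spatial arrangement of pit-field signal on each cell–cell interface,
resolved by cell type (root layer) and wall orientation. All lengths are
micrometres; arrays are stored `(z, y, x)` while user-facing coordinates
and voxel sizes are `(x, y, z)`.

## Segmentation

The wall stain outlines cells as bright ridges around dark interiors.
Segmentation applies an isotropic Gaussian blur of radius (sigma) 0.5 μm —
converted per axis to voxel units, so anisotropic stacks blur isotropically
in physical space — followed by marker-based watershed flooding of the
blurred wall intensity. "Autoseeded" is realised as: seeds are the
26-connected components of voxels below the `seed_threshold_quantile`
(default 0.5) of the blurred intensity, i.e. the dark cell interiors.
Components touching the stack border are pooled into a single background
seed whose basin becomes label 0 — the mountant around the root. Labels
smaller than `min_cell_voxels` (default 64) are merged into their
largest-contact neighbour, a deterministic stand-in for interactive
proofreading. The blur uses a kernel truncated at 6 sigma so the impulse
response matches the analytic Gaussian to better than 1e-6 of its peak.

## Surface meshing

The tissue surface is built once as a **cell-complex**: the label volume is
resampled (nearest neighbour) onto an isotropic grid with step `cube_size`
— 0.5 μm for abundance analyses, 0.2 μm for spatial statistics — and every
grid face separating two labels becomes a pair of triangles tagged with the
owning cell pair (0 = exterior). Consequences that hold *by construction*:
each wall patch is one shared object per adjacent pair; a cell's interface
areas partition its surface exactly; the a–b and b–a patches are identical.

Two sub-grid corrections then remove rasterisation bias, playing the role
that isovalue interpolation plays in marching cubes:

- **Wall snapping.** Each two-label vertex moves to the crossing of the two
  cells' Gaussian-blurred indicator functions (sigma 0.75 × the sampling
  scale), searched along the lattice axes it has faces on (range ±1.6 ×
  scale); the nearest crossing wins, and crossings where both indicators
  vanish (far field) are rejected. Blurring the indicators makes the
  crossing surface smooth, so snapped walls carry no voxel-scale ripple.
- **Junction snapping.** Vertices where 3–4 cells meet are placed by a
  damped Gauss–Newton solve driving each incident blurred indicator to its
  solid-angle fraction, re-estimated each step from widely blurred (2 ×
  scale) indicators at the current position. A Gaussian-blurred indicator
  of a wedge evaluates at the wedge apex to exactly its solid-angle
  fraction, so this target is unbiased even where the meeting regions
  subtend unequal angles (e.g. a wall ending on a flat outer surface).
  Two-label vertices whose indicators sum well below 1 (phantom contacts —
  rasterisation slivers between cells that only meet along a line) are
  detected and re-snapped as junction vertices, collapsing the sliver.

Smoothing applies the workflow's 10 uniform neighbourhood-averaging passes.
Wall vertices average over all neighbours with relaxation 0.1; junction
vertices average only over other junction vertices (including quad
diagonals, which junction zigzags land on) with relaxation 0.3, i.e. along
their junction curve — preserving the cellular connectivity geometry. The
relaxations are calibrated at the voxel scale and multiplied by
`(max(cube, voxel)/cube)²` when the grid oversamples the voxels, keeping
the physical smoothing length resolution-independent. With these choices a
10 μm cube meshes to within 5 % of 600 μm², the analytic cylindrical-sector
wall areas of the default synthetic root are recovered within 7 % (max; the
mean error is a few tenths of a percent), and 0.2 vs 0.5 μm meshes agree
within 5 %.

Interfaces below 3 μm² are removed (boundary value kept: area ≥ 3 μm²
survives). The exterior surface is meshed and measurable but excluded from
all normalisations and statistics.

## Annotation

The root axis is the first principal direction of the foreground voxel
cloud, oriented so axial position grows with z; an anisotropy ratio
(√(λ₁/λ₂)) below 1.5 raises an error (no dominant axis). Cells receive
cylindrical coordinates (s, r, θ) of their centroids and are assigned to
concentric layers by 1-D gap clustering of radial distance: sorted radii
are split at the largest gaps into as many bands as there are layer names
(outermost first). When a sample contains unnamed inner tissue, pass
`n_bands > len(layer_names)`; the extra inner bands are labelled
`inner_core` and excluded from reported classes. Gap clustering is
invariant to uniform scaling.

Interface orientation uses the area-weighted mean unit normal of the patch
(triangle normals are consistently oriented from cell_a to cell_b, so
contributions reinforce) compared against the local cylindrical frame at
the patch centroid: the largest absolute component among axial, radial and
circumferential wins; a top-two margin under 0.05 leaves the interface
`unclassified` and out of class statistics. Interaction classes are the
alphabetically ordered layer-pair names joined with "–" (same-layer pairs
collapse to the layer name).

## Projection, trim, binarisation

Each mesh vertex samples the marker stack by trilinear interpolation along
its normal at steps of at most half a voxel within ±0.5 μm, taking the
maximum (mean available as an option); max projection is robust to the
sub-voxel offset between the meshed surface and the true wall for punctate
signal. Background is removed by a trim threshold `T0 · f^l` for a vertex
whose deeper owning cell lies in layer l, with decay `f` (default 0.8)
compensating photobleaching and depth-dependent signal loss in real
stacks. When `T0` is unset it defaults to the 97.5th percentile of the
marker stack — a "low" trim suited to sparse signal of unknown intensity.
Surviving signal is binarised to `max_value` (default 1): the analysis
asks where pit-field signal is present, not how bright it is. Scaling the
stack and `T0` jointly leaves the binary signal bit-identical.

For **synthetic** runs the generator deliberately renders no depth
attenuation (see below), so analyses of synthetic stacks set `f = 1`
(nothing to compensate) and an explicit `T0 = 0.2` — between the noise
floor (sd 0.02) and the spot amplitude (1.0). The quantile default exists
for real stacks; on a nearly-empty synthetic channel it would by
construction mark ~2.5 % of noise voxels positive.

## Quantification

Total Signal is the barycentric-area-weighted sum of binary signal over
the patch (μm² at `max_value` 1); Signal Density divides by patch area.
Both are normalised per sample to percentages summing to 100 over the
retained cell–cell interfaces, trading absolute intensity for
between-sample comparability. Moran's I is computed per interface on the
0.2 μm mesh with unweighted, unnormalised binary edge adjacency — the
minimal reading that reproduces the anchor values (checkerboard −1;
two-block → +1; randomisation expectation −1/(N−1)). Interfaces with
constant binary signal (all 0 or all 1) have undefined I and are excluded
from I summaries while keeping their S and D. By default I is computed on
the binarised signal; the raw projection can be used instead via the
signal object.

## Reporting

Tables are aggregated by (interaction class × orientation class): n, mean
and SD per metric, with undefined Moran's I values skipped. Two conditions
are compared per class with Welch's two-sample two-sided t-test — chosen
because interface classes certainly differ in n and variance — and
annotated with the ladder \* p<0.01, \*\* p<0.005, \*\*\* p<0.001. Each
interface is one observation (n = interfaces of the class); no
per-plant mixed model is fitted and no multiple-testing correction is
applied by default, mirroring the reporting convention of per-interface
tissue studies. Exports (CSV, bar plots with SD error bars and stars) are
byte-deterministic for identical input.

## The synthetic root generator

The generator emulates a straight, radially layered cylindrical root
segment aligned with z: concentric layers (outer radii `layer_radii`,
innermost extends to the axis) split into angular sectors and equal axial
segments. The default geometry is a meristem-like crop: epidermis, cortex
and endodermis rings of 8 cells (outer radii 20, 13.5, 7.5 μm) around a
single-cell vascular core (3.5 μm), axial cells 16 μm, in a 46×46×64 μm
stack at 0.25 μm voxels — 100 cells, cell sizes and proportions typical of
a root meristem. A single-cell core avoids the degenerate many-wedge
junction that sectoring the innermost band would place on the axis.

Every wall is an analytic cylindrical-sector surface, so the ground-truth
table carries exact areas, classes and adjacency. The wall channel renders
voxels within half a `wall_thickness` (default 1 μm) of any label change —
including the outer surface and the cut faces at the stack boundary — at
intensity 1, blurred and with seeded additive Gaussian noise. The marker
channel draws per-wall spot counts from Poisson(rate × area) with
per-class rates (defaults 0.08/0.02/0.02 μm⁻² for apical-basal /radial/
circumferential — a 4:1:1 ratio placing most signal on transverse walls),
places spots uniformly by surface measure or via a Thomas parent–offspring
process (mean 10 offspring, 1.2 μm dispersion — pit-field patches a few μm
across; parent intensity derived as rate/offspring so both modes share the
expected count), and renders each spot as an isotropic 3D Gaussian of
sigma 0.2 μm (a confocal-scale PSF stand-in) and amplitude 1 over noise
sd 0.02. Spots are attributed to their generating wall in the truth table
even when their rendered support bleeds onto neighbours — downstream
attribution error is part of what the recovery tests measure.

Deliberately **not** simulated: optical anisotropy along z, depth-dependent
attenuation/photobleaching (the pipeline's trim decay exists for real
data), shot noise (additive Gaussian only), curved root axes, and real
root-cap/vascular anatomy. Passing recovery tests on this generator
therefore demonstrates the correctness of the geometry, projection and
statistics chain under known truth — not robustness to every imaging
artefact of real stacks.

## Problem sizes and study conditions used in the tests

The acceptance tests run the default 100-cell root at 0.25 μm voxels
(184×184×256 stack) for segmentation (exact count, per-cell IoU ≥ 0.95)
and interface-area recovery (≤ 7 %); multi-seed recovery runs use a
compact 76-cell root (radii 12/8/4.5/2.2 μm, 6 sectors, 11 μm axial cells,
28×28×44 μm at 0.25 μm) — 5 seeds for the 4:1:1 rate-ratio ranking and 20
paired seeds for the clustered-vs-uniform Moran's I comparison. The unit
suite uses a coarser 0.3 μm, 40-cell root. Moran's I is verified against a
brute-force O(N²) oracle on random graphs up to 500 vertices and against
its closed-form grid anchors.

## Known limitations

- Layer assignment assumes a radially organised sample with clear radial
  gaps between layers; heavily curved or oblique crops violate the single
  global PCA axis assumption.
- The 3 μm² filter and the phantom-contact collapse remove most, but not
  all, rasterisation slivers; a handful of sub-threshold contacts can
  survive extreme geometries.
- Per-interface Moran's I is undefined for saturated or empty interfaces;
  summaries over classes with many such interfaces rest on fewer
  observations than the class n suggests (the exports carry both counts).
- Depth compensation is a geometric per-layer decay; no functional form is
  fitted to the data.
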