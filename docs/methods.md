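# Methods

This note records the statistical model, the geometric conventions, the
defaults and why they were chosen, and the known limits of what the
synthetic validation can show.

## The agreement statistics

Given n >= 2 co-registered binary masks on one voxel grid (shape, spacing
in mm, origin; voxel-centre convention, world position of voxel (i,j,k) =
origin + (i,j,k)·spacing):

**Coverage and median structure.** The coverage map counts, per voxel, how
many observers delineated it; the fraction field takes values k/n exactly
(counts are kept as integers so the 50% tie is decided in integer
arithmetic). The median structure is the voxel set with coverage >= 1/2 —
with an even number of observers, exactly half qualifies. Its surface is
extracted by marching cubes from the fraction field at a level just below
1/2 (1e-6 below, so tie voxels fall inside, consistently with the voxel
rule), after zero-padding by one voxel so the mesh is closed even when the
structure touches the grid boundary. The alternative surface — the
boundary of the binarised majority mask — is available as
`surface_mode="mask-boundary"` for sensitivity checks; the isosurface is
the default because it is sub-voxel smooth. Vertex normals are computed
from the mesh geometry (area-weighted incident triangles) rather than from
the field gradient, which is degenerate on coverage plateaus (regions where
exactly half the observers agree); orientation (inside -> outside) is fixed
per vertex by sampling the coverage field a half-voxel along the normal.

**Signed surface distances.** For each median-surface vertex and each
observer, the distance is the nearest Euclidean distance to the observer's
contour surface, signed positive outside the observer's mask and negative
inside. The observer surface is that mask's sub-voxel isosurface at the
same level the median surface uses, so a cohort of identical masks yields
distances of exactly zero. Magnitudes are computed with a KD-tree over the
observer's isosurface vertices; the signed Euclidean distance transform is
*not* used for magnitudes because the centre-to-centre transform carries a
half-voxel inflation near the surface (measured: it biases a recovered
1 mm noise SD to ~1.4 mm at 1 mm spacing). The inside/outside sign comes
from trilinear interpolation of the binary field (outside the grid counts
as outside). Distance magnitudes above 20 mm are set to 20 mm, sign
preserved; the clip limit, sign convention, SD denominator and weighting
are all recorded in the report provenance and in the SD-map sidecar. An
empty observer mask contributes the maximal disagreement (+20 mm) with a
warning.

A ray-cast variant (`distance_mode="normal-ray"`) finds the first surface
crossing along the median-surface normal instead; it is offered for
sensitivity analysis (see Limitations for why neither variant is "the"
perpendicular distance once surfaces get rough).

**Local SD and RMS-SD.** At each surface vertex the SD of the n clipped
distances is taken with denominator n-1 (sample SD; `sd_ddof=0` switches
to the population form). The overall statistic is the root of the
unweighted mean of squared per-vertex SDs, divided by 10 to report cm.
Because the RMS aggregates squared SDs and the sample variance is
unbiased, the statistic has no small-n SD bias. An area-weighted mean
(`area_weighted_rms=True`, per-vertex weight = one third of incident
triangle area) exists because marching-cubes vertex density is not
uniform; on the phantoms used here the two differ by well under 5%.

**Volumes and Dice.** Volumes are voxel counts times the voxel volume —
exact by construction, reported in cm^3. Dice is computed from voxel
counts; two empty masks are defined to agree perfectly (Dice 1, with a
warning) so degenerate slices do not crash a batch, and empty vs non-empty
is 0. Both the all-pairs mean +/- SD and the generalized multi-observer
coefficient are reported, labelled, because a single generalized value
cannot express a pair-to-pair spread; with only one pair (n = 2) the Dice
SD is undefined and serialised as an empty cell.

## The synthetic cohort generator

The generator emulates a panel of ~10 observers delineating one structure
on an (optionally anisotropic) grid. A reference phantom is star-convex
about its centre, so its surface is a radial function r(θ, φ):

- *sphere* (radius), *tube* (transverse radius + length along z; a
  spinal-canal-scale default is radius 4 mm x length 30 mm ≈ 1.5 cm^3),
  and *blob* (ellipsoid semi-axes, optionally roughened by smooth radial
  bumps bounded by a tanh so positivity and star-convexity are preserved;
  at ~20-35 cm^3 it stands in for an ill-defined target volume).
- Phantoms must keep a margin (default 20 mm, the clip limit) to every
  grid face so clipping and perturbation never interact with the volume
  boundary; sub-voxel phantoms are rejected rather than silently empty.

Observer o delineates ρ <= r(θ,φ) + s_o + ε_o(θ,φ), voxelised by centre
inclusion:

- s_o ~ N(0, σ_sys²) is a global radial offset — a volume bias, constant
  over the surface. Systematic error is modelled as inflation rather than
  translation because a translation is partially absorbed by the median
  surface and would not be separable in tests.
- ε_o is a band-limited random field on the sphere: real spherical
  harmonics of degrees 1..L with i.i.d. standard-normal coefficients,
  L = round(π · r_mean / correlation_length). By the addition theorem the
  sum of squared orthonormal harmonics is direction-independent, so
  dividing by its square root gives *exactly* unit pointwise variance
  before scaling by σ_rand — the link "pointwise radial noise SD =
  σ_rand" holds by construction, not asymptotically. The constant l = 0
  term is excluded (a constant offset is the systematic term's job).
- Seeding: one master seed; observer o draws from the substream
  (seed, o), so adding observers never changes earlier masks, and the
  whole cohort is bit-reproducible. A perturbation driving the radius
  non-positive anywhere is resampled with a warning (error after 10
  tries).
- Non-phantom references are accepted if star-convex about their
  centroid: the radial profile is recovered by per-direction bisection on
  the interpolated indicator, and a reference whose radial representation
  misclassifies more than ~half a surface-layer of voxels is rejected.

`decimate_slices` drops every other axial slice and doubles the z-spacing,
emulating the common practice of thinning 1.5 mm scans to 3 mm to halve
delineation workload.

What the generator does *not* emulate: image appearance (contrast,
noise), breathing or cardiac motion, slice-wise human drawing artefacts
(staircase contours, in-plane smoothing), inter-observer correlation
(observers are independent draws), or non-star-convex anatomy. Passing
the synthetic suite therefore demonstrates the correctness of the
*computation* under a controlled error model, not the clinical magnitude
of variability for any particular structure.

## Problem sizes and numerical choices

- Validation cohorts run on 64^3–96^3 grids at 1 mm (anisotropic variants
  up to 1.5 mm slices); noise-recovery experiments use a 20 mm sphere on a
  96^3 grid, 10 observers, correlation length 15 mm, averaged over 20
  seeds. These sizes put >= 25 voxels across each structure, where the
  remaining voxelisation error in volume and Dice is ~1–3%.
- Grid equality between cohort members is enforced to 1e-3 mm so header
  rounding in co-registered data does not block analysis.
- Polygon rasterisation includes a voxel centre iff it lies inside the
  slice polygon (even-odd rule), with boundary ties resolved half-open
  (low edges in) by a 1e-9 mm query nudge, so abutting polygons never
  double-claim a voxel. Self-intersecting polygons are rejected.
- NIfTI masks must be 3D and axis-aligned with positive orientation;
  nonzero means inside.
- The degenerate cases all have defined behaviour: an empty median
  structure gives RMS-SD = NaN with a warning (not an error), empty
  observers give clipped maximal distances, a failing case in a batch is
  logged and skipped.

## Measured behaviour of the noise recovery

With σ_sys = 0 and the defaults above, the mean recovered RMS-SD is ~1.00
of σ_rand at 1 mm, ~0.92 at 2 mm, and ~0.70 at 5 mm. The 5 mm shortfall
is structural, not a bug: at σ_rand = 5 mm and correlation length 15 mm
on a 20 mm sphere the simulated surfaces have RMS slope near 0.9 relative
to the reference sphere, and the nearest-point distance to such a rough
surface undershoots the pointwise radial offset by roughly the local
cosine of the surface tilt. The ray-cast variant errs in the opposite
direction (overshooting by a secant factor, ~1.3 at 5 mm). In the regime
where the noise amplitude is small compared with its correlation length —
which includes realistic delineation variability on smooth organs — the
recovery is accurate to a few percent; outside it, RMS-SD should be read
as a conservative (downward-biased) summary of radial dispersion.

## Known limitations

- Star-convex observer model only; bifurcated or annular structures can
  be analysed (the analysis makes no shape assumption) but not simulated.
- "Perpendicular distance" is operationalised as nearest signed distance;
  alternatives (ray casting) are provided but no local measure equals the
  radial dispersion once surface roughness slope approaches 1.
- Volumes are voxel-count volumes, not mesh-enclosed volumes; the two
  agree within the discretisation bound (~5% for structures >= 8 voxels
  across) but are not identical.
- The sign convention (positive outside), SD denominator (n-1), clip
  limit (20 mm) and unweighted RMS are conventions; all four are recorded
  in every report's provenance block so a reported number can be
  reproduced bit-for-bit from the report alone.
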