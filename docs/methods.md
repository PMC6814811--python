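# Methods

## Measurement model

The unit of geometry is a membrane trace: an ordered 2D polyline in
nanometres, closed for a mitochondrial outer membrane (MOM) cross-section,
open or closed for an ER membrane profile (ER tubule cross-sections may be
traced either as open membrane segments or as closed outlines; both are
treated identically as length-bearing curves).

For one mitochondrion with band width Δ (default 1 nm) and N bands (default
30, i.e. a 0–30 nm contact range):

1. Every ER trace is subdivided into collinear sub-segments of length
   ≤ δ (default 0.1 nm). Sub-segments lie exactly on the polyline, so their
   lengths sum exactly to the trace's arc length.
2. Each sub-segment is assigned by its **midpoint distance** `d` to the MOM
   *curve* (not the enclosed region) to band `i = ceil(d/Δ)` — bands are the
   half-open annuli `((i−1)Δ, iΔ]`, and touching ER (`d = 0`) falls in
   band 1. Length with `d > NΔ` is excluded. Midpoint classification bounds
   the misassigned length by δ per band crossing, hence the default
   δ = Δ/10.
3. `l_i` sums sub-segment lengths per band over all ER traces (multiple
   traces contribute additively, without per-trace bookkeeping);
   `L_i` is the running sum with `L_0 ≡ 0`.
4. `L = Σ l_i`, `D = Δ·(Σ i·l_i)/(Σ l_i)`, `P` = polygon perimeter of the
   closed MOM trace, `ERMICC = L/(P·D)`.

Two conventions deserve emphasis:

- **D weights each band at its outer edge** (`i·Δ`), following the
  band-index formula literally rather than using a continuous mean
  distance; a single occupied band `k` therefore gives `D = k·Δ` exactly.
  The continuous mean distance always lies within Δ of this value.
- **Zero-contact mitochondria** (no ER within `N·Δ`) get `L = 0`, `D`
  missing (NaN), `ERMICC = 0`, and a `zero_contact` flag; they stay in
  cohort tables and enter group comparisons as zeros by default. Excluding
  them instead is a one-line filter on the flag.
- **P is the full perimeter**, not only the apposed portion, per the plain
  reading of the coefficient's definition.

ER "length" is the arc length of the membrane polyline within a band, not
an area: the defining formulas are dimensionally consistent only for
lengths, and the tracings are curves.

### Distance computation

Point-to-polyline distance is exact: the minimum over per-segment
perpendicular/endpoint distances. For throughput the MOM polyline is split
into ≤ 2 nm chunks indexed by a k-d tree; each query point evaluates exact
distances only against the k = 16 nearest chunks. The nearest chunk's
midpoint lies within `d + 1 nm` of the query, so the pruned minimum equals
the brute-force minimum for the densely sampled traces this package
handles; agreement with a full shapely scan is at the 1e-13 nm level. An ER
trace whose whole-curve distance to the MOM exceeds `N·Δ` is skipped
outright (it can contribute no length).

### Mask-derived scenes and the lattice quantum

Label masks carry no sub-pixel distance information: a dilation boundary on
a pixel grid advances in whole pixels. When membranes are digitized at an
exact band-edge separation (e.g. d = 12 px with 1-nm pixels and 1-nm
bands), an unbiased sub-pixel reconstruction scatters distances
symmetrically about the band edge and splits the length between two bands —
a knife-edge artifact of the reconstruction, not a property of the scene.
`BandConfig.distance_quantum_nm` therefore rounds measured distances to the
mask's lattice pitch before binning for mask-derived scenes
(`BandConfig.for_masks(pixel_size_nm)`), reproducing integer-pixel dilation
semantics. It is off (0) for polyline traces, which are binned
continuously.

## Segmentation I/O

Polyline CSV tables (`scene_id, object_id, role, vertex_index, x, y,
closed`, optional `units` ∈ {px, nm}) are the lossless dialect; write/read
round-trips preserve vertices to better than 1e-6 nm. Coordinates follow
image convention: x right, y down, origin at the centre of pixel (0, 0),
0-based indices; all downstream geometry is in nm.

Label masks (TIFF/PNG, 0 = background, one positive integer per organelle
instance, MOM and ER in separate masks) are converted to traces as follows:

- **Filled regions** → marching squares at iso-level 0.5 with linear
  interpolation, one counter-clockwise closed trace per connected region.
  Interior holes are ignored with a warning (the MOM is the outer boundary
  by definition). A region touching the image border is an error — its
  membrane profile is incomplete, mirroring the rule of selecting only
  cells with intact membrane profiles.
- **Thin, curve-like ER rasters** (mean width ≤ ~2.5 px) → skeletonization,
  ordering of the skeleton into an 8-connected path, and recovery as an
  open (or closed, if loop-shaped) membrane polyline.

Pixel-derived polylines are staircases whose raw chain length overestimates
the underlying smooth curve by ~5% (marching-squares contours) to ~18%
(skeleton chains), independent of scale. Both are therefore smoothed with a
short centred moving average (window 5 for contours, 7 for skeleton paths)
before use; measured residual length bias is below 0.5% for radii ≥ 20 px.
The extracted iso-0.5 contour is positionally unbiased with respect to a
centre-inside rasterization (~0.02 px mean radial error), so no half-pixel
boundary offset is applied.

## Synthetic scenes

The generator emulates manually traced EM cross-sections (images with 1-nm
pixels of 70-nm sections): one closed MOM contour per mitochondrion as a
perturbed circle `r(φ) = r₀ + Σ_{k=2..4} a_k cos(kφ + ψ_k)` sampled at
~2 nm arc steps, with ER arcs constructed as **normal offsets of the MOM
polyline** at a drawn distance d over a drawn fraction of the perimeter.
Because the offset construction realizes the distance exactly, the
ground-truth metrics are closed-form: `P` is the pre-jitter MOM perimeter,
each in-range arc contributes its polyline length to `L` in band
`ceil(d/Δ)`, and `D`/`ERMICC` follow. Truth is recorded before tracing
jitter is applied.

Default study conditions (chosen once as the generator's emulation
envelope; all drawn per mitochondrion from a single master seed through
`SeedSequence` substreams, so extending a scene never perturbs existing
mitochondria):

| parameter | default | rationale |
|---|---|---|
| mitochondrial radius | uniform 300–800 nm | typical cross-section sizes of cultured-cell mitochondria |
| shape noise amplitude | 20 nm (harmonics k = 2–4) | mild departures from circularity; curvature radius stays ≫ 50 nm |
| ER arcs per mitochondrion | 2–3 | ER-rich perinuclear sections where contact quantification is performed |
| arc distance | uniform 10–25 nm | canonical MAM cleft range |
| arc coverage | uniform 10–30% of perimeter each | modest but well-resolved apposition |
| out-of-range fraction | 5% (at 35–80 nm) | nearby but non-contact ER |
| tracing jitter | 0.5 nm RMS, correlated | sub-pixel hand-tracing error |
| raster pixel | 1 nm | the acquisition pixel size being emulated |

Tracing error is modelled as *correlated* vertex displacement (white noise
smoothed over ~15 vertices, rescaled to the requested RMS): white per-vertex
noise on a densely sampled polyline would inflate arc length by several
percent, which hand tracing does not do. With these conditions the
per-mitochondrion ERMICC distribution has a coefficient of variation of
~0.35, which makes a 50% shift in mean coverage a detectable effect
(Cohen's d ≈ 1.1) at n = 40 per group — the regime the cohort-level
recovery checks exercise.

What the generator does **not** emulate: real EM texture and staining,
membrane thickness, rough/smooth ER distinction, curvature statistics of
real organelles, 3D effects of the 70-nm section projection, and any
spatial correlation between mitochondrial size and ER contact. Passing
recovery tests therefore demonstrates correctness of the *measurement*, not
realism of any particular biological effect size.

## Cohort statistics

The experimental unit is the mitochondrion ("all data points included"):
group summaries are mean ± s.e.m. (sample SD over √n), and the two-group
comparison is Student's pooled-variance two-tailed unpaired t-test by
default — the default reading of an unqualified "unpaired t-test" — with
Welch's test available via `test="welch"` and a per-cell aggregation mode
available but off by default. Missing values (the undefined D of
zero-contact rows) are excluded with a reported count. Degenerate inputs:
zero variance in both groups with equal means returns p = 1 by convention;
with unequal means the statistic is undefined and raises.

Null-level and power checks resample mitochondria i.i.d. from a pool of
several hundred measured through the full geometry pipeline; conditional on
the pool this is exact sampling from one distribution, so the nominal test
level applies, at a small fraction of the cost of regenerating hundreds of
thousands of scenes.

## Raster-EDT oracle

The independent cross-check for the geometric core rasterizes the densely
sampled MOM curve at 0.25 nm/px, runs scipy's exact Euclidean distance
transform with `return_indices`, and resolves each ER sub-segment midpoint
to exact point distances against the curve samples that generated the
nearest raster pixel's neighbourhood. No point-to-segment projection is
involved, so the route is independent of the analytic implementation. Raw
EDT distances to pixel centres would carry an ~half-pixel low bias — enough
to flip band assignment of whole arcs lying near band edges — which the
sample-resolution step removes; measured agreement on smooth scenes is
exact for L and ≤ 0.1 nm for D. The oracle-equivalence checks use
jitter-free scenes because the correlated jitter model pushes local
curvature radii below the ~50 nm floor the comparison presumes.

## Line profiles

Profiles are consumed as CSV (position plus one column per channel);
min–max normalization maps each channel to [0, 1] and rejects constant
channels. Peaks are global maxima after a centred moving average (default
window 3 — minimal smoothing, since none is prescribed for this analysis);
exact ties are broken by first occurrence and flagged. Sub-sample peak
interpolation is deliberately not applied: the readout mirrors a by-eye
cross-section reading. The betweenness verdict is boundary-inclusive and
order-agnostic in the flanking markers. Single-line profiles are assumed
(no line-width averaging).

## Numerical choices and limitations

- Band assignment tie-break: `d` exactly at a band edge belongs to the
  lower band (half-open annuli); `d = 0` to band 1.
- Contour orientation is normalized counter-clockwise; consecutive
  duplicate vertices are dropped at 1e-9 nm tolerance; closed traces must
  be simple polygons (validated on load).
- The acceptance script's problem sizes (20 oracle scenes, pools of 250
  mitochondria, 2,000/200 test replicates, 1,000 profile replicates) were
  chosen to keep a full from-scratch rerun to a few minutes while leaving
  Monte-Carlo standard errors well inside the decision margins.
- 2D only: no correction for section projection; no automated
  segmentation; no mixed-effects modelling of cell-level clustering.
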