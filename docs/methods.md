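# Methods

## Growth model

The engine is a stochastic Eden model on a cubic lattice of `L³` sites
(`L = 200` default), each empty (0) or carrying a genotype label.  A
*surface site* has at least one of its six face neighbours empty; sites
outside the lattice never count as empty.  One division event draws a
parent uniformly from the surface list `S`, draws one of the parent's
empty face neighbours uniformly, fills it with the parent's label, and
updates `S` incrementally (add the child if it exposes an empty face;
re-check the child's occupied face neighbours, the parent among them, and
drop any that no longer do).  Labels are immutable once set and the
occupied count grows by exactly one per event — both are tested
invariants, and the incremental `S` is tested against brute-force
recomputation on random histories.

**Clock.** Each division advances time by `1/|S|` with `|S|` taken
*before* the surface update.  The pre-update convention makes the first
division of an isolated founder last exactly one generation, which matches
the definition of the time unit (every surface site divides on average
once per generation); the post-update alternative differs only at order
`1/|S|²` and is indistinguishable in any reported quantity.

**Seeding.** Sites whose centers lie within `R_s = 19` sites of the
lattice center are occupied independently with probability `N/V`,
`V = (4/3)πR_s³` ≈ 28 731 — the founder count is binomial with mean
`≈ N·V′/V` (where `V′` is the rasterized-sphere site count), not fixed.
Two-species mode assigns colors 1/2 with probability ½; multi-species mode
assigns consecutive unique lineage labels in site-scan order (we read
"every founder is its own lineage" literally; drawing labels uniformly
with replacement from `1..N` was evaluated and changes no conclusion).
Seedings that come up empty (possible at the lowest concentration) are
redrawn up to a retry limit and then rejected loudly, since only colonies
that grew are analyzed.

**Boundaries and determinism.** A division targeting the outermost lattice
shell aborts the run with a diagnostic by default (`boundary_policy =
"stop"` ends the run instead); with the default geometry the colony ends
at radius ≈ 50 sites, far from the shell at 100.  All randomness flows
from one seeded generator per replicate; ensemble replicate seeds derive
from a base seed through `numpy` seed-sequence spawning, so any run is
bit-reproducible from its manifest.

**Snapshots.** The state is summarized at `t = 0` and at the first state
past every multiple of `record_interval` (default 1 generation, the grid
on which sector counts are reported).  Because snapshot times differ
slightly between replicates, ensemble series are aligned on the recording
index.  Per snapshot we record occupied count, surface size, projected
area and perimeter, radius, per-color surface areas, occupancy and the
pooled sector count; full sector tables can be collected at chosen times.

## Metrics

All surface metrics operate on a single-voxel-thick colored mask — the
live surface list for model colonies, or the extracted surface of any 3D
label volume — so simulated and experimental colonies share one code path.

- **Radius.**  From binary z-projections (a pixel is set iff any voxel in
  its column is occupied): per colony `R = √(A_prj/π)`; the ensemble value
  is the mean of per-colony radii, *not* the radius of the mean area (the
  two differ for unequal colonies; a test distinguishes them).
- **Perimeter.**  Exposed pixel-edge count times edge length.  This
  staircase definition overshoots the continuum perimeter of a disk by
  `4/π`; it is used *identically* for colonies and for the reference
  circle, so the bias cancels in the normalized compactness.
- **Compactness.**  `ρ_prj = 4πA/P²`, normalized by `ρ′` of a
  pixel-resolved circle of equal area: the reference disk includes pixels
  by rank of center distance, cut at the count nearest the target area, so
  a disk rasterized with the same convention reproduces itself and `ρ = 1`
  exactly at every radius — the definitional anchor, asserted exactly in
  tests.
- **Occupancy.**  Focal-color surface fraction per colony, ensemble-
  averaged.  Per-colony occupancies over all colors sum to 1.
- **Sectors.**  Connected components of same-colored surface voxels,
  labeled by union-find; spatially separated same-color clusters are
  distinct sectors, and components below `min_area` are discarded (1 site
  for model colonies, 10 voxels for experimental masks, ≈ 23 µm² at the
  1.51 µm lateral voxel size).  Labeling is verified against an
  independent flood fill and against per-color `scipy.ndimage` labeling.
- **Survival curves.**  Area-weighted: `P(A > a)` is the fraction of total
  sector area held by sectors larger than `a`, evaluated at 0 and the
  distinct areas; non-increasing from 1 by construction.

**Sector connectivity.**  Default 26-connectivity (faces, edges,
corners).  Within a one-voxel-thick curved surface, corner adjacency is
the correct notion of "neighbouring on the surface": a contiguous color
patch crossing a diagonal staircase step stays connected.  Face-only
adjacency shatters rough surfaces into thousands of sliver components and
destroys the merging phase of `σ(t)` entirely (the count then rises
monotonically from the start); with 26-connectivity the count falls from
≈ the founder number to a minimum and then climbs linearly, the published
phenomenology.  6-connectivity remains selectable for sensitivity
analysis.

**Splitting rate.**  OLS slope ± SE of `⟨σ(t)⟩` on a window isolating the
late linear branch.  The default window starts two generations after the
*last* time the 3-point moving-averaged series is within one (median)
ensemble SEM of its minimum, and runs to the last recorded generation.
Taking the last near-minimal time rather than the argmin matters for the
multi-species curves, which show a transient hump (lineage fragments
appearing and re-merging while the micro-colonies fuse) that returns the
count to near its starting level before the linear rise; the plain argmin
would then sit before the hump and the "window" would span the whole
transient.  The window is always reported with the fit, and any explicit
window can be supplied.

## Mask ingestion pipeline

Externally segmented two-channel volumes (one binary volume per
fluorophore, with physical voxel sizes, e.g. the study's
(1.51, 1.51, 1.33) µm confocal grid) pass through: (1) channel merging,
with voxels claimed by both channels assigned to red — red being the less
detectable fluorophore, a double claim is evidence of red — and the
double-labeled fraction reported as QC; (2) hole filling: background
components not connected to the volume border are filled with the
majority color of their face-adjacent voxels, ties to red for consistency;
border-connected background is never touched; (3) hemisphere removal as a
planar z-cut at a configurable index, a reproducible stand-in for the
manual removal of the shadow-distorted far half; (4) surface extraction.
Upstream denoising/thresholding of raw micrographs is out of scope; the
pipeline starts from binary channels.  Volumes round-trip losslessly as
compressed `.npz` containers or multi-page 16-bit TIFF stacks with a JSON
geometry sidecar.

## Synthetic data

The fixture generators produce the known-answer inputs the tests run on:
pixel-center-inside rasterized disks (same convention as the reference
circle, so compactness answers are exact), voxel sphere shells, shells
painted as meridian wedges / hemispheres / i.i.d. random colors (known
sector counts and occupancies), two-channel pairs with a controlled
double-label band, and piecewise `σ(t) = max(c, σ₀ − kt) + st` series with
known splitting slope.  They emulate geometry and bookkeeping, not
microscopy: no optical blur, attenuation, segmentation error or colony
roughness, so passing metric tests certifies the definitions and their
implementation, not robustness to imaging artifacts.  Robustness on
realistic shapes comes from the model colonies themselves, which are
rough, and from QC counts surfaced by the pipeline.

## Study conditions and problem sizes

Ensemble runs default to the published protocol: `L = 200`, `R_s = 19`,
mean founders {16, 144, 1150}, 15 replicates, `5×10⁵` division events per
replicate, per-generation recording.  `5×10⁵` events correspond to ≈ 29–37
generations depending on seeding density (denser seedings reach a large
surface sooner, so their clock advances more slowly); the densest
multi-species condition therefore offers only ≈ 7–9 generations of linear
branch after its long merging phase, and its fitted slope carries a
visibly larger standard error than the others.  Unit tests run the same
engine on 21³–72³ lattices with 10³–10⁵ events, sizes at which the
brute-force oracles remain exhaustive.

## Dosimetry

Expected founders per inoculation bead = cell density × bead volume, with
density from OD₆₀₀ via the plating calibration OD 1 = 1.5×10⁹ cells/ml and
volume `(4/3)πr³` for the mean bead radius 29 µm (0.10216 nl).  Carrying
the volume at three significant figures (0.102 nl) reproduces the
published per-condition counts (863/108/12) exactly; the exact volume
shifts the densest condition to 864.  The lowest condition's published
count (1.0 cells/bead at 1.6×10⁷ cells/ml) is not consistent with that
volume (the inputs give 1.6) nor with its own OD times the calibration
(1.04×10⁷ cells/ml); the module computes from its inputs rather than
special-casing the row.

## Known limitations

- The model is neutral and mechanically homogeneous: no fitness
  differences, nutrient fields, pushing, or off-lattice mechanics; one
  site is a meta-population, so lengths and times map to experiment only
  qualitatively.
- Sector statistics depend on the surface-adjacency convention (above);
  published experimental counts were produced by a third-party tool whose
  convention is not documented, so cross-tool comparisons should fix
  `connectivity` explicitly.
- The splitting-rate window rule is a heuristic over a curve with no
  canonical changepoint; the window is therefore part of every reported
  fit.
- Hole-fill colors are decided by local majority vote, a modeling choice
  for a step the original workflow performed without specifying color
  assignment.
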