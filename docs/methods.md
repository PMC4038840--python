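# Methods

This note documents the models behind `arbormetry`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices that matter. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Reconstructions and sectioning

A reconstruction is a rooted tree of typed nodes (SWC convention:
1 soma, 2 axon, 3/4 dendrite) in µm. Validation requires unique ids,
a single root, parents preceding children (which rules out cycles),
finite coordinates, and non-negative radii; every corrupted-input mode
in the test corpus is rejected with an error naming the offending line.

**Shrinkage.** Tissue dehydrated and cleared in BBBA shrinks
isotropically by a volume factor of 3.32 ± 0.17; lengths measured on
cleared sections are corrected by the cube root, 1.4918. Coordinates
are scaled about the soma (any fixed point can be supplied); the
correction commutes with sectioning. A config switch
(`shrinkage.enabled`) turns it off for inputs already corrected.

**Virtual sectioning.** Slabs are half-open intervals
`[origin + i·t, origin + (i+1)·t)` of thickness *t* = 300 µm (the
vibratome section thickness); index 0 sits at the origin, and sagittal
sectioning maps the mediolateral axis to `x` (configurable). Edges are
split at slab faces by linear interpolation; a piece belongs to the slab
containing its midpoint, so boundary points fall in the upper slab.
Because the split parameters telescope, per-slab lengths sum to the
whole-arbor length to ~1e-16 relative (tested at 1e-9). How traces
crossing physical cut faces were joined in real data is unknowable here;
virtual sectioning assumes one consistent coordinate frame.

## Single-arbor metrics

* **Length**: sum of Euclidean parent–child distances; an edge is typed
  by its child node. Empty type selections return 0 with a warning.
* **Branch points**: nodes of the filtered type with ≥ 2 children of
  that type. Trifurcations count once; the soma never counts. Branch
  density is branch points per mm of cable. Because real branch
  densities were measured on two 300 µm sections per arbor rather than
  whole arbors, `branch_density_subsample` reproduces that protocol,
  selecting the two fullest sections (the selection rule is not
  specified in the source; "fullest" is this package's choice).
* **Polygon method**: per non-excluded slab, all sub-segment vertices
  (including boundary-split points — the hull of a polyline equals the
  hull of its vertices) are projected onto the section plane and
  enclosed with the smallest convex polygon (`scipy.spatial.ConvexHull`;
  an O(n³) extreme-edge oracle verifies areas in the tests). Territory
  volume is Σ area × thickness; degenerate (collinear) slabs contribute
  zero area rather than erroring. Slabs containing only the subcortical
  axon segment can be flagged `excluded` and then contribute nothing.
  Dendrite territories reuse the same machinery with the dendrite type
  filter.
* **Extent**: occupied-slab count × thickness, matching measurement
  across physical serial sections; the raw coordinate span is reported
  alongside. Exclusion flags do not apply to extent — an excluded
  section still witnesses the arbor's reach.
* **Topography**: Spearman rank correlation of soma positions vs arbor
  midpoints (`scipy.stats.spearmanr`).

Note that the polygon method deliberately over-estimates influence
territories (it fills concavities), and territory volume is quantized in
units of hull-area × 300 µm even when an arbor occupies a sliver of a
section. Both effects are inherited from the source protocol.

## Population estimators and geometry model

Internal canonical units are µm/µm³; the conversion table lives in
`units.py` only. Report rounding follows the source convention: lengths
to the nearest cm below 2 m, nearest m above; ratios to 2 significant
figures; densities to 3 decimals.

The shipped cross-species table records published inputs per (species,
system, route). The hippocampal volume (21 mm³) is omitted from the
mouse cortical density-route estimates by default, matching the source's
parenthetical treatment; `include_hippocampus=True` adds it. The
dopaminergic varicosity row is the one entry whose printed range
(55–77 cm) is not reproduced by the formula applied to its own printed
inputs (which give 48.6–68.0 cm); both values are recorded and no test
asserts their agreement.

The geometry model treats the axon as a cylinder of diameter 0.3 µm,
varicosities as 0.4/µm swellings of 0.06 µm³, and the soma as a 30 µm
sphere. Varicosity surface is *not* added to the axon surface (the
reference surface figure is the bare cylinder). The printed reference
value ~70.6 × 10³ µm³/m for axon volume differs from the computed
70.69 × 10³ by an unexplained rounding; comparisons use 0.5% relative
tolerance. The scale model multiplies linear dimensions by 10⁴ and
re-expresses each in the largest unit ≥ 1.

## Z-stack overlap correction

Adjacent confocal Z-stacks (4 planes × 2 µm = 8 µm each) double-count
axon segments near the shared face because out-of-plane signal is
incompletely rejected. With a uniform bleed depth *b*, the duplicated
fraction of a stack's traced length is 2b/(T + 2b). The estimator
divides mean duplicated length per adjacent pair by mean raw length per
stack (pooled, the default) or averages the per-pair ratios; correction
subtracts the fraction once per stack — half of each face's overlap
derives from each stack and each stack has two faces — and density is
corrected length over imaged volume. Corrected density ≤ raw density
always, with equality iff the fraction is zero; the raw density
overestimates by f/(1−f).

**Generator.** Segments of 2 µm are placed uniformly over the imaged
depth plus a *b*-wide margin beyond the outer faces (tissue continues
past the imaged stacks; without the margin, edge stacks receive bleed at
only one face and the subtract-once correction would underestimate for
the two-stack reference geometry). Margin segments bleed into edge
stacks but are excluded from the true in-stack total against which
recovery is judged. Defaults: density 0.044 µm/µm³ (the motor-cortex
set-point), 200 × 200 µm field (no field size is published; a typical
confocal frame, large enough that the estimator's sampling error is
well inside the stated recovery tolerances), two stacks, and
b = 1.362 µm — the depth implied by the observed 25.4% duplication at
8 µm stacks.

## Puncta detection and statistics

Pipeline: threshold → 8-connected components → keep components with
Feret (maximum caliper) diameter strictly > 5 px (equivalent-area
diameter is available as an option). The source protocol counted
deposits manually; automation requires an intensity criterion, and the
default is Otsu's threshold — computed exactly over unique gray levels
for images with few distinct values, because the histogram-bin-center
convention of the standard implementation can land the threshold just
below a gray level and silently flip a whole intensity class into the
foreground. **Caveat:** per-image Otsu misbehaves on fields containing
no deposits at all (it splits whatever contrast remains); comparative
analyses across groups should pass one fixed intensity threshold, as the
puncta example does.

Rasterization widens apparent diameters by up to ~1 px (a nominal 5 px
disc has a pixel-domain Feret of ~5.4), so discs at the criterion
boundary are classified by their rendered, not nominal, size; the
clean-field recovery tests therefore use 4 px and 8 px discs, which sit
unambiguously on either side of the 5 px criterion.

Group statistics: quartiles by linear interpolation between order
statistics (the box-plot convention: extremes, 25–75% box, median);
two-sample two-tailed Student t test (equal-variance by default, Welch
optional); a pair in which both groups have zero variance is flagged
degenerate with p reported as NaN.

## Arbor generator

Growth is a persistent random walk: direction
`normalize(ρ·previous + (1−ρ)·isotropic)`, default persistence ρ = 0.8,
step 10 µm, with specular reflection at the bounding-box faces (the
offending direction component flips *before* the step, so every edge has
exactly the step length and length bookkeeping is exact). Each step
branches with probability rate × step (default 4.5/mm); branch
directions are drawn fresh and trifurcations never occur. On a branch
event both child tips are scheduled at the front of the growth queue so
that branch nodes realize both children before the budget can expire
under them — with plain FIFO scheduling, events in the final queue cycle
would lose their second child and bias recovered branch density low by
several percent. Growth stops when the remaining budget is below one
step, so realized length is within one step of the target.

Defaults state the adult regime: 31 cm of cable, 4.5 branches/mm, a
2 mm box (sectioned arbors then span ~2.1 mm, i.e. seven 300 µm
sections). The generator emulates cable statistics, not biology: no
growth cones, no cortical layers, no tropism, and no claim to match the
real (roughly ten-fold) spread of arbor compactness — though persistence
and box size span that range. Two consequences observed in testing and
worth knowing: (1) a random-walk arbor's polygon territory undershoots
its bounding box until the cable saturates it, so boxes differing 10× in
volume yield density ratios of ~5× at 10 cm of cable, approaching 10×
only for much longer arbors; (2) realized branch density is binomial, so
recovery tests use 3-standard-error bands.

## What a green test establishes

Synthetic-recovery tests establish that the estimators are unbiased and
conservation laws hold *under the generators' assumptions* (uniform
segment placement, uniform bleed depth, disc-shaped puncta,
reflecting-box growth). They do not validate tracing quality, staining
uniformity, or any biological distributional claim. Population-level
numbers are exact arithmetic on published inputs and are reproduced to
their printed precision.
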