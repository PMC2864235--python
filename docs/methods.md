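# Methods

`skelopod` quantifies amoeboid cell-shape dynamics by reducing each
segmented cell outline to its medial-axis skeleton and following how the
skeleton's outer branches appear, grow and disappear between frames.
This note records the models, parameter choices and numerical decisions
behind each stage, what the synthetic test movies do and do not emulate,
and the known limitations.

## Segmentation

One binary mask per frame, exactly one connected component, holes
filled, largest component kept (fields are assumed to contain a single
cell).

* **Fluorescence** — global two-class variance-maximising (Otsu)
  threshold. For a bimodal frame this lands between the background and
  cell modes and is invariant to affine intensity rescaling.
* **Phase contrast** — Lucy-Richardson deconvolution (default Gaussian
  PSF, σ = 2 px, 10 iterations; both configurable — phase-ring width
  varies between optics) removes the halo; the Sobel gradient magnitude
  is Otsu-thresholded, specks ≤ 16 px are dropped, the remainder closed
  with a disk (default radius 3 px) and filled. Because the gradient
  band straddles the true edge, the filled region is eroded by 2 px.
* **DIC** — line-integrated DIC: cumulative sum along the prism shear
  direction turns the differential image into a pseudo-fluorescent one.
  Integrated noise leaves per-line constant offsets (stripes); the
  per-line *median* — an estimate of the background level that is not
  biased by the cell — is subtracted after integration. Total-variation
  (Chambolle) denoising is applied either before integration
  (`denoise_first`) or after it (`texture_after`); both variants then
  follow the fluorescence path. The constant spatial offset of the
  recovered cell along the shear direction is a property of the
  integration and is deliberately not corrected: it is identical in
  every frame and cancels in all shape-derived quantities.

## Boundary smoothing

The ordered pixel boundary (inner border following, 8-connected) is
fitted with a closed uniform quadratic B-spline, which has a continuous
first derivative by construction. The fit iterates (default 5 passes):
sample the current spline densely, search ±12 px along each sample's
normal for the nearest boundary crossing (shapely segment-ring
intersection; nearest boundary pixel as fallback), then re-estimate all
control points by periodic linear least squares against those feature
points (a small ridge term, 1e-8, guards conditioning). The fit stops
early below 1e-3 px mean error and aborts (`FitDiverged`) if the mean
feature distance grows three consecutive iterations beyond numerical
jitter.

The control-point count defaults to one per 8 px of perimeter (minimum
8). The spacing must stay below the width of a pseudopod (~7–8 px at
0.2 µm/px) or genuine protrusions are smoothed away; coarser spacing is
a configuration choice for blunt-shaped cells. For spiky cell types
(fibroblast-like), smoothing can be disabled entirely
(`smoothing: false`), in which case the raw pixel boundary is used.

Descriptors: centroid = shoelace area centroid of the enclosed polygon;
perimeter = arc length of the dense samples; body length = maximum
Feret diameter of the hull (41.2 px for a 40×10 px rectangle, 2r for a
disk — the intuitive "length of the cell body", unlike the
second-moment major axis which overshoots elongated shapes by ~15 %).

## Skeletonization and pruning

The skeleton is the medial axis — the locus of centres of maximal
inscribed balls — computed as the Euclidean distance-transform ridge
with topology-preserving thinning (equivalent to grassfire
propagation). The thinning's pixel-order tie-breaking is seeded to a
constant so identical masks always give identical skeletons. Pure
boundary-peeling thinning is not used: it is more robust to noise but
erases exactly the shape features of interest.

The pixel skeleton becomes a graph: degree-1 pixels are terminals,
8-connected clusters of degree-≥3 pixels are merged into single
junction nodes, chains between them are edges whose length counts
diagonal steps as √2. Degree-2 leftovers are spliced through, so the
graph is always in a canonical form.

Pruning maps each pseudopod onto exactly one *outer branch* (an edge
with a free terminal; the node attaching it is its *root*):

1. **Short branches**, length < `p_threshold` (default 1/10 of the body
   length, resolved per frame): removed if no sibling shares the root;
   otherwise compared with the shortest sibling — combined when the
   longer is < r (default 1.5) times the shorter or itself short,
   else the shorter is removed. Combination replaces both by a straight
   rasterised branch from the root to the midpoint of the two old
   terminals, keeping the approximate centre line of the underlying
   pseudopod. More than two siblings are handled by repetition.
2. **Far branches**: a terminal's distance to the membrane equals the
   local radius of curvature (the terminal is the centre of the maximal
   ball touching that boundary arc); branches with terminal-to-membrane
   distance > `prdist_threshold` (default 1/6 body length) sit in
   locally flat membrane where no pseudopodial activity is expected,
   and are removed.

Order: short-branch pruning to a fixed point, far-branch pruning, one
final short pass (removal can expose new short branches). A
`single_pass` flag restricts each criterion to one sweep. A perfectly
round cell legitimately ends with an empty skeleton; this is flagged,
never an error.

## Activity detection

For frames n, n+1 the growing region is I_{n+1}\I_n and the withdrawing
region I_n\I_{n+1}; both are computed from the rasterised smoothed
boundaries so that skeletons and difference maps are mutually
consistent. A **protrusion** is a growing component entered by an outer
branch of S_{n+1}; a **retraction** a withdrawing component entered by
a branch of S_n. Components below 4 px² (configurable) are treated as
segmentation noise. Each difference component yields at most one
activity; if several branches enter it, the branch with the longest arc
inside measures it. The length is the branch arc inside the component,
with the branch extended along its terminal tangent (last 5 px) to the
membrane when the pruned skeleton stops short; an extension that never
meets the relevant region drops the candidate with a log entry.

The start point is where the branch, walked root→terminal, first enters
the difference region — the membrane of the *persistent* cell body
(∂I_n for protrusions, ∂I_{n+1} for retractions), snapped to the
nearest dense boundary sample. This convention makes detection exactly
time-reversal symmetric: protrusions of (A,B) equal retractions of
(B,A) in start and length, a property the test suite checks pair by
pair. The alternative convention, with both starts on ∂I_n, places the
retraction start at the old tip and breaks that symmetry; we prefer the
symmetric form also because it keeps a pseudopod's start points
spatially continuous through its protrusion→retraction transition,
which the tracker relies on.

Angles are measured at the earlier frame's centroid against the
0°-line pointing up the chemoattractant gradient (fixed direction, or
centroid→source for a point source), counterclockwise positive, in
(−180°, 180°]. Blebs are a known limitation: a bleb's locally flat
curvature produces no skeleton branch, so bleb-driven protrusions are
not detected.

## Backward tracking

Pseudopod dynamics are modelled as a second-order autoregressive
process: (1) position/angle changes within a pseudopod are much smaller
than distances between pseudopods; (2) when they change, the rate tends
to be constant; (3) pseudopods have limited lifetimes. Because
pseudopods split, activities are clustered *backwards* in time: frames
are processed last→first (within a frame, by |θ| for determinism), and
each unassigned activity is scored against every assigned activity up
to `T` (default 50 s) later, joining the best-scoring track — as its
new earliest member — if the score is under `dist_threshold` (default
1/10 of the mean perimeter), else seeding a new track. Ties prefer the
smaller time gap.

The score combines first/second-order differences (Appendix-style
discrete derivatives, angles differenced on the circle) of position and
angle, weighted α = 0.5 within each pair cost and β = 0.5 between the
spatial and angular parts, normalised by the cell radius R (5 µm
converted to pixels):

    score = R * sqrt( [β (D/R)² + (1−β) Θ²] · Δt/Δt_frame )

where D and Θ are the pair costs integrated over the link's time gap
(px and radians). The leading R makes the score commensurate with the
pixel-valued threshold; R·Θ is the membrane arc swept by the angular
change. The first-order term is always the jump of the link being
scored; the second-order term (defined with three points) penalises
rate changes. The form is isolated in one function so alternatives can
be swapped. With fixed costs the score grows as √Δt — activities far
apart in time are less likely to be the same pseudopod.

A **split** is recorded when a second track's tail also lies within
`dist_threshold` of an activity just claimed by another track: the
common earlier activity is the ancestor, the lower-scoring track keeps
continuity (it is the parent lineage) and the other is marked
origin = split with a split event on the parent. The mark is provisional:
if the marked track later extends to a strictly earlier activity, it
existed before the claimed split and the mark is retracted.

## Statistics

Per pseudopod (units in parentheses): lifetime = t_last − t_first + one
frame interval (s); protrusion/retraction ratios; speeds as total
protruded/retracted length over the corresponding activity time,
converted px/frame → µm/min; persistences = longest consecutive run of
one kind × frame interval / lifetime (a single-activity pseudopod has
persistence 1 by this definition — degenerate but consistent); state
persistence = max of the two; starting angle, circular mean angle,
least-squares slope of the unwrapped angle vs time (deg/s) and the
variance of its residuals (deg²); origin and split count. Cell level:
time-average of coexisting pseudopods, fraction of split origins,
splits per minute, and plain means of the per-pseudopod quantities
(speed means over pseudopods that have that kind).

Hierarchical ranking sorts pseudopods by descending activity count
(ties: earlier start, then id) and returns the shortest prefix covering
the requested fraction of all activities. Short-/long-lived cutoffs
(7 s / 9 s at 1 s/frame) are downstream classification choices, not
pipeline logic.

Protrusion-angle distributions are characterised by a least-squares
Gaussian fit to the 36-bin histogram on (−180°, 180°] (histogram fit,
not maximum likelihood, and linear rather than circular — wrap-around
mass is visible as non-convergence, which is itself informative);
fits that fail, or whose σ exceeds 180°, return converged = False
rather than raising.

## Correlation analysis

Activity and membrane intensity are laid out on (frame k, angle bin θ)
grids (default Δθ = 4°): A(k,θ) is the signed activity length
(protrusion +, retraction −, 0 otherwise; bin collisions keep the
larger magnitude and are logged) and I(k,θ) the membrane intensity,
sampled as the mean of band_px + 1 (default 4) bilinear samples along
the inward radial from the boundary point in that bin — multi-crossing
bins use the crossing farthest from the centroid and are logged, empty
bins borrow their nearest angular neighbour. Min-max or per-frame
z-score normalisation is available; z-scored values read as "standard
deviations above the mean membrane fluorescence of that frame".

The normalised cross-correlation C(Δk, Δθ) correlates A shifted by
(Δk, Δθ) against I: angle shifts circular, time shifts zero-padded
(movies are not time-periodic), intensity centred per frame (averaging
over angles removes bleaching and illumination drift), activity centred
globally, and the sum divided by N·M·σ_A·σ_I (biased normalisation), so
|C| ≤ 1 by Cauchy-Schwarz, identical inputs peak at exactly 1, and the
output is a (360/Δθ) × (2N−1) matrix. Whether the original formulation
normalised per-angle or globally is not recoverable; global σ was
chosen and the normalisation is confined to one function.
Per-activity pairings (signed length vs I_z at the activity's bin,
optionally offset by e.g. 180°) give the site-intensity correlation
coefficient, kind-stratified means, and the binned
length-vs-intensity profile with standard errors.

## Synthetic movies

The generator renders a disk-shaped cell (default radius 25 px = 5 µm
at 0.2 µm/px — a ~10 µm cell, frame interval 10 s, matching cells that
move ~10 µm/min) with a static smooth boundary perturbation
(low-order cosine modes, ~1 px) and finger-shaped pseudopods:
rectangles with round caps, anchored inside the body, whose tip radius
is exactly (cell radius + scripted length) so truth lengths are closed
form. Events script growth (px/frame), optional hold and re-retraction,
pure retraction, angular drift, and tip splitting (a sibling finger
with the parent's current length appears at an angular offset; both
keep growing). Unrelated fingers must stay width + 4 px apart along
the membrane arc. Fluorescence is mask × intensity + Gaussian noise;
a second membrane channel paints a chosen coupling of angle and
activity onto a band inside the boundary. All randomness comes from a
single seed; identical seeds give bit-identical movies and truth
tables.

What the generator does **not** emulate: textured interiors,
photobleaching, out-of-focus light, membrane ruffling between events,
blebs, cell-cell contacts, or curved pseudopods. Passing the recovery
tests therefore demonstrates the correctness of the geometry and the
bookkeeping (detection, lengths, lineage, correlation structure) —
not robustness to every imaging artefact of real microscopy.

## Problem sizes used in tests

The standard recovery benchmark is one 100-frame movie with 8 staggered
grow-hold-retract events (growth 4 px/frame); lineage recovery uses
16-frame tip-split movies over 10 seeds; correlation checks use a
100 × 90 (frames × 4°-bins) grid with a planted (+3 frame, +20°) shift
at signal-to-noise 2. These sizes give stable statistics (recovery
rates move by ~2 % across seeds) while a full test run stays fast.

## Known limitations

* Blebs and other low-curvature protrusions are invisible to the
  skeleton (shared with all curvature-based detectors).
* Frame intervals must be short enough that a considerable part of the
  cell body overlaps between frames; at ~10 µm/min cell speed and
  ~10 µm body length that means ≲ 10 s/frame.
* The distance-score functional form is a reconstruction constrained by
  its stated properties (monotone in spatial, angular and time gaps;
  √ time factor; β/R weighting); it is isolated in
  `tracking.score_from_deltas` for substitution.
* Multi-crossing membranes (one angle, several boundary points) are
  handled by taking the farthest crossing in the intensity matrix; the
  detection/tracking path is unaffected since activities carry (x, y)
  as well as θ.
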