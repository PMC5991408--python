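# Methods

## Problem

Automatic tissue-class segmentation of sub-millimeter (≈0.7 mm isotropic,
7 T) brain MRI systematically mislabels thin bright structures — pial and
intracortical blood vessels and the dura mater — as gray matter (GM).
`histoseg` implements two semi-automatic post-processing routes that remove
such voxels from an initial GM segmentation by classifying voxels in a 2D
feature histogram rather than in anatomical space:

* **GraMag** (uni-modal): features are image intensity (typically a
  T1w/PDw ratio image) and the Euclidean norm of the spatial intensity
  gradient.  Bulk tissue forms compact low-gradient modes; thin bright
  structures produce very high gradients at medium-to-high intensities and
  trace an arc above the tissue modes.
* **CoDa** (multi-modal): three co-registered contrasts per voxel are
  treated as a *composition* — only the relative sizes of the three values
  carry tissue information, the common scale being dominated by the RF-coil
  bias field.  Compositions live on the 2-simplex and are mapped to two
  real coordinates with the isometric log-ratio (ilr) transform; tissues
  form separated modes in the ilr plane while vessels and dura spread
  orthogonally to the tissue axis.

A *transfer function* — a boolean mask over histogram bins — is carried
back to voxel space through the stored voxel-to-bin map: GM voxels whose
bin is not selected are relabeled background.  Refinement never adds GM.

## Compositional machinery

For a voxel with positive parts `v ∈ R³₊`, the closure `C(v) = k·v/Σv`
projects onto the simplex (k = 1 throughout).  The simplex carries a
vector-space structure: perturbation `x ⊕ y = C(x·y)` (componentwise) and
powering `x ⊙ p = C(xᵖ)`; the Aitchison distance is
`d_a(x,y) = sqrt((1/2D) Σ_j Σ_k (ln(x_j/x_k) − ln(y_j/y_k))²)`,
computed internally as the Euclidean norm of centered log-ratio (clr)
differences, to which it is algebraically identical.  The sample is
centered by perturbing with the inverse of the geometric-mean center and
standardized by powering with `totvar^(−1/2)`, after which the center is
uniform and the total variance is 1.  The ilr map `ln(b)·H` uses the
standard orthonormal Helmert sub-matrix

    H = [[ 1/√2, 1/√6],
         [−1/√2, 1/√6],
         [ 0,   −2/√6]],

making ilr an isometry: `‖ilr(x) − ilr(y)‖₂ = d_a(x, y)`.  Because closure
cancels any multiplicative factor common to the three contrasts, the whole
pipeline is invariant under a shared smooth bias field; this is verified to
1e-8 end-to-end.

**Zero handling.**  Compositions require strictly positive parts.  Masked
voxels with a non-positive part (noise outliers) are repaired with a
per-voxel relative floor — 1e-6 times that voxel's largest part, a uniform
composition if no part is positive — and counted in a warning.  A relative
floor (rather than one derived from cohort statistics such as a masked
median) is the only choice that keeps the repair equivariant under a
voxelwise multiplicative field, preserving the bias-cancellation guarantee
exactly.

## Gradient estimation

The gradient magnitude uses a separable 3×3×3 Scharr kernel: smoothing taps
(3, 10, 3)/16 on the transverse axes, central difference (−1, 0, 1)/2 along
the derivative axis, reflecting boundaries.  The normalization makes a ramp
of slope *s* per voxel return exactly *s*, so gradient units are intensity
per voxel; a flag converts to per-mm using the voxel size (off by default,
matching histograms of isotropic data described in voxel units).  A
Deriche-style tunable estimator is provided as a Gaussian derivative with
σ = 1/α, for matching the effective resolution of very high-resolution
acquisitions to a reference; α = 1 reproduces the standard setting.

A known, structural property of any central-difference scheme: the mid-line
of a thin bright sheet is a ridge crest where the first derivative vanishes,
so a fraction of dura voxels always shows low gradient magnitude despite
bright intensity.  The cluster-selection heuristic accounts for this (see
below).

## Histogram, graph, and normalized-cut hierarchy

Masked voxels are binned on equal-width 100×100 grids over clipped axis
ranges (intensity at (0, 100) percentiles, gradient magnitude at (0, 99.9)
so vessel extremes do not compress the range; ilr axes at (0.5, 99.5)).
The voxel→bin map is stored, making any bin selection invertible;
out-of-range voxels are never selected.

Nonzero bins become nodes of an 8-connected graph with edge weights
`exp(−(c_i − c_j)²/σ_w²)`, σ_w = 0.1, where c is ln(1+count) rescaled to
[0, 1].  Disconnected islands are joined by minimum-length bridging edges
carrying near-zero weight (1e-6): bridges are artificial connectivity, not
evidence of similarity, so the cut hierarchy separates islands cheaply.

The hierarchy is built by recursive two-way normalized cuts (spectral
relaxation; second eigenvector of the normalized adjacency, deterministic
start vector, dense solver at ≤128 nodes with a dense fallback if ARPACK
stalls).  Candidate splits are thresholds between distinct eigenvector
values (≤64, uniformly subsampled); the split minimizing the exact Ncut is
kept, with ties broken toward balance and then the lowest index.  On
subgraphs larger than 64 nodes the sweep requires the smaller side to carry
at least 5% of the subgraph association: without this floor, recursive
bisection of real histograms degenerates into peeling near-disconnected
sparse slivers (each with Ncut ≈ 0) and exhausts the 8-level budget before
any structural cut.  Small graphs are swept unconstrained, where the plain
minimum matches exhaustive search over all 2-partitions (verified on toy
graphs up to 12 nodes).  Recursion stops at depth 8, at singletons, or when
the best split costs more than `stop_ncut` = 0.999.  Levels are mutually
exclusive and collectively exhaustive, and each level refines its parent.

## Cluster selection (the rater stand-in)

Interactive cluster selection cannot be reproduced; `auto_brain_select` is
an explicitly documented heuristic operating on the deepest tree level.
A cluster is kept as brain when:

1. **CSF gap** — its count-weighted upper-quartile x lies above the first
   valley of the marginal x histogram.  The valley is the argmin between
   the first two modes found by a prominence-filtered peak search
   (moving-average smoothing, width 5 bins; prominence ≥ 1% of the
   marginal's maximum; zero-padding so edge bins can be modes) and is
   accepted only if it drops below 0.6× the lower flanking mode.  If the
   marginal does not show two separated modes the gap is undecidable and
   the test is disabled rather than risking a cut through a tissue mode.
   Testing the upper quartile rather than the median means only clusters
   essentially wholly below the gap are discarded; a cluster straddling
   the valley is kept, trading a few retained CSF voxels (harmless — they
   are not GM-labeled) against discarding cortical rim voxels (harmful).
2. **y rule** — `"low"` for GraMag histograms: count-weighted median y
   below the `gm_quantile` (default 0.9) of the binned gradient-magnitude
   distribution, excluding the vessel/dura arc.  `"central"` for ilr
   histograms: |median y − weighted median| below the `gm_quantile`
   (default 0.95) of that absolute deviation, excluding clusters spread
   away from the tissue axis in either direction.
3. **Density** (GraMag only) — voxels per occupied bin at least 0.3× the
   histogram-wide average.  Tissue classes of comparable volume form dense
   compact modes; a thin structure smears its few voxels across a wide
   intensity range, so its clusters are an order of magnitude sparser.
   This is what removes the ridge-crest dura voxels that the gradient axis
   cannot see; it is unnecessary for the compositional route, whose
   coordinates do not have the ridge blind spot.

Explicit node-id selection (`select_nodes`) and a circular-sector widget
remain available for scripted or manual transfer functions.

## Evaluation

DICE = 2|A∩B|/(|A|+|B|) on the GM label (1 when both sides are empty).
Boundaries are extracted as class-a voxels with a face neighbor
(6-connectivity) of class b — the thinnest well-defined interface layer —
for the WM–GM and GM–CSF interfaces.  The average Hausdorff distance is
the maximum of the two directed average nearest-neighbor distances
(both directed values are reported so either convention can be audited),
computed with a Euclidean distance transform and verified against an
all-pairs oracle.  Distances are in voxel-index units by default; a flag
switches to mm.

## Synthetic phantom

The methods operate purely in histogram space, so the phantom reproduces
intensity/gradient statistics, not anatomy: concentric spheres (WM core
r ≤ 14, GM shell ≤ 20, CSF shell ≤ 26 voxels on a 64³ grid), six radial
vessel tubes (radius 1.2 voxels) crossing the CSF shell from the GM
surface, and a thin dura-like cap (1.5 voxels) just outside CSF.  The cap
axis is oblique, (1,1,1)/√3: an axis-aligned flat sheet is a degenerate
geometry whose mid-line defeats central differences over a large patch,
which would violate the generator's premise that thin bright structures
carry very high gradients.  Default tissue means (arbitrary units,
t1w/pdw/t2sw): WM (100, 60, 45), GM (70, 75, 60), CSF (32, 95, 85),
vessel (160, 85, 20), dura (150, 65, 25) — fixture constants whose
orderings mimic the qualitative 7 T contrast behavior (vessels/dura bright
in T1w, CSF dark in T1w but bright in PDw/T2*w), not claims about MR
physics.  All contrasts share one smooth positive multiplicative bias
field, `exp(ln A · (g − ½))` with g a normalized off-center Gaussian bump
and peak-to-trough ratio A = 1.3.  Additive Gaussian noise is per-contrast;
the presets set σ to 0% (`clean`), 16% (`moderate_noise`) and 32%
(`high_noise`) of that contrast's GM mean.  Truth labels are noise-free and
everything is bit-reproducible per seed.

What the phantom does *not* emulate: folded cortical geometry, partial
volume mixing at interfaces, spatially correlated (physiological) noise,
susceptibility artifacts, and per-contrast bias differences (an option
exists to disable the common field).  Passing the recovery tests therefore
shows the histogram machinery separates the intended statistical
signatures; it does not certify performance on real acquisitions.

## End-to-end pipelines and problem sizes

`gramag_refine` masks the intensity volume, denoises it with Perona–Malik
diffusion (5 iterations, step 0.125, exponential conductance at 0.2× the
masked 1–99 percentile range — zero-flux boundaries conserve the mean),
computes the Scharr gradient magnitude, builds the histogram and tree, and
refines with the `"low"` rule.  `coda_refine` smooths the three contrasts
the same way, maps them through closure → standardization → ilr, and uses
the `"central"` rule.  The diffusion step follows the observation that at
moderate noise the histogram's separable shapes degrade and edge-preserving
smoothing restores them; conductance is computed from masked intensities
because unmasked ratio images contain noise-dominated air voxels that
poison a global range estimate.

The shipped validation scale is a 64³ phantom (≈74,000 brain voxels,
histograms with ≈2,000–4,000 occupied bins), where a full two-route run
with evaluation completes in about a minute; all statistical behavior the
tests rely on is stable from roughly 48³ upward.

On the moderate-noise phantom both routes remove ≥ 90% of vessel+dura
voxels from the corrupted GM while removing ≤ 5% of true GM, do not
decrease GM DICE, and cut the GM–CSF AVHD by well over 20%; the
compositional route is consistently the cleaner of the two (typically
≥ 97% removal at < 1% GM cost), mirroring its design intent.

## Known limitations

* The selection heuristic encodes one specific reading of "template-like"
  histogram shapes; its parameters (gm_quantile, density fraction, valley
  depth) are defaults for phantom-like data, not universal constants.
* The density rule assumes tissue classes of broadly comparable volume and
  can misjudge a genuine tissue class that occupies very few voxels.
* Compositions are restricted to exactly three parts (two ilr axes).
* The gradient route cannot remove ridge-crest voxels of thin sheets by
  gradient alone; in histograms without a clear sparse/dense contrast they
  will survive refinement.
* AVHD is reported as the max-of-directed-averages variant; tools that
  average the two directed values will report smaller numbers.
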