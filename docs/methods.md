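# Methods

## The reduction and its guarantee

The preprocessor discards points that cannot be vertices of the strict
convex hull (the extreme points of the set; collinear boundary midpoints
are excluded). It builds, from per-x-bin y-extremes, a **lower** and an
**upper fence**: x-sorted convex polylines anchored at the x-extreme
points. Every input point is then classified against exactly one fence
segment per side; points strictly outside either convex fence, plus the
fence vertices themselves, form the output.

Why no hull vertex is lost: a strict lower-hull vertex *v* lies strictly
below the chord between any two other input points spanning its abscissa
(the region above the lower hull is convex, and *v* on a chord would make
it a convex combination of input points, contradicting strictness). Fence
points are input points, so *v* is either a fence vertex itself, survives
convexification (it is never on/above a chord of its neighbours), or lies
strictly below its covering fence segment and is kept by the outside
test. The upper side is symmetric, and x-extreme ties are resolved
per side (lower fence endpoints take the minimum y among tied points,
upper the maximum), so a tied extreme can never hide strictly inside its
own fence. Points exactly *on* a fence segment are convex combinations of
two fence vertices and are correctly rejected.

The guarantee is at the level of vertex coordinates: when a hull-vertex
coordinate occurs multiple times in the input, ties (first-seen index in
per-bin extremes, smallest index in hull canonicalization) decide which
duplicate represents it.

## Constant-time rebinning

After convexification, the bin boundaries are no longer uniform: they are
the x-projections of the *surviving* fence points. Every fence slot
(m + 2 of them: endpoint, one per bin, endpoint) keeps its position in
the projection array `C`; removals — non-convex points, empty bins, and
a bin extreme coinciding with an endpoint — are flags, and `S` is their
inclusive prefix sum. The new label of a point with old uniform label
*q* is `q + 1 − S[q+1]` if `x ≥ C[q+1]`, else `q − S[q]`. Because a
point's own bin slot is never empty and neighbouring slots bound its bin
interval, this equals a binary search of *x* over the surviving
boundaries (counting boundaries ≤ *x*), clamped to the last segment for
*x* = x<sub>max</sub>; the test suite asserts that equivalence on every
point of every randomized instance. Empty-bin slots carry the bin's left
edge as a placeholder abscissa purely to keep `C` non-decreasing — no
point ever carries an empty bin's label, so placeholders are never read
by the branch test.

## Numerical conventions

* Orientation tests are plain double-precision cross products with exact
  sign (no epsilon); robust/exact arithmetic is out of scope. Consequently
  the package is reliable for exactly representable degeneracies (integer
  or dyadic coordinates) but, like any non-robust geometric code, can make
  epsilon-level decisions on inputs that are collinear only up to floating
  rounding. The degenerate test families are therefore built on integer
  coordinates, where every predicate is exact.
* Bins are half-open `[left, right)` with the last bin right-closed and
  x = x<sub>max</sub> clamped into bin m (the standard histogram
  convention; boundary membership is otherwise arbitrary).
* Convexification removes collinear fence points (strict convexity), and
  all hulls return strict vertices only: collinear input collapses to a
  2-vertex segment, coincident input to a single vertex. Canonical hull
  order is counterclockwise from the lexicographically smallest (x, then
  y) vertex, which makes vertex sequences directly comparable.
* Degenerate reduction paths: n ≤ 3 returns all indices; an all-equal-x
  input returns its min-y and max-y indices; m is clamped to at most n.
  These paths are this package's choices for inputs the method itself
  does not define.

## Parameters

* **m** (bin count): the only tuning parameter. Larger m tracks the
  boundary more tightly (higher reduction) at O(m) extra fence work; the
  useful region is between 10 and lg n. `choose_m` defaults to 10 for
  lg n ≥ 10 (10 is also the histogram default in Matlab and R) and
  max(2, ⌊lg n⌋) below; a `"lg"` mode selects ⌈lg n⌉ for size-dependent
  comparisons. Both are clamped to n.
* **Superellipse generator**: uniform samples in |x/a|^t + |y/b|^t ≤ 1 by
  rejection from the bounding box (exactly uniform; worst-case acceptance
  1/2 at t = 1). Convexity requires t ≥ 1. For "randomly shaped convex
  superellipse" experiments the shape exponent is drawn t ~ U[1.5, 8] and
  the aspect a/b ~ U[0.5, 2]: the range sweeps rhombus-like (low t) to
  rounded-rectangle (high t) supports.

## What the synthetic experiments do and do not show

The generator produces i.i.d. uniform points in convex supports — the
well-behaved regime in which every bin is populated and fences hug the
boundary. Real datasets (scan projections, GPS fixes, segmented images)
are neither uniform nor convexly supported; empty bins and uneven density
reduce how tightly fences track the point cloud, so measured reduction
percentages on synthetic data do not transfer to arbitrary real data,
although the hull-preservation guarantee always holds.

Two empirical facts about the superellipse experiment, both computed by
the acceptance script and tests:

* The reduction percentage is exactly invariant under anisotropic axis
  scaling (bin labels and orientation signs are unchanged), so only the
  shape exponent t matters. It decreases monotonically in t: at
  n = 10⁶, m = 10, from ≈99.9% (t = 1) through ≈96.6% (t = 2) to ≈91.7%
  (t = 8). High-t shapes have steep left/right sides whose outermost-bin
  points fall outside the first/last fence segments and must be kept.
* Averaged over t ~ U[1.5, 8] the mean reduction at m = 10 is ≈93%,
  and at m = 20 ≈97%. With the bin count in the upper part of the
  recommended region (around lg n = 20) the experiment clears 95%
  regardless of shape mix; at m = 10 the mean depends on how much weight
  the shape distribution puts on high t.

Wall-clock speedups are reported by the bench harness but never asserted:
they are hardware facts. One identity *is* asserted — substituting the
estimator k = t_n(n−s) / (n(t_r+t_s) − s·t_n) into the Amdahl prediction
1/((1−p_r) + p_r/k) returns exactly t_n/(t_r+t_s), so prediction and
measurement agree to floating-point tolerance by construction; the
decomposition's value is the interpretable k, not an independent check.

## Design choices in the hull algorithms

* The production hull is Andrew's monotone chain. Chan's algorithm
  follows the classic construction: round t guesses h_t = min(n, 2^(2^t)),
  partitions into groups of that size, computes group sub-hulls with the
  monotone chain, and gift-wraps across sub-hulls; the tangent into each
  sub-hull uses a binary search over the convex polygon for larger
  sub-hulls, with a local-optimality check that falls back to a linear
  scan in degenerate configurations so a wrap step is never wrong.
* The Jarvis march shares no code with the other two (its own
  deduplication, its own inlined cross products) so that three-way agreement
  in tests is evidence rather than tautology.
* Fence convexification uses the one-pass monotone-chain stack scan; a
  general simple-polyline convexifier (Melkman's deque) reduces to this
  in the x-sorted setting.

## Problem sizes used by the checks

The acceptance experiments use n = 10⁶ with five seeded runs per bin
count; the property suites use 1000 randomized instances (n up to 5000)
for hull preservation and rebin-oracle equality and 500 instances (n up
to 2000) for cross-algorithm hull equivalence, sizes at which the whole
suite completes in well under a minute while exercising every degenerate
family.

## Known limitations

* Single-threaded by design; the independence of the two fences and of
  the per-segment point checks is documented but not exploited.
* Non-robust floating-point predicates (see above).
* The m heuristic assumes point sets of at least a few hundred points;
  for tiny inputs the reduction cannot pay for itself.
* 2D only.
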