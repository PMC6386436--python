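# hullprep

Linear-time reduction of 2D point sets for fast convex hull computation.

Many workflows end in a planar convex hull: minimum convex polygons over
animal relocation fixes in home-range ecology, outlines of segmented
structures in biomedical images, bounding shapes over dense 3D-scan
projections. The hull itself has only a handful of vertices, yet every
hull algorithm must look at all *n* input points. `hullprep` implements a
preprocessing method that reduces the *n* points to a small subset of *s*
points — typically a few percent of the input — whose strict convex hull
is provably identical, in O(*n*) time and without sorting, so that any
hull algorithm run afterwards does a fraction of the work.

## The method

Given points *P* with coordinate vectors *X*, *Y*:

1. Find the points with smallest and greatest *x* (*p<sub>xmin</sub>*,
   *p<sub>xmax</sub>*).
2. Quantize every point into *m* equal-width *x*-bins (label
   *q* = ⌊(*x* − *x*<sub>min</sub>)/*w*⌋ + 1, *w* = range/*m*).
3. In one pass, record each bin's minimum-*y* and maximum-*y* point.
4. Join *p<sub>xmin</sub>*, the per-bin minima, and *p<sub>xmax</sub>* into
   the x-sorted **lower fence** polyline (maxima for the **upper fence**).
5. Remove non-convex fence points with one stack scan per side.
6. Re-label every point against the *non-uniform* intervals induced by the
   surviving fence vertices — in O(1) per point, using the old label *q*
   and a prefix sum *S* over the removed-slot flags:
   *q*′ = *q* + 1 − *S*[*q* + 1] if *x* ≥ *C*[*q* + 1], else
   *q*′ = *q* − *S*[*q*] — then keep exactly the points strictly outside
   their fence segment (one cross-product sign test each), plus the fence
   vertices themselves.

Everything between the two convex fences is discarded; the kept subset
has the same strict hull vertices as the input, so downstream hulls are
unchanged. The reduction factor is *p<sub>r</sub>* = 1 − *s*/*n* and the
speedup from preprocessing is *t<sub>n</sub>* / (*t<sub>r</sub>* +
*t<sub>s</sub>*), which the benchmark harness also decomposes through
Amdahl's law (enhanced fraction *p<sub>r</sub>*, enhanced speedup
*k* = *t<sub>n</sub>*(*n* − *s*) / (*n*(*t<sub>r</sub>* + *t<sub>s</sub>*) −
*s·t<sub>n</sub>*)).

The package also ships three self-contained hull algorithms — Andrew's
monotone chain, Chan's output-sensitive O(*n* lg *h*) algorithm, and a
gift-wrapping (Jarvis march) oracle used for independent verification — a
uniform-superellipse sample generator, and a benchmark harness.

## Worked example

```python
>>> import numpy as np, hullprep as hp
>>> pts = hp.make_fixture("square_plus_center")   # (0,0),(4,0),(4,4),(0,4),(2,2)
>>> r = hp.reduce_points(pts, m=2)
>>> r.indices, r.s, round(r.reduction_factor, 2)
(array([0, 1, 2, 3]), 4, 0.2)
>>> hp.monotone_chain_hull(pts.take(r.indices)).coords().tolist()
[[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]]
```

The center point (2, 2) is discarded (20% reduction on this tiny input)
and the hull of the kept subset is the original square, counterclockwise
from the lexicographically smallest vertex. At realistic sizes the
reduction is far stronger:

```python
>>> pts = hp.sample_superellipse(hp.SuperellipseSpec(n=1_000_000, t=2.0, seed=1))
>>> r = hp.reduce_points(pts, m=10)
>>> r.s, round(100 * r.reduction_factor, 2)
(33417, 96.66)
```

96.66% of one million points are removed before the hull algorithm runs.

The same operations are available from a shell:

```sh
hullprep simulate --n 1000000 --t 2 --seed 1 -o points.csv
hullprep reduce -i points.csv --m 10 -o kept.txt --stats stats.json
hullprep hull -i points.csv --algorithm chan -o hull.csv --geojson hull.geojson
hullprep bench --synthetic 1000000 --m-list 10,20 -o bench.csv
```

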