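# boxid

Box-counting intrinsic dimensionality of multi-dimensional human behavioral
sensor data.

Smartphone telemetry studies collect many channels at once — GPS position,
accelerometer activity, battery state, WiFi visibility — and most analyses
implicitly assume each channel adds independent information. `boxid` asks
the opposite question: **how many dimensions are actually needed to
represent such a dataset?** It answers with the box-counting (fractal)
dimension, which makes no linearity assumption, and contrasts it with what
PCA says under a linear assumption.

## The method

Each duty-cycle observation is reduced to a normalized 7-tuple
*t* = (hour, lat, lon, acc, stddev, bat, wifi) ∈ [0, 1]⁷. The points are
inserted into an *n-D tree*: a recursive decomposition of the unit
hypercube in which any node holding more than one point splits into 2^d
half-side children, while a node holding exactly one point is *frozen* and
never expanded. At level *l* the boxes have side ε ∝ 2^−l, and the number of
occupied boxes is

    N(ε) = (nodes with data at level l) + (leaves frozen above level l).

The box-counting dimension is the limit slope

    D_box = lim_{ε→0} log N(ε) / log (1/ε),

estimated in practice as the slope of the *linear region* of the log-log
curve: the prefix of levels before N(ε) saturates toward the sample size.
The end of that region is detected from the tree itself (the first level
where the count of nodes with data decreases, guarded against saturation),
two least-squares lines are fitted — over the detected prefix and over the
prefix extended by one level — and their average slope is the reported ID.
A sample-size check (d < 2·log₁₀ n) warns when the estimate cannot be
trusted.

Because the tree stores its points, its structure is itself informative:
per-level occupancy proportions (which decay like c/level), the level
holding the plurality of frozen leaves, and treemap exports. PCA cumulative
inertia and the feature correlation matrix provide the linear baseline.

The study datasets this pipeline was designed around are not public, so the
package ships a synthetic generator (`gen_shed_like`) that emulates their
structure — duty-cycled sampling, anchor-based mobility in an urban bounding
box, diurnal charging, activity-coupled accelerometer statistics,
location-dependent WiFi — plus geometric generators (Sierpinski gasket,
embedded k-planes) with known dimension for validation.

## Worked example

```
$ boxid run-all --seed 1 --out out/
n = 61583, ID = 3.584, k90 = 5, break level = 7
```

This simulates 20 participants over 14 days (≈80k duty cycles), preprocesses
the four raw streams into 61,583 normalized 7-D records, builds the 7-D
tree (depth 12), detects the break at level 7 (the tree's maximum
expansion; the plurality of frozen leaves also sits at level 7), fits the
two lines, and reports their averaged slope **ID ≈ 3.6**: the simulated
behavior occupies far fewer than 7 effective dimensions. The PCA baseline
needs **k90 = 5** components to reach 90% of the variance (cumulative
inertia 0.32, 0.52, 0.68, 0.83, 0.94, …), more than the intrinsic estimate —
the signature of non-linearly related features. The only strong pairwise
correlation is accelerometer mean vs. its standard deviation (r ≈ 0.96),
exactly the pair the generator couples through a shared activity level.
`out/report.json` holds the full report; per-level statistics, log-log
coordinates, PCA loadings and the correlation matrix are written alongside
as CSV.

The same estimator recovers known ground truth: a 100,000-point
chaos-game Sierpinski gasket yields ID ≈ 1.60 (similarity dimension
log 3 / log 2 ≈ 1.585), and k-dimensional slices of [0,1]⁷ return
1.00 / 2.00 / 2.99 for k = 1, 2, 3.

Python API:

```python
from boxid import gen_sierpinski, estimate_intrinsic_dimension

pts = gen_sierpinski(100_000, seed=42)
res = estimate_intrinsic_dimension(pts)
print(res.estimate.id_value)        # 1.597...
```

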