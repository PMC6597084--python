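# Methods

## Model and procedure

`boxid` estimates the intrinsic dimensionality (ID) of a point cloud in
[0, 1]^d by the box-counting dimension

    D_box = lim_{ε→0} log N(ε) / log(1/ε),

where N(ε) is the number of axis-aligned hypercubes of side ε containing at
least one point. The limit is approximated from a finite sample by a
hierarchical decomposition (the *n-D tree*) rather than by re-gridding at
every scale:

1. Every point is inserted into a tree whose root spans [0, 1] on all axes.
   A node's per-axis ranges are half-open, (a, b]; the root alone is closed
   below so that a coordinate exactly 0 (which the battery encoding
   produces) is insertable.
2. A node holding one point is **frozen** — never expanded. When a second
   point arrives, the node splits into 2^d children of half the side, and
   the cohabiting points descend together until they separate into distinct
   children (or the depth cap is reached).
3. N at level l is the number of nodes with data at that level **plus** all
   leaves frozen at shallower levels, so every point is counted at every
   scale. Per level, the side length is ε = 1/(d·2^l); the 1/d factor
   shifts log(1/ε) by a constant and cancels in every slope.

The tree is lazy: only occupied children are materialized. The per-level
"nodes allocated" statistic nevertheless follows sibling accounting (a split
allocates all 2^d children), computed analytically as 2^d per split node, so
occupancy proportions refer to the full set of cells a split creates.

Midpoints are produced by repeated halving from [0, 1] and are exact dyadic
binary floats; two distinct points always separate at the level set by their
coordinate difference (verified to level 49 in the tests), far shallower
than the default depth cap of 64. At the cap, unseparated points collapse
into one leaf with multiplicity and a warning — with deduplicated input this
is unreachable in practice.

## Linear-region selection

With finite n the log-log curve is linear only over a prefix: once N
approaches n, the curve flattens into an asymptote and any fit crossing the
knee is biased low. Two signals bound the region:

* **break level** — the first level at which the count of nodes with data
  strictly decreases (plateaus are skipped). This is the tree's maximum
  expansion; beyond it insertion slows and the asymptote begins. The fit
  prefix ends one level before the break.
* **saturation guard** — levels where N already exceeds a fraction
  (default 0.1) of the final count are excluded regardless of the break.
  On behavioral-style profiles the break binds first; on rapidly-saturating
  geometric sets (a 3-plane at n = 10^5 saturates three levels before its
  break) the guard is what keeps the fit on the linear part, and without it
  the estimate for a 3-plane is low by ≈ 0.4.

Two ordinary least-squares lines (base-10 logs; the base cancels) are fitted
over levels 1..L and 1..L+1 — level 0 is the degenerate point log N = 0 —
and the reported ID is the mean of the two slopes, bracketing the onset of
the asymptote from both sides. An explicit fit level can be forced when no
break exists (a monotone profile) or for sensitivity analysis.

The estimate is accompanied by the sample-size check d < 2·log₁₀ n; a
violation warns (the estimate is still returned) because the asymptotic
count n can then be too small for the linear region to develop.

## Preprocessing conventions

Raw streams are aggregated per participant per duty cycle (period 300 s,
assignment by floor(t/period)): most recent in-cycle value for GPS, battery
and the timestamp that yields the hour feature; mean and **population**
standard deviation (ddof = 0; the convention is not forced by the math,
only consistency matters) of per-sample accelerometer L2 norms; count of
distinct WiFi MACs. Cycles lacking any stream — most importantly a GPS fix
(indoors) — are dropped whole. Geographic filtering is inclusive at the
bounds. Outlier removal on both accelerometer features is a single pass at
3 dataset-wide SDs, not iterated. Hour is divided by 23 so the feature
attains both 0 and 1; battery uses fixed codes 0, 0.25, 0.5, 1 (the gap at
0.75 is deliberate and kept); the remaining features are min-max scaled with
dataset-wide bounds. Zero-WiFi rows are removed before scaling, and exact
duplicate 7-tuples are dropped last (they would otherwise collapse into a
single deep chain of the tree). A degenerate feature (min = max) is set to 0
with a warning rather than failing the run. Every stage records its row
count in the provenance report.

## Synthetic data: what it emulates, what it does not

`gen_shed_like` emulates the *structure* of duty-cycled smartphone studies:

* 2–3 Gaussian anchor clouds (home / work / third place) per participant
  inside a ~17 km urban bounding box, GPS noise SD 1e-4° (≈10 m), 20% of
  cycles with no fix, 5% transit cycles uniform over the box;
* accelerometer bursts of 12 samples whose noise scale (0.02 + 0.8·a) and
  sustained-motion offset (2·a) both follow a per-cycle activity level *a* —
  this shared driver is what makes the per-cycle mean and SD of the norm
  strongly correlated, and the overnight/sedentary near-zero activity makes
  resting records nearly coincident, which is what pushes leaf freezing into
  the mid levels (break ≈ 7 at 20 participants × 14 days) the way real
  telemetry behaves;
* diurnal battery charging (overnight "Charging AC" with probability 0.9)
  and anchor-specific WiFi router sets.

The defaults above are the package's study conditions; noise magnitudes are
free parameters chosen once at values a field practitioner would call
realistic. The generator does **not** reproduce real street topology,
demographics, weekly rhythms, or map-matched trajectories, so passing tests
demonstrate that the estimator behaves correctly on data with this
covariance and clustering structure — not that any particular real
population has a given ID.

Geometric generators provide exact ground truth: the chaos-game Sierpinski
gasket (similarity dimension log 3/log 2 ≈ 1.585; 100 burn-in iterations
discarded) and uniform k-planes embedded in [0,1]^d with free axes uniform
and fixed axes at the interior value 0.5, so boundary-membership rules are
never stressed in recovery tests.

## Numerical and design choices

* ε per level is 1/(d·2^l); all slopes are invariant to the 1/d factor.
* Fits use `numpy.polyfit` degree 1; r² is reported per fit and, for the
  non-linear c/level sparsity trend, flagged as indicative only. The trend
  coefficient has the closed form c = Σ(p_l/l)/Σ(1/l²) over levels
  1..24 — deeper levels sit below the sensor noise floor and are excluded.
* Ties in "most recent value" aggregation are broken by input order (keep
  last); duplicate timestamps in one stream log a warning.
* PCA is covariance-based (features already share the [0,1] scale);
  eigenvector signs are fixed so the dominant loading is positive.
  Correlation entries involving a zero-variance feature are reported as
  missing, never as 0.
* Problem sizes: validation uses 10^5-point geometric sets and a
  20-participant × 14-day simulated study (~6×10^4 records), sizes at which
  the linear region spans enough levels for stable slopes while a full run
  completes in seconds.

## Known limitations

* The estimator reports *how many* dimensions are needed, not *which*
  combinations of features span them.
* The two-prefix average inherits a mild sensitivity to where the break
  falls; profiles with long plateaus can shift the detected break by a
  level, moving the estimate by a few hundredths.
* Highly curved or multiscale manifolds whose linear region is shorter than
  three levels cannot be fitted reliably; the Camastra warning fires well
  before this regime for 7-D data.
* Tree memory is O(n · separation depth); datasets with millions of
  near-duplicate records would need the depth cap lowered or external
  deduplication first.
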