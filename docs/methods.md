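# Methods

## The measurement model

A gel photograph is a height × width grid of intensities in [0, 255], row 0
at the wells. A DNA fragment's migration distance d (pixel rows from the
top) relates to its molecular weight W by the log-linear electrophoresis
law

    ln W = α·d + β,      α < 0,  β > 0,

valid over the resolving range of the gel. α is negative because heavier
fragments travel less; β absorbs the well offset and the gel/voltage/time
conditions. Everything downstream — sizing, matching, Dice distances,
trees — is built on the detected (lane, d) pairs.

Intensities are held as floats internally (so background subtraction can
be exact) and rounded/clamped to 8-bit only on export. Rotation is
restricted to quarter turns plus cropping: that is enough to put the wells
at the top and avoids interpolation artifacts that free-angle resampling
would introduce into the profiles.

## Lane detection

Lanes are plateaus of the column-maximum profile `p[c] = max_r image[r, c]`.
The detector:

1. seeds candidate runs at `hi = 0.70 · max(p)` — at this level almost
   everything above threshold is a real lane;
2. drops candidates thinner than the candidates' mean width (strictly `<`),
   then re-averages the survivors to the typical width m (a user-supplied
   lane width replaces m and skips the estimate);
3. sweeps the threshold from `hi` down to `lo = 0.15 · max(p)` in steps of
   1% of `max(p)` (a fixed grid keeps the sweep deterministic), accepting
   runs with width in `m·(1 ± 0.25)` that do not overlap a lane accepted at
   a higher level — higher-intensity evidence wins conflicts;
4. returns lanes sorted left to right.

All thresholds are fractions of the profile maximum, so detection is
invariant to overall exposure. The width-deviation test uses the mean m
fixed in step 2 throughout the sweep; re-updating m during the sweep would
make acceptance order-dependent.

Background subtraction is per lane: the row-wise mean across the lane's
columns is passed through a rolling minimum and then a moving average, both
of window ⌈height/20⌉, and the result is subtracted from every column
(clamped at 0). The rolling minimum ducks under narrow bright bands — so
bands survive — while tracking the slow background; the moving average
smooths the staircase the minimum leaves. The window is a fixed fraction of
the image so behaviour scales with resolution. Pixels outside all lanes are
zeroed. On a constant background the operation is idempotent.

## Band detection

A lane's profile is the row-wise sum over its columns. It is smoothed by
the centered moving average

    xF[i] = 1/(2·width+1) · Σ_{k=i−width}^{i+width} x[k]

applied `passes` times, with edge replication at the boundaries (so
constants are preserved exactly, including at the edges). Defaults
width = 2, passes = 1; larger images warrant larger values. Bands are the
local maxima of the *filtered* profile with value ≥ 20 × lane width;
smoothing first is what suppresses false single-row peaks. Plateau maxima
collapse to their center row (floor of the midpoint). No minimum peak
separation is imposed beyond strict local maximality. The threshold factor
20 is an intensity-per-column-width scale: a genuine band contributes its
amplitude across the full lane width, noise does not.

## Weight calibration

Marker standards are text files (`name`, band count, then weights strictly
decreasing, one per line) in a `standards/` directory. Fitting is ordinary
least squares of ln W on d, with strictly positional pairing: the i-th
shallowest detected marker band takes the i-th largest standard weight. A
count mismatch is an error, not a guess — detection should be corrected
(bands added/removed) rather than silently sub-assigned. Violations of
α < 0 or β > 0 warn but do not fail, since noisy user data can cross those
signs while remaining usable. Duplicate distances are accepted (OLS is
defined); only an all-equal design is singular. Marker lanes are excluded
from matching and tree building by default (`include_markers` restores
them), since ladder bands are not sample characters.

## Band matching and Dice distance

Matching partitions all bands into clusters under two hard constraints: a
cluster never holds two bands of one lane, and no two members differ in
migration distance by ≥ 2% of the image height (tunable). The construction
is a single greedy sweep over bands sorted by (distance, lane): each band
joins the open cluster when both constraints hold, otherwise the cluster
closes and a new one opens. This is deterministic and linear-time; other
partitions satisfying the same constraints can exist, and ties are broken
by the sort order. Because the sweep visits bands in depth order, the
distance check against the cluster's shallowest member bounds the cluster's
full spread.

The clusters × lanes 0/1 matrix (rows ordered by mean depth) yields

    S(i,j) = 100 · 2·c_ij / (n_i + n_j)    [Dice, percent]
    D(i,j) = 100 − S(i,j)

with c_ij the shared band classes and n_i the lane's band count (the
column sum — identical, since matching is a partition). A lane with zero
bands makes S undefined and raises an error naming the lane. D is not
guaranteed to satisfy the triangle inequality; none of the tree methods
below requires it.

## Tree building

* **Neighbor Joining** (Saitou–Nei, Studier–Keppler criterion
  `Q(i,j) = (n−2)·d(i,j) − r_i − r_j`): joins the Q-minimal pair, assigns
  limb lengths `d(i,j)/2 ± (r_i − r_j)/(2(n−2))`, reduces the matrix, and
  ends at a 3-way anchor (single edge for n = 2, serialized `(a:D,b:0);`).
  On additive matrices the tree's path lengths equal the input exactly.
  Negative branch lengths are kept as computed, matching Phylip's default.
* **UPGMA / WPGMA / single / complete linkage**: merge the closest pair at
  height d/2; distances to the merged cluster update by the size-weighted
  mean, the simple mean, the minimum, or the maximum respectively. Child
  branch length = parent height − child height. All four linkages are
  monotone, so trees are ultrametric with non-negative branches by
  construction; UPGMA reconstructs ultrametric inputs exactly.

Ties in either method go to the lexicographically smallest index pair, for
determinism. Newick output carries branch lengths at 6 significant digits
by default (a `precision` argument raises this when exact round-tripping
matters); parsing is delegated to Bio.Phylo and re-validated (unique,
non-empty leaf labels). Phylip square matrices are read and written so the
pipeline can be entered at the tree stage.

## Synthetic gels

The generator composes, per scene: a background `level + tilt·row`, per
fragment a Gaussian bump in the row direction (sd `band_sigma`, default 2
rows) spanning the lane's columns at `row = (ln W − β)/α`, and optional
seeded additive Gaussian noise, clamped to [0, 255]. Defaults emulate a
well-exposed UV photograph: 20-column lanes, 8-column gaps, 500-row gel,
background 10, band amplitude 180 (230 in the randomized benchmark scenes,
i.e. bright but below saturation, with noise σ = 23 for a signal-to-noise
ratio of 10). Ground-truth rows are real-valued; detection comparisons
round to the nearest row.

The benchmark generator (`random_scene`) draws 8–16 lanes with 2–10 bands
each from a 15-row grid, so in-lane bands never blend. Real gels deviate
from this model in ways the generator deliberately omits — lane smiling,
smearing, saturation blooming, spatially correlated illumination — so
passing detection benchmarks here demonstrates correctness of the
algorithms under the stated model, not performance on degraded photographs;
the manual add/remove operations and the tunable thresholds exist for those
cases.

## Numerical and design notes

* Grayscale conversion uses luminance weights (0.299, 0.587, 0.114); the
  tests only assume a convex combination, so any fixed weighting passes.
* Profiles, matrices and images are numpy float64 end to end; similarity is
  kept on the 0–100 percent scale throughout.
* `fit_migration_model` is exactly testable: collinear points in
  (d, ln W) space are interpolated to machine precision.
* Degenerate inputs fail loudly and specifically: flat profiles ("no
  signal"), empty lanes in Dice, asymmetric or non-zero-diagonal distance
  matrices, out-of-gel fragments in scenes.
* Problem sizes in the test and acceptance runs (200 additive trees up to
  12 leaves, 100 clock trees, 100 random presence matrices up to 50×20, 20
  synthetic gels of up to 16 lanes, 100 calibration replicates) were chosen
  to exercise the full input ranges while keeping a complete run near
  interactive speed.

## Known limitations

* Lanes are strictly vertical strips; skewed or curved migration is out of
  scope (crop/rotate are the remedies).
* One marker calibrates the whole gel; nonlinear migration models and
  multi-marker interpolation are not implemented.
* Band matching is by pixel distance within one image, so fingerprints from
  different gels cannot be combined.
* Dice distances are percent dissimilarities, not evolutionary distances;
  branch lengths inherit that scale.
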