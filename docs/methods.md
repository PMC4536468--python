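# Methods

This note documents the models, estimators and design choices behind
`spindlemetrics`, in the spirit of a methods appendix: what is computed,
under which assumptions, with which defaults, and what the synthetic tests
do and do not demonstrate about real data.

## Coordinate and data conventions

All positions are metric (μm), with any voxel anisotropy (e.g. 0.5-μm
z-steps) applied upstream of the package; the pipeline never sees pixels.
Frames are 0-based integers; times are in seconds and must increase
strictly with frame within a cell. The detection-table schema is a fixed
CSV contract (`cell_id,frame,time_s,channel,x_um,y_um,z_um,intensity`)
chosen to be unambiguous and diff-friendly. Channels name what the point
is: `CENTRIOLE` (centrin), `KT_INNER` (CENPA-like inner kinetochore),
`KT_OUTER` (HEC1-like outer kinetochore), `ATTACH_MARK` (SKAP-like
attachment-maturity marker), `CORTEX` (cell-boundary reference points).

## Spindle geometry

**Pole clustering.** The 2–4 centriole detections of a frame are split into
two poles by exhaustive enumeration of all 2-group partitions (≤ 7),
minimizing the total within-group pairwise distance. With centrioles ≤ 0.5 μm
apart within a pole and poles ~10 μm apart this is unambiguous; a tie
within 1e-6 μm raises rather than guessing.

**Reference pole.** R's numerator side is the pole containing the single
brightest centriole (the grandmother, by centrin-intensity age ordering).
In 2:1 cells the convention is overridden: the 2-centriole pole is the
numerator regardless of brightness. Equal-brightness ties raise an error;
the generator never emits them.

**Plate plane.** Total (orthogonal) least squares: the plane through the
kinetochore centroid whose normal is the smallest principal axis of the
centered cloud. There is no privileged coordinate axis in 3D localization
noise, which is why orthogonal rather than ordinary regression is used.
Fewer than 3 points, or a collinear cloud (second singular value ≤ 1e-12
of scale), is an error.

**Plate position and R.** The spindle axis is the line through the two
pole *centroids* (intensity-unweighted — centriole spread within a pole is
two orders of magnitude below pole separation, so weighting is immaterial).
The plate point is the plane/axis intersection `p0 + t·û` with
`n̂·(p0 + t·û) = d`; `L1`, `L2` are its distances to the reference and
other pole, `R = L1/L2`. An axis within 1e-6 of parallel to the plane is an
error; an intersection outside the pole-to-pole segment (possible in late
anaphase or pathological frames) is flagged but still yields R.

**Spindle-center offset.** The spindle center is the pole-centroid
midpoint; the cell center is the midpoint of the two axis–cortex
intersections, taking on each side the cortex point nearest the axis and
projecting it onto the axis. The offset is the Euclidean distance between
the two centers.

**Pole intensity asymmetry** is the normalized signed difference
`(I1 − I2)/(I1 + I2)` in [−1, 1], antisymmetric in its arguments. This is
the package's declared asymmetry index; other normalizations exist and any
monotone variant would order cells identically.

## Kinetochore kinetics

**Sister pairing.** Candidate kinetochore pairs within a 2.0-μm gate are
accepted greedily in increasing distance order (ties by lowest index) —
the iterated closest-pair rule, which accepts exactly the mutual nearest
neighbors at each stage. The 2.0-μm gate is roughly twice the inter-sister
rest length and excludes cross-plate pairings at typical plate geometry.
Pairing is well posed only when neighboring pairs sit farther apart on the
plate than sisters do across it (≥ 1.5 μm spacing at a 1-μm rest length);
the generator enforces that spacing, and real data that violate it would
need an orientation-aware pairer (a known limitation).

**Distances.** Inter-kinetochore distance is the per-frame Euclidean
distance between sisters (inner marker), a centromere-tension proxy; gaps
are left as gaps, never imputed. Intra-kinetochore stretch is
`δ = (d_outer − d_inner)/2` from the outer–outer and inner–inner sister
distances; it is linear in its arguments, may legitimately be negative
under noise, and in fixed snapshots each inner point's outer partner is the
nearest outer detection.

**Oscillation analysis.** The pair center projected onto the signed
spindle axis (origin at the spindle center, positive toward the reference
pole) gives one series per pair. Its autocorrelation is mean-subtracted
and biased-normalized (`ac[k] = Σ x̃ₜx̃ₜ₊ₖ / Σ x̃ₜ²`, division by N rather
than N−k), which trades a known taper for stability at large lags. Gaps up
to 20% of frames are tolerated by averaging valid products and rescaling
with the biased taper; at least 8 valid samples are required, and a
constant series raises. Per-cell profiles average pairs pointwise; cohort
profiles average cells equally. The half-period is the lag of the first
strict local minimum deeper than −0.1; the depth threshold rejects shallow
noise dips, which also means white-noise-like series correctly produce no
call. On a discrete lag grid the estimate is the grid point nearest T/2,
so it is accurate to one sampling interval by construction.

## Phenotype classifiers

- **Anaphase onset**: first frame where the cross-pair median
  inter-kinetochore distance reaches 1.5× the median of the first three
  frames and stays there for 2 consecutive frames (single-frame spikes do
  not trigger). The rule is a package-defined operationalization — onset
  is scored from images in live-cell practice — and is validated against
  generator ground truth (±1 frame). R "at anaphase onset" is taken from
  the last frame before the detected/annotated onset.
- **Rotation**: the pole-identity-signed axis, projected to XY, compared
  with the first usable frame; the cell is rotating when the maximal net
  orientation change strictly exceeds 90°. The cumulative path angle is
  also exposed but is not the call. Frames with an axis parallel to Z are
  skipped with a warning.
- **Division symmetry**: daughter size ratio max/min strictly > 1.2. "Size"
  is whatever positive scalar the upstream measurement provides (area or
  volume); the ratio semantics are identical.
- **Attachment maturity**: a kinetochore is marker-negative below 0.3× the
  cell median marker intensity (intensity scales vary between cells, hence
  a relative cutoff); a pair counts when ≥ 1 member is negative; the cell
  is positive when the negative-pair fraction strictly exceeds 30%.
- **Minus-end asymmetry**: fold-change call at 1.5× (analyst-set and
  flagged as such; configurable).

All boundary comparisons are strict and tested at the boundary (ratio 1.2,
90°, 30%).

## Cohort statistics

Per-cell metaphase R is the mean of the first three available frames —
the earliest-timepoint convention, before centering has had time to act;
`k_first` is configurable down to 1. R-distribution summaries report the
median and the fractions strictly below 0.85 / strictly above 1.15.
Anaphase-aligned trajectories re-index each cell to time-to-anaphase,
report cross-cell medians per dt-bin (≥ 3 cells), and attach 95% percentile
bootstrap bands from resampling cells with replacement (1000 draws,
seeded); bootstrap-of-cells is the declared CI choice.

The test battery (two-sided throughout, raw p-values, no multiplicity
correction — the reports say so) is computed with scipy.stats behind the
package surface: Welch t (Welch degrees of freedom), Mann–Whitney U (exact
null when both n ≤ 20 and no ties, else normal approximation with tie and
continuity correction; the choice is recorded in the result), Levene
(mean-centered), paired t, Fisher exact (two-sided by summing
hypergeometric probabilities ≤ the observed table's) and the exact
binomial (summing P(X=i) ≤ P(X=k)). The test suite re-derives these
against independent enumeration and permutation oracles. One calibration
caveat is intrinsic, not implementational: exact conditional tests on
discrete data are conservative, so the two-sided Fisher test's true type-I
rate at n = 30 per group is ≈ 0.027, below the nominal 0.05 regardless of
implementation.

## The synthetic generator

The generator emulates live metaphase imaging of HeLa-like cells (5-min
videos at 7.5-s sampling by default; a long regime of 15 min at 30 s is a
parameter change): two poles 10 μm apart, centrioles within 0.5 μm of
their pole with centrin levels 4:3:2:2 (grandmother:mother:daughters,
grandmother at the reference pole), ~23 sister pairs on a plate disc of
radius 4.5 μm, isotropic Gaussian localization noise (default 0.05 μm),
two on-axis cortex points on an 18-μm cell axis.

Model choices, each the simplest form with a defined, testable signature:

- **Plate offset**: the plane/axis intersection divides the axis at the
  target ratio; per-cell initial R is lognormal around the cohort target
  (median exact). The default spread σ = 0.13 reproduces the dispersions
  reported for live metaphase populations (~24% of a centered cohort
  outside the 0.85/1.15 boundaries; ~40% of a median-1.12 cohort above
  1.15).
- **Centering**: exponential relaxation of the plate offset toward zero
  with time constant `centering_tau_s` — one parameter, monotone, and the
  observed signature (median R → 1 before anaphase) follows from it. No
  mechanistic force model is implied.
- **Oscillations**: per-pair sinusoid along the axis, common period
  (default 80 s), amplitude 0.3 μm, independent uniform phases. Live
  kinetochores oscillate quasi-periodically without a published generative
  model; a sinusoid is the minimal process with a closed-form
  autocorrelation (`cos(2π·lag/T)` times the biased taper), making the
  half-period estimator exactly checkable. Defaults are conventional for
  mammalian kinetochore oscillations, configurable, and not data-derived.
- **Pair placement**: Poisson-disk (dart-throwing) with 1.5-μm minimum
  spacing, so mutual-nearest-neighbor pairing is exact in the noiseless
  limit (see above).
- **Anaphase**: from `anaphase_at_s`, sister separation ramps linearly
  (doubling after 15 s, capped at 4 μm) and oscillation phases freeze.
- **Division sizes**: the cell axis is cut at the plate/axis intersection
  of the anaphase (or last) frame; the two segment lengths are the
  daughter "sizes". This is a 1-D caricature of furrow placement over the
  plate — sufficient to couple plate position to division asymmetry, not a
  volumetric model.
- **Determinism**: each cell's stream derives from `(seed, index)` via
  `SeedSequence`; identical configuration and index reproduce bit-identical
  output. Fixed snapshots use an offset stream so live and fixed draws are
  independent.

The noiseless generator is its own oracle: with noise, oscillation and
dispersion switched off, the full pipeline returns R(t), the inter-sister
rest length, δ, the rotation angle and the anaphase frame exactly (to
1e-9 or ±1 frame), because every construction step is the inverse of the
corresponding estimator's model. What the generator does **not** emulate —
point-spread blur and detection failure, kinetochore directional
instability (run–reversal dynamics), plate-spacing violations, z-anisotropy
in the noise, intensity bleaching — bounds what passing tests show: they
validate the estimators under the stated point-process model, not the
upstream detection pipeline on real images.

## Numerical choices and problem sizes

Tolerances: geometric identities are asserted at 1e-9; partition and
brightness ties raise at 1e-6/1e-9 rather than being broken arbitrarily;
the collinearity guard is 1e-12 of scale. Tie-breaks that are legitimate
(equidistant linking or pairing candidates) go to the lowest input index
and are documented in the functions.

The validation suite runs cohorts of 20–60 cells, 5–41 frames, 23 pairs —
sizes at which every sampling-error bound used in the assertions (e.g.
median R within ±0.02 of truth at n = 60, 0.05-μm noise) holds with a
comfortable margin, while the whole suite stays fast on one CPU. The
acceptance script uses the same sizes and derives all randomness from its
`--seed`.
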