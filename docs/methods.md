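# Methods

This note documents the models implemented in `dormabreak`, the design
decisions taken where the procedure was genuinely open, what the
synthetic-data generators emulate, and the known limitations.

## Chill-unit estimation

A chilling treatment is a (temperature, duration) pair applied to
replicate trays of buds; after transfer to warm conditions the
cumulative number of sprouted buds is recorded daily (day 1 = first
warm day, 70 days by default). Percentages are exact ratios
100·sprouted/n_buds; replicate curves are averaged only when forming a
response curve, never upstream.

**Rising-phase slope.** The slope of a response curve is the
ordinary-least-squares slope of sprouting percentage against warming
day, restricted to the window from the first day with a positive value
to the first day reaching the curve's maximum. This window rule is the
simplest estimator consistent with sigmoid time courses whose steepness
falls with less-effective chilling. A curve that never leaves zero has
slope 0 and is flagged `no_emergence` (temperatures at or above the
effectiveness limit behave this way); a single-day jump falls back to a
two-point slope anchored on the preceding day. Whether slopes should be
taken on replicate means or per replicate and then averaged is
unresolved in general; replicate-mean curves are used because they are
less sensitive to empty trays at weak treatments.

**Chill units.** The mean slope at a temperature is the unweighted mean
over all chilling durations applied there (durations with no emergence
contribute 0). The chill unit is the ratio to the mean slope at the
0 °C reference, so the reference row is exactly 1 and the table is
invariant to any uniform rescaling of slopes.

**Quadratic model.** CU(T) is fitted by unweighted OLS on the
(temperature, chill-unit) pairs — nothing in the data suggests a
weighting scheme — and must be concave (a ≥ 0 raises a "no interior
optimum" error: the model class presumes a biological optimum).
Derived constants: optimum temperature −b/(2a), maximum chill unit
c − b²/(4a), upper limit = larger real root. Evaluation clamps to 0
below 0 °C (outside the modelled domain; a warning is emitted, because
sub-zero treatments damage buds rather than chill them), above the
upper limit, and wherever the polynomial is negative.

**Accumulation.** Chill is accrued hourly: Ca = Σ CU(T)·hours over
schedule segments, so constant-temperature days contribute 24·CU. The
hourly basis makes accumulation exactly additive and invariant to
segment subdivision (property-tested). `ramp_schedule(start, end, step,
hold_days)` builds one 24-h segment per ramp day at start, start+step,
…, end inclusive, then a hold — so a 0→10 °C ramp at 1 °C/day is 11
ramp days. The alternative reading, in which each increment is held
within a longer program, can be built directly from segments.

## Stage (accumulation → sprouting) models

At a fixed warming day, every treatment with a positive chill unit
contributes one (Ca, sprouting %) point; zero-CU temperatures are
excluded because they deliver no accumulation at any duration. The
default functional form is a quadratic fitted by OLS — the minimal form
that supports a reported interior optimum of chilling requirement — and
the `form` field is kept extensible. Predictions are clamped to
[0, 100]. `required_ca` returns the **lower** crossing of the target
percentage: the smallest sufficient chilling is the agronomically
meaningful inverse. `verify_predictions` regresses observed on
predicted (so a perfect model gives the line Y = X), and reports the
squared Pearson correlation, slope, intercept and mean signed bias.

## Synthetic sprouting experiments

The generator draws experiments from a known quadratic chill-unit truth
at the study design scale: 9 temperatures spanning the effective
0–10 °C range, durations of 5–81 days, 3 replicate trays of 20 buds, 70
observation days. Each bud sprouts independently with probability
plateau(Ca)/100 (binomial tray noise — no replicate-level variance
information was available, so binomial-only noise is the recorded
assumption) on day ceil(delay(Ca) + U), U uniform on ±6 days.

Two structural choices make the planted truth *identifiable* by the
estimators above, and both are deliberate:

- **plateau(Ca) = min(100, 0.08·Ca)**, declining at 0.01 %/Ca beyond a
  supra-optimal accumulation of 1900 Ca. The rising-phase slope of a
  sprouting curve is proportional to its plateau, so a plateau linear
  in Ca below saturation keeps mean slopes proportional to chill units;
  a strongly curved plateau would compress slope ratios and make the
  planted optimum unrecoverable by *any* slope-ratio estimator. The
  0.08 rate reaches full sprouting at ≈1250 Ca, matching time courses
  where seven-week treatments near the optimum temperature saturate;
  the mild supra-optimal decline encodes the "excess chilling hurts"
  effect ("slightly decreased" at the longest durations).
- **bounded uniform emergence window** (half-width 6 days) rather than
  a heavy-tailed law: the replicate-mean curve is then a linear ramp
  whose observed rising window does not widen with the number of
  sprouting buds. With an unbounded distribution the window grows like
  the log of the sprout count, which systematically inflates the
  slopes of weak treatments and biases the chill-unit ratios.

Delay falls from ≈64 to 14 warming days as Ca grows
(delay = 14 + 50·e^(−Ca/500)), reproducing the later first emergence
after weaker chilling; weak treatments may run past day 70 and are then
right-truncated, as in real observation windows.

What the generator does **not** emulate: replicate-level overdispersion
beyond binomial, bud-to-bud frailty correlation within a tray,
temperature-by-duration interactions other than through Ca, and
alternating-temperature effects (which in real verification data make
observed sprouting slightly exceed constant-temperature predictions).
Passing recovery tests therefore demonstrates estimator correctness
under the stated noise model, not robustness to every field condition.

## Synthetic expression matrices

The expression generator emulates the shape of a dormancy-series DEG
matrix: 9 samples (3 dormancy states × 3 replicates), ~10³ genes in
block-correlated modules, FPKM values spanning decades, and a
per-sample sprouting-percentage trait (defaults 2–96 %). Each module m
has a latent per-sample profile with **exact** sample Pearson
correlation r_m to the trait; member genes are
baseline + loading·latent + N(0, 0.25) on the log scale, exponentiated
to FPKM. Latent residuals are constructed mutually orthogonal (while
sample dimensions remain), so the correlation between two planted
latents is exactly r_m·r_m′: with 9 samples, independently drawn
residuals would let two trait-linked modules drift into
near-collinearity by chance, making them unrecoverable by construction
rather than by algorithmic failure. Engineered hub genes are noise-free
copies of their module latent with maximal loading and a high fixed
baseline (hub genes are strongly expressed; a low baseline would push
samples toward zero FPKM where the log transform is nonlinear and wash
out the planted correlations).

## Coexpression analysis

- **Transform:** correlations are computed on log1p(FPKM) by default
  (config switch `raw` provided). FPKM spans decades and raw-scale
  Pearson correlation is dominated by outliers.
- **Network type:** unsigned, a_ij = |cor|^β with zero diagonal. TOM is
  the standard unsigned construction
  TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1.
- **Soft threshold:** per power, the scale-free fit is the R² of
  log10(frequency) on log10(mean connectivity) over 10 equal-width
  connectivity bins (empty bins dropped), requiring a negative slope;
  the chosen β is the smallest power reaching R² ≥ 0.85, else the
  argmax. For 9-sample DEG matrices powers in the mid-20s are typical
  (background correlations are large at this sample count and need a
  high power to be crushed); β = 26 is used in the study-scale tests.
- **Module detection:** average-linkage hierarchical clustering on
  1 − TOM with a **static** cut. A static cut was chosen over dynamic
  tree cutting deliberately: it is fully specified, order-independent
  (genes are sorted lexicographically before clustering) and testable,
  at the documented cost of not reproducing partitions that depend on a
  particular dynamic-cut implementation. The default cut height 0.8 was
  calibrated on the planted-module benchmarks at the 9-sample,
  β = 26 operating point; at other sample counts or powers the TOM
  scale shifts and the height should be re-examined. Clusters below 30
  genes (the default minimum module size, comfortably below the
  smallest module of interest in typical DEG studies) are labelled
  `unassigned`; surviving modules are named largest-first from the
  conventional colour order (turquoise, blue, brown, …).
- **Eigengenes:** first principal component of the per-gene
  standardized log expression, unit norm, sign-oriented so the mean
  correlation with member genes is non-negative.
- **Statistics:** GS and MM are Pearson correlations (signed and
  absolute both stored); p-values use the correlation t-test
  t = r·√(n−2)/√(1−r²) (7 degrees of freedom at 9 samples). Zero
  variance genes are excluded from all correlation work with a warning.
- **Significance:** modules with |eigengene–trait correlation|
  strictly greater than 0.9 (the threshold is a parameter).

## Hub screen

Within each significant module, edges are pairs with weight strictly
above the module's threshold (strict, matching how such cutoffs are
conventionally quoted); edge weights default to TOM, which is also what
gets exported for visualization, with a config switch for raw
adjacency. Degree is the count of retained incident edges. A
one-dimensional k-means (k = 3 by default — high/medium/low degree —
with 10 seeded restarts) splits the degrees, and the cluster with the
highest mean is the "first cluster". Real hubs are first-cluster genes
with |GS| ≥ 0.95 and |MM| ≥ 0.98 (inclusive). Both filters are applied
in every module, and the report records pass/fail per criterion so
either a combined or a per-criterion reading can be recovered. The hub
set is monotone non-increasing in each threshold (property-tested).
In the planted benchmarks, per-module edge thresholds are set at the
99th percentile of the module's TOM values, mirroring the hand-picked
per-module cutoffs used in practice.

## Numerical conventions

- Cumulative-count violations in input files raise errors naming the
  offending treatment; nothing is silently repaired.
- Model JSON stores coefficients plus derived constants; on read the
  derived constants are recomputed and a mismatch beyond 1e−6 relative
  is an integrity error.
- `required_ca` uses the closed-form quadratic roots with a 1e−9
  tolerance at tangency (target equal to the model maximum).
- All randomness flows through a single `numpy` generator per
  simulation config; equal seeds give byte-identical CSV output.

## Problem sizes in the test suite

Recovery tests run at the study design scale: 20 seeds for chill-unit
recovery (9 × 12 × 3 × 20 design), 10 seeds for stage-model
verification on held-out treatments, 20 seeds of 1000-gene / 9-sample
networks for module and trait-module recovery, and 10 of those for the
hub screen. Oracle-equivalence checks (TOM triple loop, 1-D k-means
versus the exhaustive contiguous-partition optimum, GS/MM against
direct correlation) are exact to 1e−9. The whole suite runs in well
under a minute on one CPU.

## Limitations

- The quadratic CU and stage forms are the smallest models with an
  interior optimum; they extrapolate poorly far beyond the fitted Ca
  range, and reported optima beyond the largest delivered accumulation
  are extrapolations of the fitted curve.
- The static tree cut will not reproduce module partitions produced by
  dynamic tree-cutting implementations; module counts are not
  comparable across the two approaches.
- With 9 samples, correlation estimates are heavy-tailed; the 0.9
  module–trait threshold is then a strong filter and GS/MM thresholds
  near 1 operate close to estimation noise. The planted-truth tests
  quantify exactly this regime.
- The chill-unit estimator assumes the rising-phase slope carries the
  chilling signal multiplicatively; response shapes whose slope
  saturates in Ca violate this and bias the fitted optimum (see the
  generator discussion above).
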