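# Methods

This note documents the models, estimators, parameter defaults and numerical
choices behind `tonocore`, and what the synthetic phantom does and does not
emulate.

## 1. The phantom: what it emulates

The generator reproduces the logic of a sparse-sampling pure-tone tonotopy
protocol:

- **Stimuli.** `n` tone conditions, log-spaced between `f_min` and `f_max`
  (defaults 200–8000 Hz, n = 8, which gives the ladder 200, 338.8, 573.8,
  971.9, 1646.2, 2788.4, 4723.1, 8000 Hz).  The effective frequency of each
  trial jitters uniformly within a total width of 1 semitone around the
  nominal value (an adaptation-reducing device; we read "a uniform
  distribution of 1 semitone around the nominal frequency" as total width,
  i.e. ±0.5 semitone).
- **Design.** Stimulation epochs of `epoch_len` trials of one condition
  followed by `epoch_len` silent baseline trials; `n_dummy` dummy trials open
  the session; the session splits evenly into runs.  The default human-scale
  design (8 × 20 repetitions, 2-trial epochs, 4 dummies, 2 runs) totals 324
  trials.  Epoch order is pseudorandom with approximately balanced
  first-order transition probabilities, implemented as a randomised Eulerian
  path on a condition-transition multigraph whose cell multiplicities differ
  by at most one (built per run; this requires repetitions divisible by
  `epoch_len × n_runs`).  Within a run the realised transition-count matrix
  deviates from uniform by at most one count per cell.
- **Response model.** Sparse sampling (TR ≈ 9 s, acquisition after the
  stimulus, silence before the next trial) justifies treating each volume as
  one independent sample: no haemodynamic convolution, autocorrelation or
  scanner-noise burst is modelled.  A tuned voxel's response to a tone at
  frequency `f` is `baseline + A · exp(−(log2 f − log2 bf)² / 2σ²)` with
  `σ = FWHM_oct / (2√(2 ln 2))`.  The Gaussian-in-log-frequency shape is a
  modelling choice of this package (no generative model is prescribed by the
  protocol); defaults: amplitude A = 2 signal units on baseline 100 (i.e. a
  2% peak signal change), tuning FWHM = 1.5 octaves, both optionally
  per-voxel arrays.  Additive i.i.d. Gaussian noise (default sd 1 unit = 1%
  of baseline, a realistic per-trial contrast-to-noise of ~2 at the peak)
  completes the model.
- **Geometry.** The tonotopic sheet occupies one z-slab of the 3-D volume
  (slices parallel to the lateral sulcus in the real protocol); voxels are
  1.5 × 1.5 × 2.5 mm.  The default layout plants two rectangular fields with
  mirror-symmetric gradients sharing a **low-frequency border** (A1/R
  configuration); a third caudal field adds a **high-frequency border**
  behind A1.  The low-frequency crease is always placed *between* two cell
  columns: a crease lying exactly on a column has zero directional difference
  there and would be invisible to any discrete reversal detector.

**What passing tests on the phantom do *not* show:** robustness to motion,
physiological noise, haemodynamic nonlinearity, vascular weighting,
surface-flattening distortion, or anatomical variability.  The phantom
validates the *algorithms* (estimator identities, calibration under permuted
labels, planted-truth recovery), not field performance on real data.

## 2. Tuning curves and activation

With one sample per trial, the GLM with an indicator regressor per condition
plus baseline intercept reduces exactly to condition means versus the
baseline mean; responses are percent signal change relative to the voxel's
baseline mean (undefined, and the voxel flagged, if that mean is ≤ 0).  The
tuning path optionally smooths each volume with a separable truncated
Gaussian (default FWHM 2 mm, the protocol's kernel); the classification path
never smooths.

The activation mask unions one-sided Welch t-tests (condition > baseline) per
condition at an uncorrected per-test `alpha`.  The protocol states no
threshold; we default to `alpha = 0.01` because the any-of-8 union at 0.05
would pass ≈ 34% of null voxels, which measurably pollutes the downstream
best-frequency sheet.

Split-run reliability correlates each voxel's run-1 and run-2 tuning curves
(Pearson over conditions) and compares the distribution against a scrambled
null — 10,000 (configurable) voxel pairs (v, v′ ≠ v) drawn uniformly with
replacement — by a two-sample Wilcoxon rank-sum test.  Constant tuning curves
have undefined correlation; they are excluded and counted.

## 3. Best frequency: centroid and roex

The centroid uses clipped, normalised responses `wᵢ = max(rᵢ,0)/Σ max(rⱼ,0)`
(equal to `rᵢ/(n·r̄)` for non-negative curves; clipping preserves the
convex-combination semantics, and all-non-positive voxels are flagged
invalid).  Spread is the weighted standard deviation about the centroid, and
FWHM = spread × 2√(2 ln 2) (the Gaussian sd→FWHM constant; the factor is
recorded in output metadata as `fwhm_factor`).  Both default to the **log2
frequency axis** — the stimuli are log-spaced and tonotopy is logarithmic —
with a linear-Hz option.  On a noise-free Gaussian tuning curve sampled
symmetrically about a stimulus frequency the log2-axis centroid is exact.

The roex fit `a(1 + pg)e^(−pg) + c` uses `g = |log2(f/f0)|` (log2 default;
classic linear `|f − f0|/f0` available), `f0` bounded to the stimulated
range.  Initialisation grids `f0` over the stimulus frequencies and
`p ∈ {1, 4, 16}` with per-start linear least squares for `(a, c)`; the best
start (ties to the smallest `p`, i.e. the widest filter) is refined by
bounded least squares.  The FWHM derives from the half-maximum crossing
`(1+x)e^(−x) = ½` at `x ≈ 1.6783` (computed by root finding at import, not
hard-coded): width `2x/p` in g-units — octaves on the log2 axis, `2x·f0/p` Hz
on the linear axis.

## 4. Searchlight classification

- **Preprocessing.** Per voxel and run: subtract a robust LOWESS trend over
  trial index (window fraction 0.5 of a run, 2 robustifying iterations),
  mean-correct, divide by the sd.  Voxels with vanishing residual variance
  are flagged and zeroed.
- **Neighbourhoods.** All voxels whose centre-to-centre distance from the
  centre voxel is ≤ radius (inclusive; default 4 mm).  At 1.5 × 1.5 × 2.5 mm
  voxels this is 47 voxels by brute-force enumeration; the "34-voxel"
  neighbourhood sometimes quoted for the same geometry is not reproducible
  under any obvious distance convention and the radius rule here stays
  configurable.
- **Classifier.** The multiclass problem is partitioned into all C(C−1)/2
  pairwise binary problems; each is solved by a linear max-margin classifier
  (hinge loss, L2 penalty, C-parameterisation, bias learnt as a regularised
  weight) implemented as dual coordinate descent with deterministic cyclic
  sweeps — the searchlight fits ~10⁶ tiny problems, a regime where generic
  estimator APIs are overhead-bound; the implementation is cross-checked
  against a reference library SVM in the tests.  A k-NN alternative (default
  k = 1) serves the low-trial regime.  Test-trial predictions are combined by
  majority vote; ties break by the summed signed margins, then by the lowest
  class index.
- **Cross-validation.** 5 folds, stratified by class with contiguous-in-time
  blocks per class (limits leakage between temporally adjacent trials);
  accuracy is the average over held-out parts.  Chance is 1/C (12.5% at 8
  conditions; 50% after the low/high binary collapse, which splits conditions
  at the geometric midpoint of the frequency range by default).
- **Inference.** Accuracies map to z-scores via the binomial approximation
  `z = (k − Np₀)/√(Np₀(1−p₀))`; the voxel threshold defaults to one-sided
  P = 0.01 (z* ≈ 2.326).  Cluster correction replaces random-field theory
  with a Monte-Carlo null: max face-connected supra-threshold cluster sizes
  over simulated standard-normal lattices (optionally smoothed and
  re-standardised), retaining clusters *larger than* the (1−α) quantile
  (α = 0.05).  The discrete size distribution makes the achieved α at most
  the nominal one; the achieved value is reported in the mask metadata.
  Overlap between masks is the Dice coefficient (in %), mask distance is the
  distance between centres of mass in mm.

## 5. Gradient reversals

- **Sign maps.** The directional difference at a cell is the central finite
  difference of bilinear samples one cell ahead/behind along orientation θ;
  sign 0 where |difference| < 10⁻⁹ of the map's dynamic range; cells whose
  samples touch invalid territory are undefined.
- **Edges.** A reversal is a strict +1/−1 opposition between 4-adjacent cells
  (both lattice axes — opposition along only θ's dominant axis would miss a
  vertical border for all near-vertical orientations); zero-sign cells never
  anchor an edge.  Each dual-lattice edge marks *both* flanking cells: the
  two cells are equidistant from the edge, and the symmetric rule is what
  makes the composite value equal the inter-gradient angle (each flank
  carries half of the opposite-sign orientation arc when the crease sits on a
  lattice column).
- **Composite map.** Summing the binary edge maps over θ = 0…179° in 1°
  steps yields, at a reversal, the number of orientations flagging it — up to
  discretisation (±2°), the angle between the adjoining gradient vectors
  (179 at a perfect mirror reversal, where the exactly-perpendicular
  orientation has zero derivative).
- **Borders.** Inside the core mask dilated by one cell, cells with
  composite ≥ `stability_min` (default 60°: a border must reflect a
  substantial inter-gradient angle) form 8-connected components, ranked by
  mean composite value ("stability").  A component is classified **low** if
  the median best frequency along it falls below the midpoint of the stimulus
  log2-frequency range, else **high** (A1/R borders are low-frequency
  reversals; A1/caudal-belt borders are high-frequency ones).  In the
  pipeline the best-frequency sheet is additionally restricted to
  activation-significant voxels, optionally smoothed with a nan-aware
  Gaussian (σ = 1 cell), and components smaller than 8 cells are discarded
  as speckle — without these, noise-only voxels at the rim of the core mask
  generate spurious reversal fragments.
- **Representative border angle.** 90° minus the orientation whose edge map
  correlates maximally (Pearson on the binary lattices, over the border
  neighbourhood) with the composite map, folded to [0, 90] relative to the
  reference axis.  On idealised straight reversals many orientations flag
  identical cells; the maximiser is then a tied set, and the representative
  orientation is the tied set's axial (doubled-angle) circular mean — unlike
  a lowest-index rule this keeps the angle equivariant under rotations of
  the map.
- **Direction statistics.** Per-cell gradients by central differences;
  directions are axial (defined mod 180°), so the mean and bootstrap 95% CI
  (2000 resamples) use doubled-angle circular statistics computed *before*
  folding to [0, 90] (folding first would turn {10°, 170°} into {10°, 10°}
  instead of averaging to 0°).  Histograms bin every 45°.  The
  uniform-null test for "proportion of directions below 45°" draws B
  bootstrap samples of n uniform angles on the measured range and reports
  the tail probability; its exact counterpart is the binomial tail, used as
  the oracle in tests.

## 6. Pipeline, determinism, problem sizes

Every stage persists its outputs (NIfTI lattices, TSV tables, JSON reports),
so stages can be rerun individually or fed user-supplied inputs (e.g. a
pre-existing core mask with classification disabled).  All randomness flows
from one master seed through named child seeds
(`schedule/simulate/reliability/cluster/borders`); identical configurations
reproduce result tables byte-identically.

Default problem sizes were chosen so that a full phantom run (40 × 40 sheet,
8 conditions, 20 repetitions) completes in a few minutes on one CPU, and the
test suite and the calibration script use 20 × 20 sheets with 1–3 z-slabs;
the calibration numbers (chance level under permutation, bootstrap tails)
are sample-size-aware and carry Monte-Carlo standard errors, so they do not
depend on these sizes beyond their quoted precision.

## 7. Known limitations

- The analysis sheet is a lattice; surface extraction, inflation and
  flattening of real cortex are upstream concerns, and lattice operators
  (bilinear sampling, 4/8-connectivity) are only exactly rotation-equivariant
  for quarter turns.
- Searchlight spheres straddling a mirror crease contain duplicated best
  frequencies, which can make one condition pair genuinely non-separable on
  noise-free phantoms — a property of the geometry, not the classifier.
- The binomial z-transform treats cross-validated test trials as
  independent; correlated folds make it mildly optimistic, which the cluster
  correction does not repair (it calibrates cluster extent, not voxel
  height).
- The cluster-size null simulates stationary Gaussian fields; real
  accuracy-map smoothness is neither estimated nor matched (random-field
  theory is deliberately not used).
- The roex fit can stick to a range boundary on monotone tuning curves (by
  design: the peak is constrained to the stimulated range) and is slower and
  noisier than the centroid — the package follows the centroid as the
  primary best-frequency estimate for gradient analysis.
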