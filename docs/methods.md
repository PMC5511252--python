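# Methods

## The model chain

`damacy` treats a multi-sample flow-cytometry study as a four-level
hierarchy — markers on cells, cells in populations, populations in
individuals, individuals in clinical groups — and couples the levels
with an explicit chain of fitted statistics. Everything below is
fitted on training individuals and applied unchanged to held-out
samples; the only exception is deliberately the per-individual
centring/scaling modes, which by definition recompute a sample's own
statistic.

### Preprocessing (multiset centring and scaling)

Fluorescence intensities are approximately log-normal, so the raw
matrix is log10-transformed first. Where the data contain values below
1 (background-subtracted channels can go negative), all values are
shifted by `1 − min` before the log, so the global minimum maps to
log10(1) = 0. This pins down the otherwise undefined log of
non-positive values with a monotone map and reduces to a plain log10
for data that are already ≥ 1. The fitted shift is stored; held-out
values that still fall below the shifted origin are clipped to the
smallest positive float before the log.

The centre is the unweighted mean over individuals of the
per-individual column means — *not* the grand mean over cells. The
per-marker scale is `sqrt(mean over individuals of the per-individual
column variance)`. Both choices make every sample count equally
regardless of how many cells were acquired; with the population
(divide-by-N) variance convention, exact r-fold replication of any
sample's cells provably changes neither statistic, and the test suite
asserts this. Variants: `per_individual` (each sample self-centres,
removing between-individual offsets entirely), `per_group` (one centre
per clinical group; unusable for samples of unknown group, and the
code refuses them), and `median_overall` (per-individual medians, then
the median across individuals — useful when the dominant cell type
should sit at the origin; scaling still uses the mean-variance rule,
since a median-based scale is a separate question and the mean-variance
rule keeps the replication invariant). Mode choice is configuration,
evaluated explicitly with `validation.evaluate_preprocess_modes`; no
mode is ever selected silently.

### Base model (cell-count-normalized PCA)

A single PCA describes marker co-expression across *all* cells. To
keep samples with many cells from dominating the loadings, each
individual's block of the preprocessed matrix is divided by its own
cell count before the decomposition; the loadings are the leading
right singular vectors of that normalized stack (deterministic SVD, no
iterative fitting; data are already centred, so the decomposition is
about the origin). Note the block weight in the implied Gram matrix is
`1/N_i` per block, i.e. big samples are damped more than
proportionally — this is the method's stated normalization, and its
observable contract (identical cell clouds give identical loadings
regardless of N) is what the tests pin. Component signs are fixed by
making each component's largest-magnitude loading positive, so
repeated runs are bit-identical.

Per-individual explained variance of component k is the variance of
that individual's scores on k divided by the trace of the individual's
own centred covariance — the one definition under which the fractions
of an individual sum to exactly 1 over a full basis. Individuals with
a single cell have zero variance and report zero fractions rather than
an error.

### Histograms

Sample score clouds are compared through normalized histograms on one
shared grid. Per component the bin width is `(P99.95 − P0.05)/F` of the
pooled training scores (linear-interpolation percentiles, pinned for
reproducible grids), anchored at P0.05: the 0.1% most extreme scores do
not stretch the grid. Bins are half-open with the upper edge of the
last bin closed; cells outside the grid — the trimmed 0.1% and any
held-out cells beyond the training range — are clipped into the
boundary bins, so every cell contributes and every histogram sums to
exactly 1 after division by the sample's cell count. Discarding
outliers instead would silently break the unit-mass semantics for
held-out samples.

Smoothing is a separable Gaussian pass per axis (mathematically equal
to the full K-dimensional Gaussian convolution, which the tests verify
against a nested-loop oracle), σ = `smoothing_factor` in bin units,
kernel truncated at ±4σ, reflective boundaries, with the result
renormalized to sum 1 since boundary handling can leak a little mass.
Because renormalization is mandatory, smoothing before or after the
count normalization gives identical histograms. σ = 0 is the exact
identity.

### Top model (OPLS-DA) and the leukocyte map

Histograms are flattened row-major (first component = slowest axis)
into the design matrix `C`; bins whose across-sample variance on the
training samples falls below the threshold are dropped and the
surviving-column mask is stored. Classes are coded control = −1,
challenged = +1 and centred, `C` is column-centred (centring vector
stored), and the model is orthogonal-signal correction followed by one
predictive PLS component: repeatedly, the current weight `w ∝ Cᵀy` is
computed, the part of the dominant loading orthogonal to `w` is
extracted as an orthogonal weight, and its component is deflated; after
`n_ortho` deflations the predictive weight is recomputed and normalized
to unit length. With `n_ortho = 0` this is exactly single-component
PLS1-DA, which the tests verify against an independent NIPALS
implementation. A two-class problem has exactly one predictive
direction, so only `n_ortho` is tunable; it is selected by inner
cross-validation from {0, 1, 2} by default. A useful identity: because
orthogonal scores are uncorrelated with `y`, deflation leaves `Cᵀy`
unchanged — the leukocyte map is therefore invariant to `n_ortho`,
which only reshapes the score distribution.

Prediction applies the stored mask, centring and OSC filter and
projects on `w_top`; the score is an affine function of the smoothed
histogram, so each cell shifts its sample's score by the weight of the
bin it lands in. Scores above 0 classify as challenged; a score of
exactly 0 is counted as a misclassification (conservative,
deterministic). For a 2-component base model the masked weights are
scattered back onto the F × F grid (zeros at masked bins) to form the
leukocyte map; the base-model loading vectors are overlaid so each
red/blue region can be read as a marker-expression profile.

### Validation

Double cross-validation with leave-sample-out folds: stratified outer
folds partition individuals, never cells; the inner loop refits the
*entire* pipeline (preprocessing through top model) on inner-training
individuals to choose `n_ortho`; iterations reshuffle fold membership
under per-iteration seeds spawned from the master seed, all logged.
The no-leakage contract — every fitted statistic derives from training
individuals only — is enforced structurally (each fold fits on a
physically subset dataset) and asserted bitwise in the tests.

## Defaults and units

| parameter | default | meaning |
|---|---|---|
| `center_mode` / `scale_mode` | `overall` / `pooled` | multiset mean centring, mean-variance scaling |
| `k_base` | 2 | base-model components (≤ J); histogram uses the first two unless `pc_pair` says otherwise |
| `bins_f` | 500 | bins per component |
| `smoothing_factor` | 5.0 | Gaussian σ, in bins |
| `variance_threshold` | 1e-6 | minimum across-sample bin variance |
| `n_ortho` | 1 (CV grid {0,1,2}) | orthogonal components |
| `outer_folds` / `n_iterations` | 6 / 20 | cross-validation recipe |

`bins_f`, `smoothing_factor` and `variance_threshold` are coupled to
the per-sample cell count. The defaults suit clinical samples of the
order of 10⁵ cells, where occupied smoothed bins hold fractions around
10⁻³ and cross-sample variances clear 1e-6 comfortably. With
~10³-cell samples the same resolution spreads each sample over so many
bins that *every* variance falls below 1e-6 and the design matrix
would be empty: occupancy per occupied bin scales like 1/(occupied
bins), so the meaningful variance scale drops with its square.
`PipelineConfig.for_small_cohorts()` therefore uses F = 100 and a
threshold of 1e-10 (σ stays 5) for the simulated cohorts used in the
tests and the acceptance script; this is a resolution choice for small
samples, not a change of method.

## The synthetic cohorts

`synthetic.simulate_cohort` draws, per individual, a cell count from a
range (so samples are unbalanced), per-cell population assignments from
the group's mixing fractions, and cells from Gaussian populations on
the log10 scale — optionally with a linear *continuum* drift emulating
gradient-shaped responses — plus per-individual jitter of population
means (biological variability, default sd 0.08 log units) and
measurement noise (default sd 0.03). Values are exponentiated so the
pipeline's log transform recovers the generative scale. Presets:
`lps_like` (8+8 individuals, 1500–2500 cells, J = 6; a compact gradient
population at 5% in controls vs 30% in challenged), `null` (20+20,
800–1200 cells, identical mixtures), `aml_like` (8+8; one population
shifted 0.6 log units along one marker in the challenged group). The
effect sizes are fixture parameters of this package, not estimates
from any clinical cohort.

What the simulator does *not* emulate: spillover/compensation
structure, doublets and debris, acquisition-time drift, heavy-tailed
or zero-inflated channels, and correlated (non-diagonal-jitter)
between-individual variation. Passing tests therefore demonstrate the
statistical machinery — equal weighting, leakage-free validation,
effect localization — under the model's own assumptions, not
robustness to every artefact of real cytometry data.

A note on map-recovery behaviour worth knowing when reading results:
because histograms are compositional (rows sum to 1), planting an
extra population in one group necessarily depletes the baseline
population's fraction, and the fitted map shows *both* — strong
positive weights on the planted region and compensating negative
weights on the baseline. On the simulated cohorts the positive
top-decile weights land inside the planted region essentially without
exception, while the overall top-decile fraction inside the region
hovers near 0.7 depending on how the negative bins rank. Both numbers
are reported by `validation.planted_region_recovery` and by the
acceptance script.

## Problem sizes and determinism

The test battery and `scripts/acceptance.py` run the simulated cohorts
described above (16 samples × ~2000 cells and 40 samples × ~1000
cells, F = 100); a full double-CV on each takes well under a minute on
one core. All randomness flows from explicit seeds: cohort draws from
the cohort seed, fold shuffles from per-iteration seeds spawned from
the CV seed, and refitting with the same configuration and data is
bit-identical.

## Known limitations

- Two groups only in the top model (one predictive direction); no
  multi-class extension.
- No compensation/spillover handling or logicle/arcsinh transforms:
  files are taken as acquired, pre-gating is upstream.
- The leukocyte map is defined for 2-component score grids; higher-K
  top models work end-to-end but expose weights only in vector form.
- The variance filter uses a fixed absolute threshold; it must be
  rescaled (see above) when sample sizes differ by orders of magnitude
  from the ~10⁵-cell regime the default targets.
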