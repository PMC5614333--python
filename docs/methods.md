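# Methods

## The channel model

A population of isogenic worms held at food level *f* yields one response
vector **g** per worm (one background-subtracted fluorescence value per
reporter/neuron). Treating worms as independent draws from p(**g**|f), the
food→expression map is a discrete memoryless channel once responses are
binned, and every quantity the package reports is a functional of the F×M
conditional probability matrix. The key assumptions are (i) worms within a
condition are exchangeable — batch effects must be small relative to
within-condition spread, or balanced across conditions; (ii) the discrete
set of food levels is the full input alphabet; (iii) binning at the chosen
grid resolution retains the biologically meaningful differences between
conditions.

## Density estimation

Per (genotype, condition), a Gaussian kernel density estimate of the
response vectors is evaluated at the centers of a hypercubic grid — GS bins
per dimension spanning the per-readout minimum-to-maximum range pooled over
*all* records entering a comparison, so that every density in a comparison
lives on the same grid — and renormalized to sum to one. Bin intervals are
half-open with the last bin closed; linear indices are row-major in readout
order.

Bandwidth: the default `normal_scale` rule uses the full sample covariance
scaled by the multivariate normal-reference factor
(4/(d+2))^{2/(d+4)} n^{−2/(d+4)}; `scott` (diagonal factor n^{−1/(d+4)})
is available as an alternative. Both are normal-reference selectors; for the
mildly skewed log-normal expression data they oversmooth slightly, which
biases information estimates down (see "Known limitations"). Evaluation at
bin centers (rather than integrating the kernel over each bin) is
deliberate: the difference is second order in bin width and vanishes under
the GS-convergence check. A degenerate sample (n = 1, or singular
covariance) falls back to an isotropic kernel of one bin width per
dimension so that normalization-style tests remain meaningful.

Expression values are used on the linear scale by default. Zero-probability
bins stay exactly zero; all information routines use the 0·log 0 = 0
convention rather than flooring probabilities.

Grid resolution: estimates should be compared across GS ∈ {20, 30, 40}; when
refining GS stops changing the information estimate, the smaller GS is
preferred for cost. The acceptance runs use GS = 20 for the 3-readout
design (8000 bins) — at 3000 worms this is already past the point where the
capacity estimate moves by more than a few hundredths of a bit.

## Capacity and the decomposition

Blahut-Arimoto alternating optimization, started from the uniform input,
with the standard per-iteration bounds: the mutual information at the
current input is a non-decreasing lower bound on C and max_f KL(p(g|f)‖p(g))
an upper bound; iteration stops when they agree to `tol` (default 10⁻⁸
bits, max 10⁵ iterations; non-convergence is flagged on the result, not
raised). The returned capacity is the final lower bound, so it is within
`gap` of the true maximum.

Marginal informations I_N, the shuffle information I_sh and the derived
redundancy/signal/noise terms are all evaluated at the *joint* channel's
optimal input p\* — not at each marginal's own capacity-achieving input —
so that all terms describe the same operating point. The shuffle surrogate
replaces each conditional joint by the product of its own marginals, which
preserves every marginal response distribution and removes only
within-condition correlation. Sign convention: noise correlation
= I_joint − I_sh (positive when trial-to-trial co-variation helps), signal
correlation = I_sh − ΣI_N; both live in one function each, so the
convention can be flipped without touching callers.

## Uncertainty and bias correction

Finite-sample KDE densities contain spurious condition differences, so
information estimates are biased upward in n; smoothing biases them
downward. Two procedures quantify and correct this:

- **Five-fold spread**: records are partitioned into 5 disjoint folds,
  stratified within each (genotype, condition) cell (sizes within a cell
  differ by ≤ 1); the statistic is recomputed on each 80% complement and
  the standard deviation across the five values is reported.
- **Jack-knife extrapolation**: the statistic is recomputed at data
  fractions {0.5, 0.625, 0.75, 0.875, 1.0} (values chosen to put five
  evenly spaced points on the 1/n axis without dropping below half the
  data); at each fraction below 1 the subsample is redrawn R = 10 times
  (seeded, stratified per condition) and averaged to tame subsampling
  noise. A least-squares line of estimate versus 1/n_effective
  (n_effective = fraction × n) is fit and its intercept — the 1/n → 0
  limit — is the corrected estimate; the slope is reported as a bias
  diagnostic. The fit is first order in 1/n only: with five points,
  higher-order terms are over-fitting.

## Image quantification

The reporter signal of one cell is the sum of the K brightest voxels in a
closed, boundary-clipped box around the cell center, minus K times the
background level, estimated as the mode of the box's voxel-intensity
histogram. Histogram bin width is max(1 count, Freedman-Diaconis width);
bins are aligned so the box minimum sits at a bin center, and ties go to
the lowest bin (the background is the dim majority). This makes a flat
stack quantify to exactly zero and makes the net intensity invariant under
adding a constant to every voxel, up to one bin width × K. K is a
required parameter: it must be chosen once per experiment, large enough
that the brightest-K set fully encapsulates the cell in every image (for a
Gaussian-like spot of width σ voxels, K ≈ the voxel count within radius
3.5σ).

## The synthetic generator

`CodingConfig` draws worm populations from per-state multivariate normal or
log-normal response distributions. The default emulates the broad-range DR
design: six food levels named by their bacterial concentrations, three
readouts with log-normal noise (log-SD 0.30–0.35, i.e. 30–40% CV, typical
of single-copy transcriptional reporters), inter-neuron correlation 0.25
from shared worm-level factors, 500 worms per level, and log-mean profiles
in which ASI peaks at intermediate food (non-monotonic), ADF decreases from
ad libitum to starvation and NSM responds weakly. Constructed variants
isolate coding strategies: `redundant_config` (two readouts tracking one
gradient), `synergistic_config` (states coded purely in the sign of the
inter-readout correlation), `uninformative_config` (identical states; true
information zero).

`oracle_mi` computes the true I(**g**;f) of a config by seeded Monte-Carlo
integration of the exact densities, in log-space for the log-normal family
(the Jacobian cancels between conditional and mixture), with a reported
standard error. It is the ground truth against which the KDE pipeline is
validated.

What the generator does *not* emulate: batch/trial structure (all draws are
i.i.d. within condition), heavy-tailed outliers, censoring at the imaging
dynamic range, and missing readouts from failed cell identification.
Passing the recovery tests therefore demonstrates correctness of the
estimation machinery under the stated model, not robustness to those
real-data pathologies — the exclusion/merge plumbing handles them
structurally, but their statistical impact must be judged per dataset.

## Numerical choices and problem sizes

All logarithms are base 2. Channel rows and input distributions are
validated to sum to 1 within 10⁻⁶ and renormalized exactly; conditions with
an all-zero density row are rejected at channel construction. Seeds control
every stochastic step (simulation, fold assignment, subsampling,
Monte-Carlo); identical seeds give bit-identical results.

The bundled end-to-end validation uses the full default design (6 × 500
worms, GS 20, R 10, 50 000 oracle samples), which runs in well under a
minute; the quick examples and resampling demonstrations use 150–300 worms
per state and GS 10–15, sizes at which each density fit takes milliseconds
while the estimator behavior (positive bias, fold spread, sign recovery)
is already clearly expressed.

## Known limitations

- Normal-reference bandwidths on linear-scale log-normal data oversmooth
  the narrow low-food conditionals; with GS = 20 this costs the capacity
  estimate roughly 0.05–0.1 bits relative to the continuous-channel oracle
  on the default design. The jack-knife removes sample-size bias, not this
  smoothing/binning bias; comparisons across genotypes on the same grid are
  affected far less than absolute values.
- The capacity-achieving input p\* of an *estimated* channel is itself
  noisy and tends to concentrate on well-separated conditions; downstream
  quantities evaluated at p\* inherit that variability (quantified by the
  five-fold spread).
- Adaptive or plug-in bandwidth selection, continuous (k-NN) information
  estimators and higher-order jack-knife fits are out of scope.
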