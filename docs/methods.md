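# Methods

## The MDF statistic

Given a channels × samples recording, the analysis proceeds in four
stages.

1. **Latent embedding.**  Channels are z-scored and unmixed with
   fixed-point FastICA (log-cosh contrast, whitening to unit variance,
   tolerance 1e-4, at most 1000 iterations) into d = 2 (default) or 3
   independent components.  ICA is defined only up to sign, permutation
   and scale; every downstream quantity is invariant to these (asserted
   numerically in the test suite), so the particular ICA variant is not
   critical.  For reproducibility the returned components are ordered by
   the channel-space variance their mixing column explains and sign-fixed
   to non-negative skewness.  If the fixed-point iteration stalls, up to 3
   deterministic restarts are attempted; `on_fail="use_last"` additionally
   accepts the final non-converged estimate, which is still a valid
   whitened projection — appropriate for batch studies on short recordings
   where a metastable source that never switched wells is near-Gaussian
   and hence genuinely inseparable by the log-cosh contrast.

2. **Sliding-window density maps.**  The latent trajectory is cut into
   windows of length L sliding by s samples (trailing partial window
   dropped; W = floor((M − L)/s) + 1).  Each window becomes a d-dimensional
   histogram with 128 equal-width bins per dimension over the [min, max]
   range of each component across the *whole* recording (right-most edge
   inclusive), smoothed with a Gaussian kernel of sd 8 bins (truncated at
   4 sd, reflect boundary), and normalized to unit mass.  Smoothing is
   implemented as a banded smoothing matrix applied by matrix product over
   the whole window stack; a unit test verifies exact agreement (1e-15)
   with `scipy.ndimage.gaussian_filter`.  Smoothing precedes
   normalization; the order does not affect the correlations.

3. **The MDF matrix.**  Entry (i, j) is the Pearson correlation of the
   flattened (row-major, identical across windows) density maps of windows
   i and j.  The matrix is symmetric with unit diagonal by construction.
   A window whose smoothed map has zero variance (possible only for
   degenerate inputs) is an error naming the window.

4. **The complexity statistic.**  σ(MDF) is the population standard
   deviation (ddof = 0) of the strict upper triangle (the diagonal is
   excluded; the lower triangle is redundant).  Lower σ(MDF) means the
   manifold is explored more evenly across windows — more states, and
   smoother, more frequent transitions among them.  The convention
   (population vs sample, diagonal excluded) is configurable but fixed by
   default; the mean of the upper triangle is reported alongside because
   different dynamics can share a mean while differing in spread.

### Parameters that matter

| parameter | default | role |
| --- | --- | --- |
| `n_components` | 2 | latent dimensionality (3 supported; 128³ cells is memory-heavy, reduce `n_bins`) |
| `window_length`, `slide` | 800, 10 samples | simulation benchmark setting; empirical analyses use 1–30 s windows sliding by 100 ms at 100 Hz |
| `n_bins` | 128 | histogram resolution per dimension |
| `smooth_sd` | 8 bins | Gaussian smoothing of the occupancy histogram |
| `corr_dtype` | float64 | `float32` halves the cost of the W × W correlation for long recordings (relative error ~1e-5, far below replicate variability) |

Density bounds are computed per recording (per condition); windows in
seconds are converted by `round(length · fs)`.

## The bistable benchmark

Ground truth with a known state repertoire: N uncoupled units
`dx_i = (1 − x_i²) x_i dt + √(2σ) dW_i`, stable equilibria ±1, unstable 0;
the attractor count is 2^N sign patterns.  Integration is fixed-step
stochastic Heun (predictor–corrector, the same Wiener increment in both
stages, variance dt per step) at dt = 0.01; the full study horizon is
[0, 2000], i.e. 200,000 samples per variable.  In the deterministic limit
the integrator's global error against the closed form of `ẋ = x − x³` is
below 1e-4 at dt = 0.01 and scales as O(dt²).  Initial conditions default
to a uniform draw from {−1, +1}^N (inside an attractor, avoiding the
unstable origin); no burn-in is applied by default (`burn_in` available).
The noise grid {0.10, 0.20, 0.35} spans low/mid/high switching regimes
(Kramers rate ≈ 0.225 · exp(−0.25/σ) per unit time per variable).

## Scaled study dimensions

Replicate studies use a horizon of **t_end = 200** time units (2,000 time
units in the full-length setting): with slide-10 windows the full horizon
would produce ~19,900 windows and a ~13-teraflop correlation per
replicate.  The scaled horizon is chosen so that every variable crosses
the well barrier several times even at the lowest noise amplitude
(expected ≥ 4 transitions at σ = 0.10), keeping the system in the
stationary metastable regime.  This matters: at horizons where a variable
typically visits one well only, the system sits in the transient
"few distinct attractors" regime in which σ(MDF) *rises* with the state
count before the asymptotic decrease sets in, and the monotone ordering
genuinely reverses at low noise.

The 9-cell monotonicity study ({N = 2, 3, 4} × noise grid, 20 replicates
per cell) pairs replicates by **common random numbers**: replicate r uses
the same base seed in every cell, so the one-sided paired Wilcoxon
contrasts between adjacent cells compare like with like — the standard
variance-reduction design for paired simulation contrasts.

## Surrogate cohorts

A surrogate subject mixes N simulated bistable latents (dt = 1/fs, so one
simulator time unit is one second) into C channels through a random
matrix with orthonormal columns (full rank, comparable channel variances)
plus i.i.d. Gaussian observation noise (sd 0.2, ~0.2 of the latent
amplitude).  Conditions emulating rest/music/speech use N = 2/3/4 at a
common noise amplitude σ = 0.2; cohort studies use 200-s recordings at
100 Hz with 8 channels and 8-s windows sliding by 1 s.  With
`shared_drive=True` all subjects of a condition share the latent
trajectory (one drive seed) while mixing and observation noise remain
subject-specific — the construction that plants stimulus-locked shared
dynamics for the intersubject-correlation analysis.

What the surrogates do *not* emulate: 1/f spectral shape, volume
conduction, spatially structured noise, nonstationary artifacts.  Passing
tests therefore demonstrate that the pipeline recovers *planted*
low-dimensional metastable structure, not that it is robust to every
property of clinical recordings.

Two measured limitations of this surrogate family are documented rather
than hidden.  First, the channel-level switching rate (threshold-crossing
control) cannot be exactly equalized across conditions by tuning the
latent noise: over σ ∈ [0.16, 0.35] the mean rate is essentially flat in
σ but graded in N (≈ 1.56 / 1.36 / 1.26 crossings·s⁻¹ for N = 2/3/4 over
the 2–3 SD threshold grid), because channels mixing more latents carry
relatively less tail mass beyond the threshold.  The cohort tests
therefore assert descriptive comparability (adjacent-condition means
within 25%, gaps below the between-subject spread) rather than
statistical indistinguishability.  Second, the dFC comparator does not
merely fail to separate the conditions — on these surrogates its std
tends to move *opposite* to the complexity ordering (transition-induced
covariance transients grow with N), which still supports the point of the
comparison: dFC variability does not track the latent state repertoire.

## Comparators

**Switching rate**: each channel is z-scored and binarized at
|z| > threshold (two-sided — excursions of either sign count); every
change of the binary state between consecutive samples is one switch; the
rate is averaged over channels.  The threshold grid is 2.0–3.0 SD in
steps of 0.1.  Zero-variance channels are excluded with a warning.

**dFC**: per window, the channels × channels Pearson FC matrix; dFC(i, j)
is the correlation between the vectorized strict upper triangles of FC(i)
and FC(j); the statistic is the population std of the strict upper
triangle.  At least 3 channels are required (with 2, each FC has a single
off-diagonal entry and the correlation between FC vectors is undefined).
The window grid is shared with the MDF so the comparison is like-for-like.

## Group statistics

**ISC**: each subject's MDF matrix is flattened to its strict upper
triangle (the symmetric half is redundant) and subjects are correlated
pairwise.  ISC inherits the MDF's invariance to the per-subject ICA
sign/permutation indeterminacy.

**CBPT** (paired, over an ordered axis such as window lengths): paired
t statistic per point; contiguous runs with |t| above the cluster-forming
threshold (default 1) form clusters with mass = Σt; the null distribution
of the maximum |mass| is generated by random per-subject sign flips of the
paired differences (exact for paired designs; default 10,000
permutations); cluster p = (1 + #{null ≥ observed}) / (1 + n_perm), so
p > 0 always and the test is two-sided.  The threshold applies to the
t statistic by default (a flag switches to raw mean differences — the
conventional choice is the statistic).  Zero-variance points map to
t = 0 (zero mean) or ±∞ (nonzero mean), and all-zero differences yield no
clusters rather than an error.  Under a simulated paired null
(S = 12, K = 30, 1000 permutations, 500 replicates) the family-wise
false-positive rate at α = 0.05 is 0.044.

**Wilcoxon**: the paired signed-rank test delegates to
`scipy.stats.wilcoxon`; at least 5 non-zero differences are required.

## HFa extraction and artifact rejection

HFa is the mean of the mean-normalized analytic amplitudes of four
contiguous 10-Hz subbands spanning 80–120 Hz: per subband a zero-phase
4th-order Butterworth band-pass (zero-phase filtering preserves envelope
timing), Hilbert-transform envelope, division by the envelope's temporal
mean; the average of the four is resampled to 100 Hz by polyphase
anti-aliased resampling.  Input must be sampled above 240 Hz.  Each
normalized subband has temporal mean exactly 1 by construction; filter
edge transients concentrate in the first/last ~2 s.

Artifact rejection: a channel is flagged when its variance exceeds
median + 2·IQR of the channel-variance distribution (the literal
"variance > 2·IQR" reading is available by flag); on retained channels,
samples beyond 5 SD of the channel (mean/SD estimated once, before any
replacement, single pass) are replaced by the channel mean, preserving
length and temporal structure.  Flagged channels are kept in place and
reported — `drop_flagged` removes them — so the output shape always
matches the input.  The IQR rule presumes a heterogeneous variance
spread; on perfectly homogeneous channels it can fire on sampling noise.

## Numerical and design notes

- Bin assignment is `floor((x − lo)/(hi − lo) · n_bins)` clipped to the
  grid, which makes the right-most edge inclusive; mirrored or permuted
  components map to mirrored/transposed maps exactly, giving the MDF its
  sign/permutation invariance up to measure-zero edge ties.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); same seed ⇒ bit-identical trajectories,
  embeddings and matrices.
- The simulator's inner loop is JIT-compiled (numba) and consumes
  pre-generated Wiener increments so the compiled path and the reference
  `heun_step` arithmetic agree step for step.
- Degenerate inputs fail loudly: constant latent dimensions (degenerate
  density bounds), constant channels (z-scoring, dFC windows), all-flagged
  channel sets, all-zero paired differences in the Wilcoxon.
- The pipeline writes a provenance record (all parameters, seeds, package
  version) sufficient to regenerate every number it outputs.

## Known limitations

- The empirical-scale MDF (10-min recordings, slide 100 ms, window grid
  1–30 s) is computationally heavy at full resolution; `corr_dtype`,
  `n_bins` and the window grid are the knobs to trade resolution for time.
- σ(MDF) is not monotone in state count in the transient few-transitions
  regime (see *Scaled study dimensions*); recordings should be long
  relative to the slowest switching timescale.
- 3-component analyses default to 128³ cells per map; reduce `n_bins`
  (e.g. 32) for realistic memory use.
- The CBPT forms clusters on runs of |t| above threshold, so a cluster
  may mix signs across adjacent points; with the default threshold 1 this
  matches the prescribed construction, but it differs from
  implementations that cluster positive and negative excursions
  separately.
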