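# Methods

This note documents the models, estimators, defaults, and design choices of
`thetadircomm`, and what the synthetic-data generators do and do not
emulate.

## The nMVAR model and the connectivity estimator

An M-channel series follows x(n) = f(x_p) + σ(n) with
x_p = [x_1(n−1), …, x_M(n−1), …, x_1(n−p), …, x_M(n−p)] (lag-major order)
and zero-mean white noise σ. The estimator decomposes f = f_lin + f_nonlin
*structurally*: the network is a linear shortcut W x_p + b in parallel with
one hidden tanh layer V tanh(U x_p + c). The prediction is exactly the sum
of the two parts, so "linear" and "nonlinear" connectivity are properties
of disjoint parameter sets rather than of a post-hoc decomposition.

Fitting minimises one-step-ahead MSE with full-batch Adam (default
learning rate 0.02, up to 400 epochs), seeded and therefore bit-for-bit
reproducible. Channels are z-scored internally; all connectivity values are
in standardized-input units. Two choices matter for the scientific
behaviour:

* **Warm start.** W is initialised at the least-squares VAR solution and V
  at tiny random values (sd 0.01), so the hidden pathway only learns
  structure the linear part leaves in the residual. On purely linear data
  the fitted model's validation MSE matches the least-squares VAR within a
  few percent; on data with a planted quadratic coupling it is >10% lower.
* **No point mass at zero.** The tiny (rather than exactly zero) V
  initialisation keeps the nonlinear sensitivities continuous. With an
  exact-zero initialisation, early stopping frequently returns NC ≡ 0, the
  surrogate null collects an atom at zero, and percentile thresholds become
  degenerate — the retention rate under the null is then far off nominal.

Early stopping uses the last 20% of samples as a held-out tail (patience
60), restoring the best parameters. Trial-boundary predictor windows are
excluded from the design matrix, so fitting on concatenated trials equals
fitting on the pooled set of valid within-trial windows (asserted exactly
in tests).

Connectivity extraction: lC(i→j) sums |W| over lags; NC(i→j) averages the
absolute partial derivative of f_nonlin for target j with respect to
x_i(n−k) over observed predictor windows and lags. The original method's
exact extraction formulas are not published in enough detail to replicate
numerically; these definitions are this package's declared reconstruction,
and validity is established by ground-truth recovery and null calibration,
not by numeric identity with any other implementation.

**Model order.** The pipeline default is p = 7 (the order used for the real
recordings this pipeline is modelled on). `select_model_order` fits linear
VARs for p = 1..p_max and reports Akaike and Schwarz (BIC) criteria
(statsmodels), with BIC breaking disagreements and orders clipped to ≥ 1.
Synthetic benchmarks use the generating order (p = 2) directly.

**Surrogates.** Phase randomisation is applied per channel independently:
uniform random phases on all non-DC/non-Nyquist rFFT bins, amplitudes
untouched. This preserves each channel's periodogram exactly (machine
precision) and its mean, while destroying cross-channel temporal structure.
The model is re-fitted per surrogate with identical hyperparameters and
initialisation seed; a connection is retained when its value exceeds the
95th percentile (default, configurable) of its own per-connection null.
With 20 surrogates the effective exceedance rate under an exchangeable null
is ≈9% (the 95th percentile of 20 samples is interpolated between the two
largest order statistics); with the default 100 surrogates it is ≈5%.
`n_surrogates=0` skips significance with a warning (all-true mask).

**Normalisation.** Per subject and per measure, every entry of both
conditions is divided by the maximum entry across both conditions, mapping
into [0, 1] with the maximum exactly 1. lC and NC are scaled independently.
Network averages use off-diagonal entries by default; self-connections are
computed and reported but excluded from averages unless requested.

## Beamforming

DICS: the band cross-spectral density is a trial-averaged Hanning-tapered
cross-spectrum accumulated over the band's DFT bins in the 300–600 ms
post-stimulus window. Filters are unit-gain minimum-variance rows
w_v = (l_v' C_r⁻¹ l_v)⁻¹ l_v' C_r⁻¹ on the real part of the CSD with
λ = 0.05 × mean diagonal (the common "5% regularization" convention).
Power is w Re(CSD) w'; noise normalisation divides by s_min·‖w_v‖², with
s_min the smallest CSD eigenvalue — a spatially inhomogeneous noise
estimate that removes the centre-of-volume bias. The same machinery on the
time-domain covariance (same window) gives LCMV virtual channels; a common
filter can be computed from the condition-pooled CSD and applied per
condition. A degenerate (all-zero) covariance reduces the filter to
w = l/(l'l), so zero input yields zero virtual series rather than an error.

The theta band-pass for virtual series is a Hamming windowed-sinc FIR
(default order 256 at 128 Hz) applied forward–backward (zero phase), chosen
so the 300–600 ms window alignment that temporal-causality estimation
depends on is not shifted by group delay; the doubled attenuation
comfortably exceeds 40 dB in the stop band with <1 dB passband ripple.

## ROI selection

Voxels within 3% of the maximum source power are kept; the phrase is read
as value-relative (power ≥ 0.97 × max), not as a top-3% quantile — it
references "the highest value", not a count. The quantile alternative is
available via `mode="quantile"`. DBSCAN runs on physical voxel positions
with ε = 1.5 × grid spacing and min_pts = 3, where min_pts counts the point
itself so every cluster has ≥ 3 members; ε = 1.5g admits face (g) and edge
(√2·g) neighbours but not corner (√3·g) neighbours. Points are processed in
lexicographic coordinate order, making border-point assignment
deterministic and independent of input order (sklearn's DBSCAN provides the
core algorithm). Clusters are ordered by size descending, ties by smallest
voxel index, and named AC1..ACk unless a label table is supplied;
anatomical naming is out of scope for the toy grid.

## Time–frequency and cluster permutation

`tf_decompose` computes short-time Hanning-tapered Fourier power; requested
frequencies are mapped to the nearest DFT bins of the analysis window
(duplicates dropped), with the window required to span ≥ 2 cycles of the
lowest frequency. Power is scaled so a unit-amplitude sinusoid at a bin
centre has power 0.25 regardless of window length.

The cluster-based permutation contrast uses a paired t at every (channel,
frequency, time) point, a two-sided cluster-forming threshold at α = 0.05,
same-sign clustering under channel adjacency plus 4-connectivity over
(frequency, time), the max summed-t statistic, and subject-level sign
flips (default 1000; `n_perm="all"` enumerates all 2^n patterns, used by
the calibration tests). The original analysis names the test but not its
window length, step, threshold, or permutation count; these defaults follow
the method's standard formulation and are configurable. Channel adjacency
defaults to a distance threshold at 1.3 × the median nearest-neighbour
sensor distance.

## Behavioral statistics

RT summaries use correct GO trials only by default (the source analysis
does not state this; a `correct_rt_only` switch exposes the alternative).
The 2×2 repeated-measures ANOVA is an explicit within-subject
sums-of-squares decomposition; with two-level factors every effect has
1 df, each F equals the squared paired t on the contrast scores, partial
η² = F/(F + df_error), and a sphericity correction is vacuous (hence none
is applied). Cohen's d for paired designs is d_z = |t|/√n, the convention
that exactly reproduces the study's printed d values from its printed t and
n = 53 (the study prints t(53) for the RT test where n = 53 pairs implies
df = 52; the package reports df = n−1 and reproduces the d values with
n = 53, leaving the printed-df discrepancy unresolved). Normality
diagnostics are not used to gate any test.

## Association

Spearman rank correlation (average ranks, t-approximation p) is the default
for every covariate analysis — robust to the biomarker's right skew; the
source report is ambiguous between r and rho, so Pearson is available
behind `method="pearson"`. BH-FDR is applied within each (condition,
measure) family of single connections (16 rows for four nodes,
self-connections included); network-average rows are adjusted within their
own per-condition family. Subjects missing from either table are dropped
pairwise; fewer than 5 complete pairs is an error.

## Synthetic data: what it emulates, and what it does not

* **nMVAR series** from explicit ground truth (stationarity of the linear
  part checked by the companion spectral radius; explosive nonlinear
  trajectories abort with advice to lower gains). Nonlinear forms are
  square, pairwise product, and tanh — enough to exercise NC without
  inviting blow-ups. Burn-in default 1000 samples.
* **Sensor trials** from a toy head model: a regular voxel grid (default
  spacing 5 units, the analog of a 5 mm grid), sensors on a surrounding
  hemisphere, inverse-distance leadfield with unit-norm columns. Active
  voxels carry band-limited oscillations (random frequency in 4–7 Hz and
  phase per trial) inside a 300–600 ms post-stimulus window with 25 ms
  ramps, amplitudes set per design cell, plus white sensor noise. The model
  has the localisation properties the beamforming stages need; it is not
  anatomically or volume-conduction realistic, and no ocular/muscle
  artifacts are simulated — so passing tests demonstrate method
  correctness, not robustness to real-EEG artifact structure.
* **Behavior logs** for the 2×2 design: lognormal RTs (positive support,
  right skew typical of RT data; the distributional shape is this package's
  choice, not an inference about the study data) matched to per-cell
  mean/sd, Bernoulli accuracy per cell. Defaults plant the study's group
  pattern: GO RT 495/524 ms (compatible/incompatible), GO accuracy
  95.04/89.41%, NOGO correct rejections 69.30/74.62%.
* **Cohorts** couple a per-subject connectivity scaling factor to a
  positive biomarker (lognormal margins, mean 6.55, cv ≈ 0.49) through a
  Gaussian copula with r = 2 sin(π·ρ/6), so the realised Spearman
  correlation is centred on the target ρ; a construction-time self-test
  enforces |realised − target| ≤ 0.15 for n ≥ 50. Subject series scale the
  base network's cross-couplings (diagonal terms untouched), so the base
  network must keep a stationarity margin for the largest scalings — the
  bundled base network (weak feed-forward couplings, one quadratic and one
  tanh edge) is stationary up to ≈2.5× scaling.

## Benchmark problem sizes

The validation suite and `scripts/acceptance.py` use: linear-coupling
recovery on M=4, p=2, n=20 000 (10 seeds; rank correlation truth vs lC);
quadratic-edge detection and white-noise null calibration with 20
surrogates per fit (10 seeds each; the null uses M=5 → 20 non-self
connections) plus one full 100-surrogate run on M=3, n=10 000;
cluster-permutation null calibration over 200 runs at n_perm=500 with an
exhaustive-enumeration cross-check at n=8 subjects; DICS localisation over
20 random single-source placements at SNR ≥ 10; DBSCAN against a
brute-force oracle on 200 random instances (n ≤ 50); and cohort association
recovery at n=50 subjects, target ρ=0.5, 10 seeds. The demo pipeline
configuration shrinks everything (8 EEG subjects × 16 trials, 15-subject
cohort, no surrogates, order 3, peak threshold 30% on the 50-voxel toy
grid — the 3% value-relative rule keeps too few voxels to form a
minimum-size-3 cluster on so coarse a grid) so the end-to-end run completes
in a couple of minutes.

## Known limitations

* lC/NC are reconstructions of the published measures' intent, not of an
  exact published formula; absolute values are not comparable across
  implementations, only within an analysis (the per-subject [0,1]
  normalisation reflects this).
* Surrogate calibration is exact only under channel-exchangeable nulls; for
  strongly cross-correlated linear data the NC null tends to be
  conservative.
* When a genuine nonlinearity is present, the hidden units that model it
  carry nonzero weights to every output and input, so NC entries *adjacent*
  to a true nonlinear edge (notably self-connections of the involved
  channels) are somewhat inflated relative to the fully-null surrogates and
  can pass the mask. The directed contrast (true edge vs its reverse)
  remains clean; interpret isolated near-threshold retentions cautiously.
* The toy head model cannot validate anatomical claims (atlas labels,
  hemispheric assignments); the `label_table` hook accepts user-provided
  names but none are bundled.
* BrainVision import covers the binary multiplexed IEEE-float/INT layouts
  mne reads; the bundled writer exists only to round-trip synthetic
  fixtures.
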