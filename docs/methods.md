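# Methods

This note documents the models behind `vitalwatch`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer should know about.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic vital-sign model

Each channel is simulated as

    x_t = baseline + circadian_amplitude * sin(2*pi*t / 86400 s) + e_t,
    e_t = a * e_{t-1} + u_t,     u_t ~ N(0, noise_sd^2),

an AR(1) noise process (initialised from its stationary distribution, so
the long-run variance is `noise_sd^2 / (1 - a^2)`) riding on a diurnal
sinusoid.  Defaults for the six canonical channels are typical resting
adult values (e.g. heart rate 74 bpm, innovation SD 1.5 bpm, lag-1
autocorrelation 0.6; SpO2 98%, SD 0.4%).  One named generator per
`(seed, channel index)` pair makes streams reproducible and means adding
a channel never perturbs existing ones.

Anomalies are additive spikes (one sample), level shifts and linear
drifts (default 20 samples), dropouts (samples set missing) and
oscillation bursts, with magnitudes expressed in multiples of the
channel's innovation SD.  The default scenario injects spike and
level-shift events with 6 SD magnitude and random sign at a 5% sample
density into the test stream; the training stream is always anomaly-free
(the detector's contract is to be trained on typical data).  Default
sizes: 8 000 training samples and 8 004 test samples at 1 Hz, which at
the default window geometry (window 8, stride 4) gives 1 999 training
windows and 2 000 test windows.

What the generator does **not** emulate: waveform morphology (ECG/PPG),
cross-channel physiological coupling beyond optional feature-level
cross-correlation, activity- or posture-driven regime changes, and
realistic artifact shapes (motion, probe detachment).  Passing tests
therefore demonstrate correct behaviour under stationary AR(1) noise with
additive anomalies, not performance on clinical recordings.

## State-space preprocessing

Per channel the smoother uses a local-linear-trend model (state = level +
slope) with transition [[1, dt], [0, 1]] and the integrated-noise process
covariance q·[[dt³/3, dt²/2], [dt²/2, dt]], rebuilt per elapsed interval
so irregular sampling is handled by composing time updates across gaps.
Measurement noise defaults to a robust estimate from first differences
(median absolute difference / 1.349, squared).  The filter implements the
standard measurement update with the prior term, and the RTS gain uses
the transposed transition, `B_k = P̂_k Φᵀ P̄_{k+1}⁻¹`; both choices are
required for the filter to pass its conjugate-Gaussian oracle and for the
smoother to satisfy the variance-ordering property (smoothed ≤ filtered ≤
prior) on arbitrary stable models.

Two robustness devices protect the baseline from the very anomalies the
pipeline must detect: innovations are clamped at 3 innovation SDs during
filtering, and `vitalwatch.agrnn` detrends in two passes — residuals
beyond 4 robust SDs after the first pass are masked before re-smoothing.
Without these, a level shift drags the two-sided smoother and
contaminates the residuals of neighbouring normal samples, which
measurably inflates the false-alarm rate.

Covariances are symmetrized after every update; PSD checks use a 1e-9
tolerance.  Only fixed-interval smoothing is provided (no fixed-lag
mode).  Normalization uses the population-variance convention (divisor =
count) and the signed square-root form, which at the default targets 0/1
is the per-channel z-score and is idempotent.

## Windowed features and discriminant PCA

Windows of 8 samples at stride 4 yield, per channel: mean, SD, min, max,
slope; plus lag-0 Pearson cross-correlation for declared channel pairs
(defaults: heart rate–pulse rate and systolic–diastolic, the two
physiologically coupled pairs).  Cross-correlation with a constant window
is defined as 0.  Windows in which any channel exceeds 30% missingness
are dropped and logged rather than imputed.  The small window keeps
single-sample anomalies a large fraction of their window, which matters
for the min/max features that carry most of the detection signal.

PCA uses the 1/(n−1) covariance and `eigh`; components are sorted by
descending eigenvalue and tiny negative eigenvalues are clipped at 0.
The discriminant stage regularizes per-class covariances two ways:
shrinkage γ toward the pooled covariance and shrinkage ρ toward a scaled
identity, guaranteeing invertibility for ρ > 0.  Class scatters carry no
divisor; the 1/[(1−γ)n_j + γn] factor of the γ-blend supplies the
maximum-likelihood normalization (so at γ=0 the class covariance is the
ML estimate scatter/n_j).  Defaults: γ=1 (pooled), ρ chosen by the
identity-shrinkage heuristic (tr(mean class covariance / n) + d)/d
clipped to [0,1].

## Recursive feature elimination

Features are standardized internally so the relevance ranking is
invariant to units (heart-rate bpm vs SpO2 %).  The base learner is a
linear max-margin classifier fit by projected-gradient ascent on the SVM
dual (deterministic: step 1/L with L the spectral norm of the Gram
matrix, 300 iterations, box [0, C], C=1), which directly yields the
nonnegative dual coefficients that the relevance weights consume.
Each round records stratified cross-validated accuracy (5 folds by
default), eliminates the single feature with the lowest rank-discounted
relevance φ = Z/rank (ties: lowest index first), and retrains; the
"ideal feature count" is the round with the highest mean CV accuracy,
ties resolved toward fewer features.  Batch elimination is available via
the `batch` argument.

## The detector

Training pipeline (all on anomaly-free data): chronological split into a
fitting segment (70%) and a calibration segment (30%); two-pass robust
detrending; window features standardized by the fitting segment's
mean/SD; an autoencoder (one dense layer each side, tanh encoder, linear
decoder, bottleneck max(2, ⌈p/3⌉)) fit by full-batch Adam steps on the
mean squared reconstruction loss; a genetic algorithm over (code mask,
alarm quantile, hidden-size scale); a vanilla tanh recurrent cell without
biases trained by full backpropagation-through-time with global-norm
gradient clipping to predict the next window's code.

**Anomaly score.**  The recurrent prediction is mapped back through the
decoder and compared with the observed window in feature space; the score
is the largest per-feature deviation in units of each feature's
calibration error SD.  Scoring in the observed space rather than the code
space keeps localized single-channel anomalies from being diluted by
averaging over code dimensions, and lets the decoder's reconstruction
error contribute signal for deviations the bottleneck cannot represent.
When a window's score exceeds the threshold, the prediction (not the
observation) feeds the next recurrent step, so one anomalous window does
not raise a false alarm on its normal successor.

**Threshold calibration.**  The threshold is the genome's quantile of the
scores on the *held-out* calibration segment.  Scores on windows the
network was fitted to sit systematically low (generalization gap), so
including them would bias the threshold below its deployment quantile;
the calibration scores are stored in the model bundle so the quantile
identity can be verified exactly.

**Genetic search.**  Fitness is balanced accuracy on the calibration
split, where synthetic spike/level-shift anomalies (6 robust SDs, 8%
density) injected into a copy of the calibration segment supply
positives; each genome is scored with a reduced-epoch recurrent net as a
surrogate for the final model.  The alarm-quantile gene is searched
within [0.975, 0.995]: the lower edge keeps the expected flagged fraction
of typical windows near 2.5%, leaving the 5% clinical false-alarm budget
room for calibration noise and residual baseline contamination.  Balanced
accuracy alone is nearly flat in the quantile once the classes separate,
so without this bound the search drifts toward alarm rates a monitoring
deployment would not accept.  The `ga_vary_scalars` switch freezes the
scalar genes (quantile 0.98, scale 1.0) so that repeated fits — e.g. the
six cross-validation folds — are directly comparable; the harness uses
it.

**Optimizer note.**  Both networks use adaptive-moment (Adam) gradient
steps rather than raw gradient descent: with raw steps the linear
autoencoder diverges at practical learning rates on feature matrices
whose scales differ by orders of magnitude, whereas Adam converges to
reconstruction losses below 1e-4 on low-rank fixtures regardless of
scale.  The recurrent trainer additionally clips the global gradient norm
at 5 and aborts with diagnostics if the loss exceeds 1e6 or becomes
non-finite.

## Cross-validated reporting

The six-fold harness operates on labelled windows (stratified, seeded
fold assignment).  Inside each fold the detector's autoencoder and
recurrent net train only on the fold's normal windows (chronological
order preserved); the labelled anomalous windows serve as the genetic
search's validation positives.  The per-fold table reports accuracy and
the RMSE between predicted flags and true labels, both in percent, with
mean ± SD.  Hardware resource consumption is inherently
platform-dependent, so the kit reports a deterministic operation-count
proxy (multiply-adds per scored window) clearly labelled as a proxy.
Lifetime (data-arrival-rate × period) and propagation latency
(distance/speed) are implemented as literal formulas with unit
pass-through and no network simulation.

## Problem sizes

Defaults were chosen once for the study conditions and are used by the
acceptance experiments: detection uses 8 000 training samples / 2 000
test windows per seed over 3 seeds; the six-fold harness uses 1 500
windows per seed with the reduced harness configuration (population 8,
4 generations, 60 recurrent epochs); feature-selection recovery uses 600
windows × 20 features × 5 seeds; the genetic-search oracle uses 20 runs
of population 30 × 50 generations against exhaustive enumeration of the
255 valid 8-bit masks.

## Known limitations

* The detector assumes the training stream is representative; concept
  drift beyond the circadian component is not modelled.
* Detection operates at window resolution; a one-sample spike flags its
  whole window(s).
* The score is calibrated per model; thresholds are not transferable
  between detectors.
* Windows with more than 30% missingness are dropped, so dropout
  anomalies longer than the window are detected only through their edges
  unless missingness itself is monitored upstream.
* The genetic search's fitness is stochastic (it retrains a surrogate
  net per genome); with tiny budgets it can return masks that the final
  full-budget net would not rank best.
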