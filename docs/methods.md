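# Methods

This note documents the models implemented in `acimage`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for
reproducing results.

## Task and stimuli

The task is a single-interval forced choice: listeners hear one of four
/aCCa/ nonwords (*alda, alga, aRda, aRga*) in white noise and report
whether the final syllable is /da/ or /ga/. The response on trial *i*
is coded *r_i* = 0 ('da') / 1 ('ga').

The package synthesizes the four targets by additive formant synthesis:
four AM sinusoids follow piecewise-linear F1–F4 trajectories under a
two-syllable voicing envelope with a stop closure at 328–395 ms. All
targets share 680 ms total duration, a 328 ms first syllable, and a
48 kHz sampling rate, and are power-normalized to unit RMS. The
trajectories place the second-syllable formant onsets at the loci that
carry the place-of-articulation contrast: for /da/ an F1 onset near
665 Hz, F2 near 1380 Hz and F3 near 2557 Hz; for /ga/ an F2/F3
convergence ("velar pinch") near 1977 Hz. These synthetic stand-ins
are not natural speech; they exist so that the cue geometry the
analysis interrogates is acoustically real and fully known.

Noise tokens are i.i.d. Gaussian white noise, RMS-normalized, and
bit-reproducible from an integer seed, so a trial is fully determined
by (target label, noise seed, SNR). SNR is defined on full-waveform
broadband RMS — `mix = target + g·noise` with
`g = RMS(target)/RMS(noise) · 10^(−SNR/20)` — and the mixture is
re-normalized to unit RMS, so absolute level carries no information.

## Cochleogram front end

Each stimulus is represented as a 54×81 map: 54 gammatone channels
(4th order) with center frequencies ERB-spaced from 100 to 8000 Hz
(Glasberg–Moore ERB-rate scale, endpoints anchored), and 81 contiguous
equal time frames over the 680 ms. Per channel: circular
frequency-domain bandpass filtering (zero-padded to a fast FFT
length), half-wave rectification, block-mean decimation (factor 8 at
48 kHz), a 2nd-order Butterworth lowpass at 150 Hz for envelope
smoothing, frame averaging, and `20·log10` compression floored 60 dB
below the map maximum. The 100–8000 Hz band covers the F1–F4 cue
region and the audiometric range relevant to the task; the front end
is deliberately simple (no adaptation or compressive nonlinearity
beyond the log) and every choice is config-pinned because the analysis
downstream is defined relative to this fixed representation, not to a
specific model of the periphery.

Filtering runs in float32 by default (the fast path that makes
10,000-trial simulations tractable, ~15 ms per stimulus); float64 is
available where strict numerical covariance matters (e.g. exact
20·log10 k level shifts under waveform scaling).

The flattened map (channel-major, 4374 bins) is the predictor vector
*S_i*.

## Simulated listeners

A simulated listener is a linear template observer: response 'ga' iff
`⟨T, cochleogram⟩ − c + ε > 0` with internal noise
ε ~ N(0, σ²). The standard observer uses the matched template — the
clean-target 'ga'-minus-'da' mean cochleogram difference, unit
Frobenius norm — with the criterion calibrated to be unbiased on noisy
stimuli at −10 dB SNR. With internal noise σ = 10 the observer runs
the staircase near −12 dB SNR with d′ ≈ 1.6, matching the operating
point a real cohort reaches in this task. Per-observer strategy quirks
are modeled as smooth Gaussian-bump perturbations added to the
template before renormalization.

SNR is adapted by a 3-down 1-up transformed up-down rule: one step
harder after three consecutive correct responses, one step easier
after any error. Its asymptote is the SNR where
p_correct³ = 1/2, i.e. 79.4% correct. Steps are 1 dB (2 dB during an
80-trial initial approach phase), starting at 0 dB, clipped to
[−30, +20] dB; these staircase constants are declared defaults of this
implementation. Targets are drawn uniformly at random per trial and
the standard run is 10,000 trials in 20 sessions of 500.

What the generator does **not** emulate: learning and fatigue across
sessions, reaction times, lapses, multiple listenings of a stimulus,
or nonlinear/off-template listening. Passing tests therefore validate
the estimation and inference machinery against a known linear ground
truth; they do not certify behavior on real listeners, whose decision
process need not be linear in the cochleogram.

## ACI estimation

The ACI is the coefficient map of a penalized logistic regression of
*r_i* on *S_i*:

    minimize over (β, b):
      −2 Σ_i [ r_i z_i − log(1+e^{z_i}) ]  +  λ (‖D_t β‖² + ‖D_f β‖²)
                                           +  ε_ridge · λ · ‖β‖²

with z_i = b + ⟨β, S_i⟩, first-difference operators D_t, D_f along the
two lattice axes, ε_ridge = 10⁻³ (removes the constant-map null space
of the difference penalty; strict convexity), and an unpenalized
intercept. Predictors are standardized per bin on the training data;
the standardization is stored with the model and re-applied at
prediction time (it makes λ comparable across observers; `beta` in
natural units is the standardized-space solution divided by the
per-bin scales).

Solver: damped Newton with preconditioned conjugate-gradient inner
solves. The CG preconditioner is the exact sparse penalty plus the
deviance diagonal, factorized per Newton step (the lattice penalty has
≤ 5 nonzeros per row, so this is cheap); the forcing sequence loosens
inner solves far from the optimum and performs one high-accuracy solve
terminally. Near the optimum the objective decrement falls below
float64 resolution, so steps there are accepted on gradient-norm
decrease rather than an Armijo test. Convergence requires terminal
gradient norm ≤ 10⁻⁶ (default), else an error reports the achieved
norm. Problems with ≤ 1500 parameters use exact dense Newton solves
instead. On 54×81 maps with ~4000 balanced trials a fit takes a few
seconds.

Model selection: 10-fold cross-validation (random equal partition,
seeded). In every training and test set the proportions of correctly
and incorrectly categorized trials are equated by seeded subsampling
of the majority class, so the listener's accuracy level does not leak
into estimation or evaluation. Scores are the cross-validated deviance
(CVD, summed over the balanced test set; a per-trial deviance is also
stored since balanced test sizes depend on accuracy) and the
cross-validated classification rate (CVR; p = 0.5 counts as
predicting r = 1). λ is chosen from a log grid (default 10 points,
10⁰–10⁵) by the lowest mean CVD — averaged across all observers of a
cohort when several are analyzed together, ties broken toward the
smoother map — and the final ACI is refit on the complete balanced
dataset at that λ. On simulated 10,000-trial observers the CV curve is
U-shaped with its minimum typically at λ ≈ 10⁴.

## Specificity

Each model is also scored on every other observer's data
(cross-prediction): model *j*'s probabilities on observer *k*'s
balanced test folds, using the same fold partition and balancing seeds
as *k*'s own cross-validation (so auto- and cross-prediction deviances
are sums over identical test sets), and *j*'s stored standardization
(the model is a fixed decision rule; applying *k*'s standardization
instead is available via the functions' arguments). The full N×N
matrix is computed; the diagonal carries the auto-prediction CVDs.
Specificity of observer *k* is the mean off-diagonal cross-prediction
deviance of their data minus their auto-prediction deviance; positive
values mean part of the data is predictable only by the listener's own
map.

## Group statistics

*Cluster permutation test.* Per-bin equal-variance two-sample t-tests
(Welch is a keyword away), thresholded at a per-bin two-tailed
α = 0.05 (config-exposed; no principled value exists for a
cluster-forming threshold), 4-connected components split by t sign,
cluster mass = signed sum of t within the cluster. The null is the
maximum |mass| over clusters under random permutations of group labels
(default 5000), with p = (1 + #{null ≥ |mass|})/(n_perm + 1); when the
number of distinct label splits is not larger than n_perm, all splits
are enumerated and p-values are exact proportions. 4-connectivity (no
diagonals) is the documented adjacency convention; reported cluster
and ROI sizes depend on it.

*ROIs.* One-sample running t-test against zero on the pooled cohort
(both groups), threshold p < 10⁻¹⁰, 4-connected components of at least
7 bins. Polarity is the sign of the mean pooled weight; centroids are
weight-magnitude-weighted means of frame times and center frequencies.
Mean ROI weights per observer are then compared between groups with
two-sample t-tests.

*Individual deviance analysis.* Two passes at the 1.65 SD threshold
(the conventional two-decimal fifth-percentile normal quantile):
controls beyond 1.65 SD of the control mean are removed, mean/SD are
recomputed on the trimmed controls, and each case beyond 1.65 SD of
the trimmed statistics is flagged (deviance direction declared per
measure). Degenerate controls (zero SD before trimming) raise; if
trimming itself collapses the SD to zero, a case is deviant iff it
differs from the trimmed mean.

## Numerical and scaling choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); trial tables, folds, balancing,
  permutations and study runs are bit-reproducible.
- Probabilities are clipped to [10⁻¹², 1−10⁻¹²] before deviances.
- Degenerate inputs: all-zero waveforms yield the all-floor
  cochleogram; zero-variance bins get t = 0, p = 1 with a warning;
  zero-RMS signals cannot be mixed or normalized and raise.
- The test suite runs scaled-down versions of the full study as the
  package's own verification sizes: one 10,000-trial observer for
  recovery (with a 2,500-trial subset for the trial-count contrast and
  a 4-point λ sub-grid with 5 folds for selection), 2,500-trial
  observers for the specificity cohorts, 20×20 lattices with 18+18
  maps, 500 permutations and 200 repetitions for permutation-test
  calibration, and miniature (2+2 observers × 500 trials) end-to-end
  studies. `StudyConfig()` defaults to the full reference conditions
  (18+18 observers, 10,000 trials, 5000 permutations).

## Known limitations

- The formant-synthesized targets are schematic; cue positions are
  exact but natural-speech redundancy (harmonics, bursts, amplitude
  detail) is absent.
- The front end is one reasonable cochleogram, not a calibrated
  auditory model; absolute deviance scales depend on balanced test-set
  sizes and are not comparable across experiments with different
  accuracy levels.
- The observer model is linear with Gaussian internal noise; template
  recovery quality is reported in the standardized predictor space
  (the noise-expressed part of the template), since bins without
  trial-to-trial variance carry no recoverable weight.
- The cluster-forming α and the adjacency convention materially affect
  cluster/ROI sizes; both are explicit parameters.
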