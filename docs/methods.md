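# Methods

## Recording model and reconstruction

A CI telemetry trial is modelled as 65 recording windows of
`samples_per_window` points (default 2048, i.e. ~1.2 MHz within the 1.7 ms
window), each followed by a 13.68 ms reset. The window start-to-start period
of 15.38 ms gives the effective series rate `round(1000 / 15.38) = 65 Hz`,
and 65 windows span the 1 s cue–target interval. Reconstruction discards the
first `discard_n` samples of every window (default 100, the filter-artifact
prefix, 0.083 ms of the window) and averages the remainder; averaging a
window is a linear operation, so the reconstruction is linear in the input
and provably invariant to anything written over the discarded prefix.

The optional band-pass mirrors standard EEG practice: a Hamming-windowed
sinc FIR, 4–25 Hz, order 424 (425 taps; we define order = taps − 1 so the
group delay of 212 samples is integral and one-pass zero-phase compensation
is exact). At 65 Hz this order corresponds to the nominal 0.5 Hz transition
width of the Hamming design rule. Because the kernel (6.5 s) is far longer
than a trial (1 s), each trial is padded to ≥ 3 kernel half-lengths before
filtering and truncated back. Padding is configurable:

- `mirror` (default): even reflection; smallest assumptions, but reflecting
  a narrow-band signal reverses its phase progression, so in-band components
  of a single 65-sample trial incur edge transients of order 10–25 % RMS.
- `wrap`: periodic continuation; exact for the integer-Hz components of a
  1 s window (used by the tests that verify zero-phase behaviour).
- `zero`, and `concat` (filter all trials as one continuous record).

These transients are condition-independent and common to all trials, so the
condition contrasts and classifiers downstream are unaffected in
expectation; the filter's in-band idempotence (< 5 % RMS change) holds for
long band-limited records and is tested there.

## Spectral estimation

Each 65-sample series is demeaned, least-squares linearly detrended,
tapered with a periodic Hann window and Fourier-transformed. The 1 s window
fixes 1 Hz resolution; power is reported on the integer bins 4–25 Hz
(22 bins) as a taper-energy-normalised one-sided density
`2|X_k|² / (fs · Σw²)` (mV²/Hz). The scale convention is irrelevant to every
inference in the package (contrasts, ranks, standardized features); the
untruncated energy-convention periodogram is exposed separately and
satisfies Parseval's identity exactly, anchoring the scale. The 5-point
moving-average smoother is display-only and never feeds statistics. Bands:
theta 5–8, alpha 9–13, beta 14–24, broadband 4–25 Hz; band power is the
arithmetic mean over the band's bins. Within-subject error bars use the
Cousineau normalisation (remove each subject's cross-condition mean, restore
the grand mean) with the Morey correction `sqrt(C/(C−1))`.

## Permutation inference

Dependent-samples inference treats the per-subject condition difference as
the exchangeable unit: under the null the difference vector's sign is
exchangeable, so the null is built by flipping each subject's whole vector
(preserving within-subject correlation across bins). The cluster variant
thresholds per-bin paired t values at the one-tailed critical value for
`cluster_alpha` (default 0.05), groups contiguous supra-threshold frequency
bins, sums t within clusters, and compares the maximum observed mass to the
permutation maxima. The band-averaged variant is the single-bin degenerate
case; for n ≤ 20 subjects an exhaustive 2ⁿ enumeration is available and the
sampled estimator is verified against it. Monte-Carlo p values use the
add-one convention, so the smallest attainable p at 10 000 randomizations is
~1e−4. Paired Cohen's d is mean(diff)/SD(diff) (n − 1 denominator); an
identical pair of conditions yields d = 0, while a zero-variance nonzero
difference is undefined and raises.

## Decoding

Features are a trial's band power bins (broadband 22, theta 4, alpha 5,
beta 11 columns), standardized per subject over all trials (population-SD
convention, matching common ML tooling; a sample-SD option exists).
Full-dataset standardisation and the reuse of the same trials for neighbour
grid search and evaluation reproduce the published procedure and are mildly
optimistic; both facts are documented here rather than silently "fixed",
and the permutation chance level is computed under the identical procedure,
so observed-vs-chance contrasts remain calibrated. kNN uses Euclidean
distance, odd k only (no two-class vote ties), and breaks distance ties by
lowest training index — predictions are fully deterministic and equal an
exhaustive distance-sort oracle. Cross-validation is stratified shuffled
two-fold; the neighbour grid is odd k from 1 to ⌊n/10⌋ (24 candidates at
488 trials), CV-score ties resolved toward the smallest k. The permutation
test shuffles labels globally, redraws stratified folds per permutation,
and scores at the fixed best k; chance is the mean of the permutation
scores and p the add-one probability. Group statistics: per-band one-sided
paired t (observed > chance) with paired d, a two-factor repeated-measures
ANOVA (band × type) with partial η² (via pingouin), and the count of
subjects with per-subject permutation p < 0.05 (uncorrected) in any band.

## Volume-conduction check

Cross-correlation reports the Pearson correlation over the overlapping
samples at each lag (positive lag = EEG delayed). The Bayesian test of the
zero-lag correlation evaluates the JZS marginal-likelihood integral

    BF10 = sqrt(n/2)/Γ(1/2) · ∫₀^∞ (1+g)^((n−2)/2) (1+(1−r²)g)^(−(n−1)/2)
                                 g^(−3/2) e^(−n/(2g)) dg

by quadrature in log-g coordinates with the integrand's peak factored out
(stable for |r| up to 1 − 1e−6 and large n); it matches an independent
implementation of the same integral to < 1e−4 in ln BF. Per channel, the
per-trial zero-lag r values are computed against the 65-sample CI series;
the channel's evidence is the mean of per-trial ln BF10 (n = 65 each), with
the BF of the trial-averaged r reported alongside — the aggregation across
trials is genuinely ambiguous and both aggregates are exposed. Verdicts use
ln(BF10) thresholds 1.1 (substantial) and 2.3 (strong). Channels over the
implant can be excluded by index; exclusion is user-supplied, never
inferred.

## Synthetic sessions

The generator emulates the experimental design exactly: per block, 43/42
auditory/visual cues shuffled, 8 visual and 8 auditory oddballs drawn
independently and uniformly (joint oddballs possible), behaviour as
independent Bernoulli(0.96) correctness. Each trial's latent signal is a
continuous 1 s process: Gaussian broadband noise plus a theta-band
component obtained by band-passing white noise to 5–8 Hz (4th-order
Butterworth, zero-phase) and scaling to a target RMS amplitude — amplitude-
modulated narrow-band noise rather than a sinusoid, so simulated spectra
are peakless like real low-SNR telemetry. The amplitude is
`base_theta_amplitude` times `attend_auditory_gain` on auditory-cue trials
(times a per-subject lognormal jitter with log-SD `per_subject_gain_sd`),
and times 1 otherwise; per-trial amplitudes are retained as ground truth.
The process is synthesised at `latent_rate` (default 1040 Hz = 16 × 65,
ample for a 4–25 Hz analysis band) and linearly interpolated onto each
window's sample times, shifted by the trial's start jitter ~ U[0, 27] ms
(maximum entropy over the stated range; applied per trial). Each window
then receives an independent Gaussian offset (SD 0.4 mV — one offset per
window, since each window is an independent recording) and a deterministic
exponential artifact (peak 5 mV, decay constant prefix/5) over its first
`artifact_prefix_len` samples, so tests can verify artifact invariance; the
real artifact's shape is unknown and only its removal matters.

Scale choices (base theta RMS 0.5 mV, broadband noise SD 0.5 mV, default
gain 1.2) were fixed once to give the low single-trial SNR regime of
single-channel CI telemetry: per-trial theta-band signal power of the same
order as the noise power falling in the band, yielding subject-level
decoding accuracies in the 0.55–0.65 range rather than a trivially
separable problem. What the generator does *not* emulate: electrode
geometry and current spread, ECAP waveforms, 1/f background structure,
autocorrelated behavioural lapses, or recording dropouts. Passing tests
therefore demonstrate correctness and calibration of the analysis machinery
under the design's statistical structure, not fidelity to any particular
patient's data.

## Simulation sizes and numerical choices

Cohort-level suites run at reduced scale while keeping the 65-window trial
structure and 16-subject cohorts: null calibration uses 200 cohorts × 24
trials/subject with 64-sample windows and 1000-permutation band tests
(the sign-flip test is exact under the symmetric null, so trial count does
not affect its level, only its power); parameter recovery uses 20 cohorts ×
120 trials/subject at gain 1.5 with 100-permutation chance estimates. The
decoding chance calibration runs at the full default design (~488 retained
trials, 1000 permutations). Degenerate inputs are contracts, not silent
NaNs: zero-variance features, empty conditions, even k, |r| = 1 and
mismatched shapes raise; the one deliberate exception is t = 0 / d = 0 for
exactly identical conditions. Master seed → per-stage, per-subject child
streams via `numpy.random.SeedSequence([master, stage, subject, ...])`, so
every result is bit-reproducible and adding subjects never perturbs
existing ones.

## Known limitations

- The filter-length/trial-length mismatch makes single-trial filtering
  padding-dependent; the choice is explicit and configurable rather than a
  claim about any particular toolbox's internals.
- Grid-search-on-evaluation-data and full-data standardisation are
  reproduced deliberately; a nested/within-fold workflow would give
  slightly lower, less optimistic observed accuracies.
- Theta and alpha band tests are run without cross-band correction,
  mirroring the two-band analysis design.
- The rmANOVA treats accuracies as unbounded Gaussians, adequate for
  accuracies near 0.5 with 16 subjects.
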