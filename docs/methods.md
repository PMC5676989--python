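# Methods

`wheelbeat` implements a continuous ECG-biometric pipeline for single-lead
signals acquired through dry electrodes under intermittent contact — the
regime of sensors embedded in a steering wheel, where contact loss and
amplifier saturation dominate and classical fixed-passband cleaning is not
enough.  This note records the model, the tunable parameters, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Pipeline

A recording `(x[n], fs, lead-on mask)` is processed as:

1. **Gating & framing.** Samples outside lead-on runs are discarded.  Each
   maximal contact run is cut into 5 s frames advancing by 1 s (4 s
   overlap): a first identity decision is possible five seconds after
   contact, renewed every second.  Frames are anchored at the run start and
   never span a contact dropout; trailing partial windows are dropped.
2. **Denoising.** Savitzky-Golay smoothing (local least-squares polynomial
   fit) removes broadband high-frequency noise without blunting the QRS,
   then the signal's own 1 s moving average is *subtracted* to remove
   baseline drift.  A moving average is itself a lowpass, so only the
   subtraction removes low frequencies; we read the "moving average filter
   … removing low frequency noise" combination this way and treat the
   moving average as a dense (stride-1) convolution.  Both filters use
   reflect padding so 5 s frames have no end transients.
3. **R-peak detection** (grey-scale morphology).  Stage 1 averages
   open-then-close and close-then-open filtered copies, erasing impulsive
   spikes of either polarity.  Stage 2 (peak-valley extraction, PVE)
   subtracts a morphologically smoothed copy from the stage-1 output; what
   survives are deflections sharper than the PVE structuring element.
   Candidates above an adaptive threshold — half the median of the five
   largest PVE values in the frame — become R-peaks, with a 0.25 s
   refractory period.
4. **Segmentation & normalisation.** A fixed window of 0.25 s before and
   0.40 s after each R-peak (no time normalisation — onset/offset
   localisation is unreliable at this noise level) yields templates of
   `round(0.65 fs)` samples, z-scored with the population-SD convention;
   zero-variance segments (saturation plateaus) are discarded.
5. **NCCC outlier rejection.**  For templates `x_1..x_N`, `NCC_ij` is the
   maximum over integer lags of the zero-normalised cross-correlation and
   `A_i = (1/N) Σ_j NCC_ij` (the self term `NCC_ii = 1` included, matching
   the printed summation bounds).  Templates are ranked by descending `A`
   (ties broken by original index); the cluster is seeded with the top
   `n = 3` and grown greedily: with `m` the running mean of cluster
   members' `A` and `ε = ε₀ m²` (`ε₀ = 0.1`), the next-ranked template is
   admitted iff `m − A_i ≤ ε` and `A_i ≥ 0.5`, stopping at the first
   rejection.  The selection is therefore always a prefix of the ranking
   and never smaller than `min(N, n)`.
6. **Ensemble & features.** The pointwise mean of the selected templates is
   the ensemble heartbeat; from it we extract either the orthonormal DCT-II
   coefficients below 40 Hz — `floor(2·(L/fs)·40)` of them, 52 for the
   canonical 650-sample beat — or the 163 level-2 Haar detail coefficients.
7. **Recognition.** SVM (RBF, `C = 10`, `γ = 1/d`, sigmoid-calibrated),
   kNN (`k = 3`), a one-hidden-layer MLP (64 units), or GMM-UBM (diagonal
   mixture over all enrolment data, per-subject MAP mean adaptation with
   relevance factor 16, softmax-normalised adapted-vs-background
   log-likelihood ratios).  All models emit a per-identity score vector in
   `[0, 1]` summing to one; features are standardised with statistics
   fitted on training data only.
8. **Continuous decisions.** Identification is the score argmax (ties to
   the earlier enrolled identity); authentication compares the claimed
   identity's score against a per-user threshold set at that user's
   equal-error point on validation scores.  Past-score weighting replaces
   the current vector with the convex combination of the last `N = 4`
   vectors under half-Gaussian weights
   `w = exp(−(t_n − t₀)²/(2σ²))`, `σ = 2 s` — one past score per second of
   frame overlap.

## Synthetic data

No public steering-wheel ECG collection exists, so the package carries its
own generator.  The clean signal follows the limit-cycle dynamical ECG
model: a phase variable advances at the instantaneous angular heart rate
and the voltage obeys `dz/dt = F(θ) − z`, with `F` a sum of five
Gaussian-derivative angular events (P, Q, R, S, T).  On the attractor the
planar subsystem is pure rotation, so we integrate the exact reduction with
an exponential-Euler recursion — fast, vectorised, bit-reproducible — and
rescale event gains per beat so wave amplitudes are realised in mV
regardless of heart rate.  Beat-to-beat intervals carry ~0.1 Hz and
~0.25 Hz oscillatory modulation plus white jitter (fractional SD = the
subject's `hrv`, default 5%).  Ground truth (R-peak samples, clean
reference, lead-on mask, subject label) travels with every stream.

Cohort subjects draw wave amplitudes and widths uniformly within ±20% of
textbook values, wave angles within ±6°, heart rate in 55–90 bpm.
Contamination adds baseline wander (lowpass-filtered noise below 0.5 Hz,
0.2 mV RMS), 50 Hz powerline pickup (0.05 mV), broadband EMG-like noise
(0.05 mV SD), Poisson saturation episodes (2/min, mean 1 s) that pin the
signal at the ±2.5 mV rail with a 0.5 s exponential recovery, and Poisson
contact-loss gaps (2/min, mean 2 s) that clear the lead-on mask.  The whole
record is clipped at the rail, as a real front end would.

What the generator does **not** emulate: electrode impedance dynamics and
skin-contact artefact shapes of real dry electrodes, pathological rhythms,
ectopic beats, multi-lead geometry, or within-subject day-to-day drift.  A
green end-to-end test therefore establishes that the pipeline's machinery
is correct and that its stages compose as designed under a realistic noise
budget — not that the paper-reported field performance transfers.

## Numerical and design choices

- **Sampling rate 1000 Hz** (default, configurable): the only rate at which
  a 0.65 s beat gives both 52 sub-40 Hz DCT coefficients and 163 level-2
  Haar details, the two printed feature counts.
- **Savitzky-Golay window 51 samples (0.051 s), order 3**: preserves the
  ~0.1 s QRS while averaging broadband noise.
- **Morphology structuring elements**: flat, 0.02 s for the noise-filtering
  stage and 0.07 s for PVE.  Flat opening removes peaks *narrower* than the
  element, so the filtering element must be shorter than the R deflection
  (~40 ms base width on synthetic beats) for the R to survive stage 1, and
  the PVE element must be wider so the smoothed copy loses the R and the
  subtraction extracts it.  With the assignment reversed the detector
  returns nothing — measured, not assumed.  PVE uses
  `filtered − close(open(filtered))`; the alternative ordering is a config
  flag.
- **max-NCC lag search**: all integer lags, numerators via FFT
  cross-correlation, means/SDs computed on the overlapping support only
  (cumulative-sum identities), lags with under 50% overlap excluded —
  short overlaps produce spurious near-1 maxima.  Values are clipped to
  `[−1, 1]` against FFT round-off.
- **z-score**: population SD (divide by N), fixed and tested.
- **DCT count**: `floor(2·L·fmax/fs)` with the division performed last, so
  exact-integer cases (650·80/1000 = 52) are not perturbed by rounding.
  This floor form realises the half-open band `[0, 40)` Hz; the closed band
  would give 53.
- **Haar boundary**: odd-length levels extend by repeating the last sample
  (half-sample symmetric), giving per-level length `floor((L+1)/2)` —
  650 → 325 → 163.
- **EER**: equal-error point of the ROC convex hull (the
  pool-adjacent-violators construction standard in speaker verification),
  linearly interpolated along the crossing segment.  This is invariant
  under strictly monotone score transforms and well-defined on the small,
  discrete score sets the protocols produce; a naive staircase FAR = FRR
  crossing is neither.
- **Score calibration**: margin classifiers are mapped to probabilities by
  logistic (sigmoid) calibration fitted on training scores.  Per-frame
  min-max rescaling is deliberately rejected — it destroys cross-frame
  comparability, which the past-score weighting relies on.
- **MLP early stopping** is enabled only with ≥ 100 training vectors; on
  smaller sets the validation split starves the fit and the network never
  leaves its initialisation.
- **GMM-UBM component count** (default 16, configurable): with mean-only
  MAP adaptation, a background model rich enough to dedicate components to
  individual subjects leaves nothing for adaptation to move and the
  likelihood ratio flattens — on a six-subject synthetic cohort, 2
  components identify at ~0.95 while 16 sit near 0.51.  The default keeps
  the conventional speaker-verification setting; small, highly separable
  cohorts warrant 2–4 components.
- **Protocols**: 70-30 splits each subject's ensembles chronologically
  (train strictly precedes test); `folds = k > 1` instead partitions the
  sequence into k contiguous blocks, each testing once.  The scarce
  protocol trains only on ensembles wholly inside the first 30 s of each
  subject's first recording.  Because adjacent frames share 4 s of signal,
  any test frame overlapping a training frame of the same recording is
  excluded before scoring.
- **Denoising quality metric**: RMSE against the clean reference is
  computed over lead-on samples; inside contact-loss gaps there is no
  signal to recover and both the raw and denoised records are equally
  uninformative.
- **Seed fan-out**: one global seed, per-stage sub-seeds by CRC-32 hashing
  of the stage name (all below 2³¹).

## Known limitations

- The synthetic cohort is markedly easier than real steering-wheel data:
  subjects are stationary, morphology is exactly repeatable, and noise is
  statistically well-behaved.  Reported synthetic IDR/EER characterise the
  pipeline, not field accuracy.
- NCCC's stop-at-first-rejection rule means one borderline template can
  shadow later good ones; this is the specified behaviour, and the
  selection-prefix invariant depends on it.
- Saturation plateaus inside an otherwise-usable frame are handled only by
  template rejection; no interpolation or reconstruction is attempted.
- Template/model update over time (re-enrolment, ageing) is out of scope.
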