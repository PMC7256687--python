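# Methods

`neurodecline` implements a multimodal pipeline that predicts decline in
cognitive domains over an 18-month interval from three data sources:
task/rest EEG connectivity, structural MRI volumetry and texture, and
baseline neuropsychological testing.  This note documents the models,
the numerical choices, and what the synthetic cohort generator does and
does not emulate.

## EEG preprocessing

Recordings are rereferenced to the average of the two earlobe
electrodes (removing the bias of the original FCz reference), then
filtered with a zero-phase 1 Hz high-pass at 48 dB/oct and a 50 Hz
notch.  The 48 dB/oct rolloff maps to an 8th-order Butterworth; we apply
it forward–backward (`sosfiltfilt`), which gives zero phase at the cost
of doubling the effective order — a deliberate reading, since the
filter was specified by rolloff and "zero-phase" without naming the
realization.  The notch is realized as a 2nd-order Butterworth bandstop
of 2 Hz width; width and order were open choices.

Artifacts are detected with three amplitude rules applied per channel
and unioned: (a) a step of more than 50 µV between consecutive samples
marks ±100 ms; (b) a peak-to-peak range above 200 µV within any 200 ms
window marks the window; (c) a peak-to-peak range below 0.5 µV over any
100 ms window (flat, amplifier-disconnect-like data) marks the window
plus ±500 ms.  All windows slide with a one-sample stride.  Only the
scalp analysis channels participate in detection.

Data are cut into 1000 ms segments (500 samples at 500 Hz): event-locked
segments run from 100 ms before to 900 ms after stimulus onset; resting
segments are consecutive, non-overlapping, and start at the beginning of
the rest block (the overlap/offset policy was open; non-overlapping
windows keep segments statistically independent).  Any segment touching
the artifact mask is dropped.

## MVAR connectivity

Each segment is modelled as an order-10 multivariate autoregressive
process.  The estimator is a Vieira–Morf lattice (partial-correlation)
recursion.  At each stage the forward/backward prediction-error
covariances are recomputed empirically over the aligned sample range
with unbiased `1/(n − lag)` scaling; the normalised reflection
coefficient is then a true correlation matrix of whitened error
sequences, so its singular values cannot exceed one and the recursion is
numerically stable even at order 10 on 500-sample, 17-channel segments.
A guarded Cholesky adds minimal jitter in the rare near-singular case.
The lattice estimate is cross-checked in the tests against an
independent least-squares VAR fit (statsmodels) at large n.

From the coefficient polynomial `Ā(f) = I − Σ_k A_k e^(−i2πfk/fs)`, the
transfer function `H = Ā⁻¹` and spectral matrix `S = H Σ Hᴴ` are
evaluated on a 1 Hz grid from 2 to 125 Hz (124 points).  Implemented
measures: auto/cross spectrum, complex/real/imaginary coherence,
partial coherence (from the inverse spectral matrix, ridge-regularised
with a logged epsilon if singular), PDC / PDCF / gPDC
(column-normalised coefficient-polynomial family), DTF / ffDTF / dDTF
(row-normalised transfer-function family; ffDTF normalises over the full
frequency grid; dDTF multiplies ffDTF by the partial-coherence
magnitude), Geweke–Granger causality, and the raw transfer function and
coefficient polynomial.  "Direct causality" is ambiguous in the
historical literature; it is implemented as an alias of dDTF's
direct-influence convention and can be disabled.

Measures are averaged over the classical bands delta (2–4), theta
(5–7), alpha (8–13), beta (14–30), gamma (31–80) and high gamma
(81–125 Hz), as the arithmetic mean over the integer frequencies of the
closed band.  Complex-valued measures are reduced to magnitudes before
banding, except the explicitly complex coherence variant whose real and
imaginary parts are averaged separately; whether magnitudes were taken
before or after band averaging in the original workflow cannot be
resolved from its description, so the convention is fixed here and
documented.  One model is fitted per segment; no averaging across
segments precedes feature extraction, because each segment becomes one
classification sample.

Flattening keeps the nonredundant entries: upper triangle for symmetric
measures (including the diagonal only for the spectrum), all ordered
off-diagonal pairs for directed measures, (real, imaginary) pairs for
complex entries.  Identifiers are `measure:band:source->target` /
`measure:band:a<->b`, and a 17-channel montage yields 816 values per
symmetric measure and 1632 per directed measure.

## MRI region features

**Volumetry.** Each region's voxel volume is divided by the summed
volume of all segmented regions — global brain volume, deliberately not
total intracranial volume, because brain volume (unlike TIV) tracks
neurodegeneration.  Fractions sum to one.

**Orthogonal-plane 3D LBP.** For every voxel, an 8-bit local binary
pattern is computed in each of the three coordinate planes (radius 1,
8 neighbours, `>=` comparison, bit order E, NE, N, NW, W, SW, S, SE).
Per region, three 256-bin histograms accumulate over voxels whose
centre lies in the region mask and whose in-plane neighbourhood stays
inside the volume; each histogram is normalised to sum one and the
three are concatenated (768 values per region).  Plain LBP histograms
are used — no uniform-pattern reduction — and histogram normalisation
makes regions of different sizes comparable; both were open choices and
are flagged as such.  The implementation is verified against a naive
per-voxel double-loop oracle.

**Stationary-wavelet GGD texture.** An undecimated (stationary) 3D
wavelet transform with Haar filters is computed to 2 levels, keeping
all 8 low/high axis combinations per level (deeper levels decompose the
all-lowpass band); the family and depth were unspecified upstream and
are configurable.  Volumes are symmetrically padded to a multiple of
2^levels and the coefficients cropped back to the input grid.  For each
region × subband, a zero-mean generalized Gaussian density is fitted to
the masked coefficients (the all-approximation band is mean-centred per
region first), giving 16 × 2 = 32 parameters per region.

The GGD fit is by moment matching: with `m1 = mean|x|` and
`m2 = mean x²`, the shape β solves
`Γ(2/β)² / (Γ(1/β) Γ(3/β)) = m1²/m2` by monotone root finding on
β ∈ [0.05, 20] (log-gamma arithmetic for stability), and
`α = m1 Γ(1/β)/Γ(2/β)`.  A moment ratio outside the bracket (flatter
than uniform) clamps β to the boundary with a logged warning.  Regions
under 30 voxels are fitted but flagged unreliable.

## Neuropsychological scoring

Raw subscale scores are converted to z-scores against test-manual norms.
Scales where higher raw scores mean worse performance (error and miss
counts, reaction times, the Beck Depression Inventory) are sign-flipped
in one central table so that larger z is always better.  This makes the
decline rule uniform: a participant declines in a domain iff the
z-change between baseline and follow-up is ≤ −1 (at least one normative
SD) on at least one member subscale; improvements and sub-threshold
changes are "no decline", and a ≥ 1 SD BDI worsening triggers the
depression label through the same rule.  Thresholding the *change*
against the 1-SD criterion (rather than the baseline z) is the literal
reading of "decline of at least one standard deviation" and is the
fixed convention here.

Domains: executive functions (7 scales: two Wechsler subscales, four
verbal-fluency subscales, the attentional-flexibility summary),
visual-verbal memory (5: four verbal-memory subscales plus the
cerebral-damage-test summary), divided attention (3: the flexibility
summary, its error count, and the divided-attention summary — the
precise mapping of the "two summary scales" is ambiguous and the
configuration makes it explicit and editable), and depression (BDI).
Overlap between domains is allowed.  Baseline features are simply all
baseline subscale z-scores (`psy:<subscale>`).

## Prediction

With EEG present, every segment is one sample and the
participant-constant MRI/neuropsychology vectors are replicated onto
each of the participant's segments; without EEG, one row per
participant.  Columns are z-standardised with statistics from the
training split only.

The classifier is a linear 2-norm soft-margin SVM: squared-hinge loss
(slack penalised quadratically), dot-product kernel, cost C = 1 by
default, optional inverse-class-frequency weighting for imbalanced
designs.  Whether features were standardised upstream is unknown;
training-fold standardisation is assumed and documented.

Cross-validation is nested with three layers, every split grouped by
participant (all segments of one participant in one partition) and
stratified by label.  The outer layer holds out 20% of participants,
touched exactly once.  The middle layer is a 5-fold over the remaining
80%; each run performs greedy forward feature-subset selection and
records the chosen subset, yielding per-feature selection frequencies
(0..5) as a consistency measure.  The inner layer is the 5-fold inside
the selection: starting from the empty set, each step adds the feature
that maximises mean inner-fold balanced accuracy, stopping at a cap of
30 features or when the best improvement is ≤ 1e-4; ties break to the
lower column index, making selection deterministic.  The exact selection
algorithm was an open design point; greedy forward selection with
inner-CV balanced accuracy was chosen for determinism and because it
respects the 30-feature cap semantics.  How the five middle-run subsets
combine into one final model was also open: the implemented rule ranks
the union by selection frequency, truncates to the cap, and retrains on
the full 80% — preserving the frequency maps as the consistency readout.

Both segment-level and participant-level metrics are reported;
participant-level predictions are the majority vote over a participant's
segments (ties to the positive class, logged) and are the headline.  A
result is flagged reportable only when sensitivity and specificity both
reach 70%; below that benchmark an apparently good accuracy is treated
as the classifier being biased toward one class.

## Synthetic cohorts

The generator exists so the whole pipeline can run and be validated with
no external data.  Defaults mirror the emulated study conditions: five
diagnostic groups of 19/4/6/3/18 participants (MCI, subjective cognitive
complaints, right/left temporal lobe epilepsy, healthy controls), 17
channels at 500 Hz, 180 s of rest, 72 trials per task condition,
83-region label volumes, and per-domain decliner fractions of 0.54
(executive), 0.46 (memory), 0.49 (divided attention) and 0.15
(depression).  All randomness derives from one root seed through a fixed
`SeedSequence` spawning scheme (one child per modality, one grandchild
per participant in participant order), so cohorts are bit-identical
across runs.

EEG is realised from a stable MVAR process: each channel carries an
oscillatory AR(2) pole at 10 Hz with radius 0.7 and innovation SD 2 µV
plus 1 µV white observation noise — values chosen to give realistic
scalp amplitudes (≈ 5–20 µV) with a visible alpha peak; stability of
the companion matrix is checked and violations raise rather than
diverge silently.  Directed coupling edges add off-diagonal
coefficients at configurable lags.  Decliners carry a recoverable
signature: their designated coupling strengths are scaled, which shifts
the PDC of the planted ordered pair at all frequencies (the
coefficient-polynomial normalisation makes near-resonant bands
saturate, so discriminative power often appears in non-resonant bands).
Artifacts (steps, high-amplitude excursions, flat stretches) are
injected at known times for detector-recall tests.

MRI label volumes are ellipsoidal parcels on a jittered grid — parcels
never leave their grid cell, so packing is overlap-free by
construction; real atlas geometry is irrelevant to validating
mask-based feature math.  Intensities are per-region means plus
smoothed Gaussian texture; decliners' designated regions are shrunk
(radius scaling) and/or texture-scaled.  Neuropsych tables draw baseline
z-scores around group-level offsets; decliners receive a planted drop of
1.5 SD on one subscale that belongs exclusively to their domain (so
planted and computed labels agree exactly), and all other changes are
drawn strictly inside ±0.6 SD.

What the generator does **not** emulate: volume-conducted mixing and
realistic head-model topographies, 1/f background spectra and
non-stationarities, realistic brain anatomy or partial-volume effects,
correlations between baseline cognition and subsequent decline, and the
two-week reconsolidation effects of repeated testing.  Passing
recovery tests therefore demonstrate that the pipeline is correct and
leakage-free and can find planted multimodal signal — not that real
cohorts contain such signal.

## Problem sizes in the shipped experiments

The packaged recovery experiment and the reproduction script use a
scaled-down cohort chosen to exercise every stage while staying cheap:
2 × 8 participants, 6 EEG channels, 20 s of rest (20 segments each),
8-region volumes of 24×24×20 voxels, PDC + volumetry + baseline
neuropsychology (212 features), selection cap 10, and a 6-permutation
label-shuffle null.  Estimator calibrations run at n = 10⁵ samples.

## Known limitations

* The lattice estimator matches the cited estimator class
  (partial-correlation with unbiased covariance scaling) but the exact
  toolbox mode it emulates is not documented upstream; agreement is
  validated against closed-form spectra and an independent OLS fit
  rather than against that toolbox.
* EDF/BrainVision reading requires the optional `mne` dependency;
  cohort EEG exports use a `.npy` + JSON-sidecar container.
* The permutation null on small cohorts is coarse (few held-out
  participants), so "≈ 50%" is asserted as a band, not a point.
* With strongly unbalanced domains (depression at 15% decliners) the
  grouped stratified folds need enough minority participants; the fold
  count adapts downward and a warning is logged below 30% minority
  share.
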