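# Methods

## The measurement being modelled

Pulsed thermography applies a timed radiative heat pulse to a specimen lying
on a reflective stage and records its surface temperature with a thermal
camera. Materials differ in how much they heat under the lamp and how fast
they relax back to ambient — broad, thin botanical tissue (leaves, bract)
heats far more than dense seed coats, and loose cotton lint retains heat
longer than most contaminants. Pulse-phase thermography analyses the recorded
temperature signal in the frequency domain: the temporal Fourier transform of
each pixel (or of the specimen-mean trace) yields amplitude and phase values
per frequency component, which serve as classification features alongside two
scalar waveform gains.

The acquisition protocol is fixed throughout: 1 s front buffer at rest, 5 s
of lamp stimulation, 10 s of cooling, 1 s rear buffer, at 30 frames/s
(510 frames; 450 after trimming the buffers). Frame indices are 0-based with
half-open phase intervals, so the lamp-off frame is the first cooling frame.

## Synthetic-video generator

No thermal recordings ship with this package; a simulator generates videos
with the structure the analysis assumes.

**Thermal model.** Each specimen pixel follows a lumped-capacitance
(zero-dimensional Newtonian) heat balance:

    T(t) = T_amb + g (1 − e^{−t'/τ_h})      while the lamp is on,
    T(t) = T_amb + ΔT_peak e^{−t''/τ_c}     after lamp-off,

with equilibrium gain `g` (°C), heating and cooling time constants `τ_h`,
`τ_c` (s). The front buffer sits at ambient; the rear buffer continues the
cooling decay. This is deliberately not a heat-conduction PDE: the analysis
only consumes the specimen-mean trace and low-frequency spectral content, and
the exponential family reproduces the qualitative waveform differences
(different peaks, different cooling slopes) that drive the classification at
negligible cost.

**Spatial structure.** A geometry mask per class (broad ellipse for leaves
and bract, thin rotated ellipse for bark/stems/twine, disk for seeds and seed
coats and hulls, centred rectangle for paper and module cover, full window
for cotton lint) is placed near the stage centre with small positional
jitter. Per-pixel equilibrium gain is jittered (CV 0.05) to model spatial
inhomogeneity, and mask-boundary pixels cool faster than the interior
(cooling-rate multiplier 1.6 by default), which makes specimen edges visible
in phasegrams as they are in real pulse-phase imagery.

**Between-specimen variability.** Real specimens of one class differ in
mass, thickness and attitude, so their lumped parameters vary. Gain and both
time constants are drawn per specimen from lognormal distributions (CV 0.08
for most classes, 0.10 for the thermally overlapping bract/green-leaf/
brown-leaf triplet, 0.05 for the comparatively uniform cotton lint). Without
this term every specimen of a class would produce an essentially identical
mean trace and all classes would separate trivially; with it, the
identification task shows the expected confusion structure.

**Calibration.** Two anchors are fixed: brown leaves peak near 75 °C and
seed coats near 35 °C over a 25 °C ambient. Bract cools distinctly faster
than cotton. All other class parameters are free choices of this package —
interpolations chosen so that the peak-temperature ordering, the confusable
triplet, and a weakly separated bark/paper pair emerge — and must not be
read as measured material properties. The grey-body radiant-emission law
(`E = εσT⁴`) is provided as the radiometric layer but videos are expressed
directly in temperature units, as radiometric cameras export.

**Noise.** i.i.d. Gaussian per pixel per frame with sd 0.045 °C, the
noise-equivalent temperature difference of an uncooled microbolometer. No
fixed-pattern noise, vignetting or drift is modelled; background pixels sit
at the stage temperature plus noise only (the polished-steel stage reflects
the lamps rather than heating).

**Determinism.** Per-specimen RNG streams derive from
`SeedSequence(config.seed, spawn_key=(class_index, sample_index))`, so any
single video can be regenerated bit-identically regardless of generation
order.

**Problem sizes.** The default study replica is 12 classes × 20 specimens =
240 videos at 80 × 80 pixels — the spatial resolution is reduced from the
camera's 320 × 240 because the analysis operates on specimen-mean traces and
a coarser grid leaves every geometric and statistical property intact while
keeping a full replica generation near one minute; full resolution is a
config field.

**What passing tests do and do not show.** The generator shares the
analysis's own model family (exponential traces), so classification accuracy
on synthetic data demonstrates that the pipeline recovers separations that
exist in its feature space — not that real cotton contaminants are separable
at these rates. Convective-vs-radiative heating differences, emissivity
variation, specimen micro-geometry and camera artefacts are all outside the
simulation.

## Segmentation

Cotton fills the field of view and is cut to a centred square window (100 px
on the 240-px reference frame, scaled proportionally); paper specimens use a
centred rectangle well inside the specimen; every other class is segmented
by Otsu thresholding of the frame of peak temperature, with foreground =
above threshold. "Frame of peak temperature" is implemented as the frame of
maximal spatial mean, which is robust to isolated hot noisy pixels. The Otsu
threshold uses a 256-bin histogram spanning the frame's min–max range
(scikit-image's convention); a per-sample manual threshold override replaces
the original interactive adjustment. When the histogram has a near-empty gap
between modes, several thresholds tie in between-class variance to machine
precision; any maximiser is accepted.

## Features

* **Waveform:** rest, peak and final temperatures are single-frame reads at
  the lamp-on, lamp-off and cutoff frames of the untrimmed mean trace
  (an optional ±w-frame smoothing mean is available, default w = 0; for a
  zero-rear-buffer protocol the final read falls back to the last frame).
  Features are peak − rest and final − rest.
* **Spectral:** raw (unnormalised) DFT of the trimmed mean trace, whole or
  split into rising (150-frame) and falling (300-frame) portions. Retained
  component indices are `0 .. N/2 − 1`; the upper aliased half and the
  exact-Nyquist bin are discarded, and the identically-zero 0-Hz phase is
  dropped. This convention yields 225/224 (whole), 75/74 (rising) and
  150/149 (falling) amplitude/phase counts for the default protocol. Phases
  lie in (−π, π]. Amplitude normalisation is immaterial downstream (features
  are standardised per training fold) but is fixed for reproducibility.
  Odd-length traces are an error rather than a silent convention choice.
* **Phasegrams/ampligrams:** the same transform per pixel of a trimmed
  video at one retained component, NaN outside the mask.

Classification uses amplitude and waveform features only; phases are
extracted and stored but excluded from the default classifier inputs.

## Statistics

Pairwise class separation uses the two-sample Hotelling T² with pooled
covariance and the exact F transform — equivalent to two-group one-way
MANOVA but with a simpler contract. No multiple-testing correction is
applied across the 66 pairs; the working threshold is a raw p = 0.001.
Ledoit-Wolf-style shrinkage exists only as a fallback for singular pooled
covariance and is never used by default.

Canonical discriminant analysis solves the generalized eigenproblem of
between-class versus within-class scatter. Eigenvalues are reported on the
raw scatter-ratio scale (so they are ≈ 0 under the null); score vectors are
rescaled so the pooled within-class covariance of the scores is the
identity, and eigenvector signs are fixed (first non-zero loading positive)
for reproducible plots.

## Classification

LOOCV with per-fold standardisation. LDA is classical pooled-covariance
discriminant analysis (no shrinkage unless a fold's covariance is singular);
the SVM is a linear-kernel soft-margin machine with C = 1 and one-vs-one
multiclass reduction, since the original kernel and hyperparameters are
unspecified. The detection task collapses the labels to cotton versus
foreign matter; identification keeps all 12 classes. The amplitude-feature-
count sweep evaluates the k = 1..15 lowest-frequency amplitudes; the working
feature sets are the two waveform gains and the ten lowest-frequency
amplitudes of each spectral mode, giving the 4 × 2 × 2 accuracy grid.

## Numerical and degenerate-input choices

* Constant frames cannot be Otsu-thresholded (error; supply a manual
  threshold). Constant videos tie-break the peak frame to index 0.
* Container storage is little-endian float32 — the common radiometric
  export precision — and round trips are bit-exact by construction.
* Hotelling pairs whose pooled covariance is singular are recorded as NaN
  within the pairwise sweep rather than aborting it.
* All accuracies are reported as fractions rounded to 4 decimals.

## Known limitations

Single specimen per scene; no tracking, no multi-pulse protocols, no
thermographic signal reconstruction or lock-in analysis; no camera-count
radiometric rendering; simulated and analysed dynamics share the same model
family (see above). The bark/paper pair is calibrated to be only weakly
separated, so the pairwise amplitude test typically finds 65 of 66 pairs
significant at p = 0.001 on default-seed replicas.
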