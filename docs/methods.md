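# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `ecogpipe`.

## Signal model and preprocessing

Recordings are multi-channel cortical voltage traces (microvolts) with
per-contact metadata: patient, acquisition block (contacts recorded
simultaneously), an on-tumor flag, and the distance in mm from the
FLAIR-defined tumor border.  Compartment labels follow half-open, gap-free
distance bins: tumoral (flagged), close peritumoral (0, 15] mm, far
peritumoral (15, 30] mm, healthy (>30 mm).  The printed clinical convention
("<15", "16–30", ">31") leaves 15–16 and 30–31 mm undefined; the continuous
bins close those gaps and are the package's convention.

Filtering is a zero-phase (forward–backward) Chebyshev type II bandpass,
order 4 and 40 dB stopband attenuation per pass by default.  The default
passband is 0.1–250 Hz (capped at 0.45 × sampling rate): the analysis uses
band powers to 100 Hz and slopes to 200 Hz, so a 0.1–50 Hz preset, while
available in the configuration, would destroy most of the feature set and is
not the default.

A numerical point worth recording: at a 2 kHz rate a 0.1 Hz band edge places
filter poles within 2×10⁻⁴ of the unit circle.  Standard float64
`filtfilt`-style filtering then injects corner-frequency artifacts orders of
magnitude above the stopband floor (the per-section internal states reach
~10⁴–10⁵ and cancellation fails).  `ecogpipe` therefore runs the biquad
cascade in extended precision with even-reflection padding sized to the
lowest band edge (6 / low_hz seconds, capped at the signal length) and
steady-state initial conditions solved in extended precision.  Odd
(point-symmetric) padding is deliberately avoided: it adds a DC pedestal of
twice the endpoint value over the whole pad, which re-excites the slow corner
mode.  With these choices a stopband tone is attenuated below 10⁻² of its
input amplitude as designed, and the forward–backward symmetry holds to
~0.1% of signal RMS.

Resampling is polyphase (`scipy.signal.resample_poly`), never naive
decimation.  Artifact rejection is automatic: within each channel, 1 s
windows are dropped when the robust z-score of their peak amplitude (median
and MAD across the channel's windows) exceeds 6, or when the window variance
falls below 10⁻¹⁵ (flatline); channels retaining under 10 s are removed.
The clinical practice this mirrors was visual inspection; the thresholds are
package defaults, not published values.

## Spectral features

Welch PSD: Hann window of 2 s (n = 2 × sampling rate), 50% overlap, density
scaling (Σ PSD·Δf ≈ variance), averaged across artifact-free segments
weighted by segment length.  Mains bins at 50 Hz and all harmonics ±1 Hz
(half-width configurable; no published value) are masked before every power
summation.  Bands are half-open [low, high) to avoid double counting; "beta"
is 12–29 Hz in the power table (the conventional list runs alpha to 12 and
low gamma from 30) and 12–30 Hz in the connectivity table — both tables are
kept verbatim per stage rather than harmonized.  Relative power divides by
the total over all retained bins of the computed range (0.5 Hz–Nyquist); the
total's range is a package choice.

Per-patient normalization divides each feature column by that patient's
maximum of the column.  A per-feature maximum (rather than one global
maximum across features) keeps features commensurable; the global mode is
available as a configuration option.  Normalized aperiodic features are only
meaningful when the raw offsets are positive, which holds for physical
(µV²/Hz) scales; the synthetic generator therefore works on a microvolt
scale.

## Aperiodic parameterization

The background is knee-free: log₁₀ PSD(f) = b − χ·log₁₀ f.  The fitting
algorithm per channel and range: (1) robust line fit (OLS, then refit on the
bins below the 75th residual percentile, so oscillatory peaks do not tilt the
line); (2) iterative peak removal — locate the largest positive residual,
fit a Gaussian in log-power over linear frequency (FWHM bounded to 1–12 Hz,
capped at half the range width), subtract; stop at 6 peaks or when the
residual falls below 0.1 log₁₀ units; (3) final plain OLS on the
peak-subtracted spectrum; offset = intercept, exponent = −slope (reported as
a positive magnitude).  On a noiseless power law no peaks are detected and
the fit is exact to numerical precision; on simulated 1/f^χ noise (120 s at
2 kHz) the 1–200 Hz exponent is recovered within 0.01 on average.

Fits are produced over 1–200, 20–30, 20–40, 30–45, 40–60 and 60–120 Hz.
The feature block exposes 7 aperiodic columns: a single offset taken from the
widest (1–200 Hz) fit plus the six exponents — matching the 7-aperiodic
feature inventory (1 offset + 6 slopes).  Narrow-range slopes on real spectra
are deliberately *not* pure estimates of the generative χ: strong band
oscillations adjoining a range steepen or flatten its measured slope, which is
precisely why these ranges carry discriminative information.

## Connectivity

Per band: zero-phase Chebyshev-II bandpass, Hilbert analytic-signal phase,
1 s trimmed at each end against filter transients (no published choice), then
PLV between all pairs of channels sharing an acquisition block.  PLV is
computed over the full retained recording, not short epochs.  Compartment
summaries average distinct within-group pairs (diagonal blocks; groups with
fewer than two channels are reported missing) and all cross pairs
(off-diagonal blocks).  For independent phases the sample PLV has mean
√(π/4N) (Rayleigh), which the tests use as the null calibration.

## Statistics

Kruskal–Wallis (tie-corrected, χ² approximation, k−1 df; all-identical input
is defined as H = 0, p = 1).  Dunn's post hoc uses mean-rank differences with
the tie-corrected variance factor N(N+1)/12 − Σ(t³−t)/(12(N−1)) and two-sided
normal p-values; the adjustment method is Holm by default (Bonferroni
available) — the multiplicity method was a free choice and Holm is uniformly
more powerful at the same family-wise error.  Mann–Whitney is exact for
tie-free samples up to n = 20 per group, tie-corrected asymptotic otherwise.
Spearman uses average ranks and the t approximation for p.

Infiltration strata: healthy = 0 cells/250 µm², low = 1–49, high = ≥50.
A count of exactly 50 goes to "high" (the printed strata "<50" and ">50"
leave 50 unassigned).  Correlations are computed within each stratum and
reported missing below n = 4.  Electrode contacts are treated as independent
observations, as in contact-level clinical analyses; patient-level clustering
is a known limitation, not modelled.

## Classification

The electrode descriptor has exactly 38 columns: absolute and relative power
in six bands (12), offset plus six slopes (7), each in raw and per-patient
normalized form (19 × 2).  Rows with any missing feature are excluded with a
logged count (no imputation).

The split is stratified 70/30 with the train size = round(0.7·n) and
largest-remainder per-class allocation — a 708-row cohort yields 496/212.
Hyperparameters are chosen by stratified 5-fold cross-validation on mean
macro F1 with seeded, reproducible folds.  The kNN model is a random-subspace
ensemble: 30 learners, each a kNN on a random 19-of-38 feature subset,
combined by majority vote with a deterministic tie-break toward the lowest
class index; the neighbor count k is tuned over odd values 1–19.  The
published phrase "19-neighbor subspace" is ambiguous between subspace
dimension and neighbor count; this package reads it as dimension 19 (half the
feature space, the natural random-subspace choice) and tunes k.  The SVM uses
a cubic polynomial kernel with features standardized on training statistics
only (the scaler is part of the fitted pipeline, so test-set leakage is
impossible by construction); C is tuned over {0.1, 1, 10}.  Macro averaging
is used for summary precision/recall/F1 because the compartment classes are
imbalanced; no resampling or class weighting is applied by default.

The 2-class scheme is tumoral vs non-tumoral by default; a tumoral-vs-healthy
variant (dropping peritumoral rows) is available, as both collapsed schemes
appear in clinical practice.

## Synthetic cohort generator

Each channel is colored noise + band oscillations + line noise + a shared
within-compartment component:

- **Colored noise** by spectral shaping: random-phase Fourier coefficients
  with |X(f)|² ∝ 10^b·f^(−χ), inverse transformed — exact in expectation,
  deterministic per seed.
- **Band oscillations**: white noise bandpass-filtered to the target band and
  rescaled to the target RMS (stochastic, physiologically jittered; not pure
  sinusoids).
- **Line noise**: 50 Hz sinusoid (3 µV RMS) plus a half-amplitude 100 Hz
  harmonic, random phase per channel.
- **Coupling**: within a compartment with coupling c, background =
  √(1−c²)·private + c·shared, leaving the PSD invariant while setting
  within-group coherence (and hence PLV) monotonically by c.

Default compartment profiles (µV scale) encode the qualitative clinical
contrasts: tumoral — offset 3.0 (suppressed broadband), dominant delta
(40 µV RMS), weak fast oscillations, coupling 0.8; close/far peritumoral —
offset 3.5, exponent 2.3/2.25 (steeper slopes), strong beta (40/38 µV),
coupling 0.4/0.35; healthy — offset 3.5, exponent 2.0, moderate alpha/beta,
coupling 0.25.  These amplitudes were chosen once as physiologically
plausible values that produce the documented orderings (tumor relative delta
highest, peritumoral relative beta and 20–40 Hz slope highest, intratumoral
PLV highest); they are configuration, not estimates of any patient cohort.
Default contact counts are 121/243/212/134 (total 710, the reference cohort's
classifier inventory); counts are configuration because the clinical totals
are themselves inconsistent across analyses (708–718 contacts).

Sampling defaults are 2 kHz and 120 s (recordings of at least two minutes per
electrode position).  End-to-end demonstrations and the acceptance script use
a scaled-down cohort — 30 channels per compartment, 60 s at a 500 Hz analysis
rate — which preserves every analyzed frequency (Nyquist 250 Hz > 200 Hz)
while keeping a full run under a minute; exponent-recovery checks keep the
full 120 s at 2 kHz.

Infiltration counts are Poisson with log-rate = log(12) + β·z + ε, where z is
the standardized target feature and ε is N(0, 0.4²) noise; β is calibrated by
bisection against an internal Monte-Carlo estimate of the within-low-stratum
Spearman ρ, so a requested effect (e.g. ρ = −0.5 against absolute beta) is
recovered in expectation.  The baseline rate 12 makes most biopsies
low-infiltration, as in peritumoral security-margin sampling.

What the generator does **not** emulate: interictal discharges and seizures,
stimulation artifacts, anatomical geometry and volume conduction, non-1/f
spectral knees, inter-patient heterogeneity beyond independent channels, and
real class overlap.  Synthetic compartments are far better separated than
clinical ones — classifier scores near 1.0 on synthetic cohorts demonstrate
the pipeline's correctness, not clinical performance, and the tests are
phrased as orderings, calibrations and recovery errors for that reason.

## Reproducibility and degenerate inputs

All randomness flows from integer seeds through `numpy` `SeedSequence`
spawning; identical configurations reproduce recordings, splits, folds and
reports bit-for-bit (the pipeline writes a manifest with the configuration
and bookkeeping counts).  Degenerate inputs have defined behavior: zero
signals give zero spectra; constant channels have undefined phase and are
flagged; all-identical samples give H = 0, p = 1; zero per-patient maxima
normalize to 0 with a warning; strata or groups below minimum size are
reported missing rather than silently dropped.
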