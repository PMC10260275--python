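# Methods

This note documents the models, numerical choices and open design decisions
behind the package, and what the synthetic-data tests do and do not show
about real recordings.

## Preprocessing

Signals are filtered with Hamming-windowed sinc FIR kernels applied by
symmetric convolution with group-delay compensation (`mode="same"` on an
odd-length kernel), so every filter in the package is zero phase. The
kernel length follows the standard Hamming design rule (normalized
transition width ≈ 3.3/N). For the broadband filter the −6 dB cutoffs are
0.1 and 35.1 Hz with 0.2-Hz transitions, giving a nominal 0.2–35 Hz
passband; the spindle-band filter is fixed at order 2816 at 256 Hz (scaled
proportionally at other rates, forced even) to match the published setting.
Re-referencing subtracts the A1/A2 average from every non-mastoid channel;
the mastoids are left untouched so the operation is idempotent.

Epochs (30 s) are excluded when their stage is out of scope or when summed
artifact overlap exceeds 8 s (a longest-single-interval variant sits behind
`artifact_rule="single"`; the published rule does not say which reading was
used). Contact-impedance failures are hardware metadata not present in EDF,
so they enter as an optional per-epoch boolean flag (default all-pass).
The spindle-density denominator is included-epoch minutes *without*
subtracting sub-epoch artifact time — events inside artifact segments are
discarded instead — with an artifact-corrected denominator behind
`density_denominator="artifact_corrected"`. N2 and N3 are pooled for all
event detection.

## Spindle detection

Thresholds are channel-wise: the **mean rectified amplitude** of the
band-passed trace over artifact-free NREM samples, multiplied by 5
(detection) and 2 (extent). The rectified trace itself returns to zero
every half cycle (~36 ms at 14 Hz), so a literal "stay above the extent
threshold for 250 ms" test on it would never pass; event geometry is
therefore evaluated on the **instantaneous-amplitude envelope** (Hilbert
magnitude) of the band-passed trace, while the threshold mean stays on the
rectified trace (a Hilbert-envelope mean sits behind
`spindle_amplitude="envelope"`; for a sinusoid the two differ by π/2).

An event is a maximal run of envelope ≥ lower threshold that contains a
sample ≥ upper threshold at least 0.25 s from both run edges (this is the
bilateral 250-ms flank rule and yields the 0.5-s minimum duration; using
"some above-upper sample" rather than "the argmax sample" makes the rule
deterministic for flat-topped bursts whose maximum location is otherwise
set by sampling jitter). Candidates separated by a sub-lower gap shorter
than 78.1 ms (20 samples at 256 Hz, about one period at 13 Hz) are merged,
the later candidate absorbed into the earlier one and the peak taken as the
larger maximum. Events longer than 3.0 s or with rectified peak amplitude
above 200 μV are rejected; events touching excluded epochs or artifact
sub-intervals are dropped entirely (strictest reading). Plateau ties in
peak location resolve to the first sample.

## Slow oscillations and coupling

SO detection is two-pass on the 3.5-Hz low-passed trace: candidate cycles
are consecutive positive-to-negative zero-crossing intervals of duration
0.8–5 s inside included NREM; cycles within half a kernel length of the
signal edges are discarded (filter transient). Selection keeps cycles whose
trough is strictly below the candidate-mean trough *and* whose peak-to-peak
amplitude strictly exceeds the candidate-mean peak-to-peak; a relative
tolerance of 1e-9 on the strict inequalities prevents numerically identical
cycles from passing. Candidate means are per channel per night, computed
after the duration gate. Cycles whose extremum falls on a boundary sample
are discarded as noise-dominated.

Coupling phase uses the analytic-signal (cosine) convention on the
0.2–1.25 Hz band-passed trace: 0 rad at the SO positive peak, +π/2 at the
falling zero-crossing, ±π at the trough, increasing through the cycle. A
spindle is paired with the unique SO cycle containing its amplitude peak
(cycles are disjoint by construction); the coupling distance is |phase|.
Channel summaries use the arithmetic mean of distances over events (no
per-epoch weighting), the circular mean phase, and the classic Rayleigh
approximation p = exp(√(1+4n+4(n²−R²)) − (1+2n)).

A property worth knowing: pairing is gated on the spindle peak lying inside
the cycle span, so when spindles lock exactly at the cycle-edge phase
(+π/2 at the boundary zero-crossing), peak-time jitter censors events
asymmetrically and biases the recovered mean phase; at phases near the SO
peak — where real frontal/central coupling concentrates — the effect is
negligible. The same censoring means that under uniformly distributed
coupling phases the detected-pair phase distribution is slightly depleted
near +π/2, so the Rayleigh p of a κ = 0 cohort is stochastically somewhat
smaller than uniform (occasionally crossing 0.05 even though the injected
phases are exactly uniform).

## REM spectra

Per-epoch Welch estimates (1024-sample Hamming segments, 50% overlap,
`detrend=False`) in dB of μV²/Hz; a linear-power mode sits behind
`psd_scale="linear"`. Band means average bins whose center lies in
[low, high). Epochs shorter than 1024 samples are skipped with a log entry.
Standardization z-scores the two theta cells against all 12 channel×band
cells using the sample SD (ddof = 1; the published analysis does not state
which); the choice affects both theta z-scores by a common factor, which
partially cancels in the lateralization ratio. `rem_theta` is the mean of
the two theta z-scores. Because `theta_lat` divides by the mean of two
z-scores, which can be near zero, the lateralization guard (below) applies.

## Memory scoring

Hits are targets called old (recollected or familiar); recollection-only
mode counts only "recollected". d' = z(hit) − z(fa) with extreme rates
replaced by 1/(2n) (n = 25 trials per cell; perfect cells are likely at
this size, so a rule is mandatory — the log-linear +0.5 correction sits
behind `correction="loglinear"`). Button codes 1/2/0 map to
recollected/familiar/new at ingest. Difference scores are exact cell
arithmetic and propagate missing cells as NaN.

## Statistics

The two-way repeated-measures ANOVA is a direct sums-of-squares
decomposition (each within effect tested against its effect×subject
interaction), no sphericity correction (plain degrees of freedom are
reported, matching the reporting convention of the analysis this mirrors);
it is cross-checked in the tests against pingouin and a brute-force oracle.
Partial eta² = SS_effect/(SS_effect+SS_error).

The repeated-measures ANCOVA uses the univariate within-subject approach:
the 6 d' cells are projected onto orthonormal Helmert contrasts (mean, time,
emotion, time×emotion); each contrast column is regressed on
[intercept, mean-centered covariate, mean-centered dummy-coded controls],
and the covariate's extra (type-III) sums of squares are pooled across
columns, F = (ΣSS_hyp/q)/(ΣSS_err/(q(n−p))). For single-df effects this
equals the squared t of the corresponding contrast regression (asserted in
tests). The covariate is mean-centered; SPSS-style GLMs may bookkeep the
three-way interaction differently for uncentered covariates. Missing
numeric controls are mean-imputed (matching the handling of missing
questionnaire scores); BDI/GAD-7 enter as ln(x+1) since both scales start
at 0. Handedness, with several missing values, is treated as an imputed
distinct category and used only in sensitivity reruns. Bonferroni
correction is applied only to the pairwise post-hocs; covariate models are
reported unadjusted.

Follow-up regressions are ordinary least squares of a difference score on
the predictor plus the same controls, optionally also the matching
difference score from the previous retrieval.

## Synthetic data

The generator emulates the study conditions: 32 subjects; stage fractions
N1 5.7%, N2 36.3%, N3 24.0%, REM 18.4%; 256 Hz; frontal fast-spindle rate
3.3/min; SO rate 5/min at 75 μV and 0.6–0.9 Hz; mean coupling distance
0.95 rad with phase-locking concentration κ = 5 and 70% of spindles
coupled (tight locking keeps the per-subject mean phase estimable from the
few dozen pairs a scaled-down night yields, consistent with the strong
clustering of frontal SO-spindles near the SO peak); REM theta at 20 μV
with per-subject hemispheric asymmetry; memory d' declining from ≈2.6
(immediate) to ≈1.9 (24 h) with a 0.35 criterion shift for emotional foils
at 24 h, reproducing the emotional false-alarm inflation; subject ability
SD 0.4; and effect wiring from the true coupling lateralization to the
neutral−emotional d' gap (weight −1.5, the sign meaning that a
right-lateralized, i.e. larger right-hemisphere, coupling distance
accompanies a smaller neutral benefit).

Background EEG is Gaussian 1/f noise (RMS 15 μV). Spindles are
Hann-windowed 13–16 Hz bursts of 0.8–1.5 s whose peak amplitude is
parameterized in units of the background's rectified band-passed mean
(default 16×, i.e. comfortably above the 5× detection threshold even after
the injections themselves raise the channel mean), so injection strength is
expressed in units of the detector's own threshold. A Hann (not
flat-topped) window gives each burst a unique central maximum, so detected
peak times are stable. SOs are single −sin cycles; phase-locked spindles
are placed on the Hilbert-phase map of the band-pass-filtered SO template
(band-passing shifts an isolated cycle's positive peak, so placement on the
raw template would bias the injected phase by up to ~0.3 rad). κ = 0
produces the uniform null for Rayleigh calibration. A vectorized
score-level path (binomial counts from the same equal-variance
signal-detection model) serves the 500-seed calibration studies;
distributional equivalence with the item-level path is tested.

**What the generator does not emulate:** real EEG nonstationarity, sleep
micro-architecture (arousals, cycling within stages), spatially correlated
noise across channels, slow spindles, K-complexes, realistic artifact
morphology, or item-level memory effects (valence/arousal gradations,
serial-position effects). Passing injection-recovery tests therefore shows
the detectors implement their rules correctly at realistic SNR — not that
they would achieve the same recall on clinical recordings.

## Problem sizes

The default simulation is the reduced-night mode: 40 epochs (20 min, of
which ≈12.5 min NREM and ≈3.5 min REM); `SimulationSpec.full_night()` gives
960 epochs. The calibration study uses 500 score-level cohorts of n = 32;
the end-to-end recovery study uses 10 EEG cohorts of 32 reduced nights.
These sizes were chosen so the whole test battery runs comfortably on a
single CPU while keeping every estimate's Monte-Carlo error well inside the
asserted bounds.

## Numerical details and degenerate inputs

* Lateralization indices guard against near-zero denominators
  (|mean| < 1e-6 → missing value with a log entry, never ±inf).
* Empty pair lists produce a missing coupling summary (None), not zeros.
* dB spectra floor at 1e-20 μV²/Hz before log.
* The EDF writer scales each channel to its symmetric extremum over ±32767
  digital units, so round-trip error is bounded by one quantization step.
* Collinear ANCOVA designs (condition number > 1e8) and rank-deficient
  follow-up designs raise diagnostics errors rather than returning numbers.
* Constant band-power tables and empty NREM masks raise; they indicate
  degenerate inputs.

## Known limitations

* The ANCOVA engine covers the fully-within 3×2 design with one continuous
  covariate; it is not a general mixed-model framework.
* No Greenhouse–Geisser correction by default; plain dfs are reported.
  `sphericity="gg"` applies the epsilon-adjusted p (cross-checked against
  pingouin in the tests).
* The coupling analysis reports distance, mean phase and Rayleigh p only —
  no modulation-index or event-locked time–frequency measures.
* Median-split subgroup ANCOVAs and recollection-based supplementary
  analyses beyond the scoring mode switch are out of scope.
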