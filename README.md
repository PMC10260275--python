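# spindlelat

Overnight sleep-oscillation lateralization and emotional recognition-memory
analysis: a tested Python pipeline for studying how the hemispheric
asymmetry of NREM and REM sleep oscillations relates to the recognition of
neutral versus emotional pictures.

## Who this is for

Sleep/memory researchers with standard overnight polysomnography (six EEG
channels: F3, F4, C3, C4 and the mastoids A1, A2, sampled at 256 Hz), a
manually scored 30-s hypnogram, artifact annotations, and a three-retrieval
recognition task (immediate / 12 h / 24 h) in which items are judged
*recollected*, *familiar* or *new*. Because no participant data of this kind
are publicly redistributable, the package ships a first-class synthetic-data
generator that emulates every input with known ground truth, so each stage
of the pipeline is testable end to end.

## What it computes

**Fast sleep spindles (13–16 Hz).** The preprocessed signal (0.2–35 Hz
zero-phase FIR, linked-mastoid reference) is band-pass filtered (order 2816
at 256 Hz) and thresholded channel-wise: detection threshold 5× and extent
threshold 2× the mean rectified amplitude over artifact-free NREM (N2+N3).
Events must keep the amplitude above the extent threshold for 250 ms on both
sides of the peak (minimum duration 0.5 s), last at most 3.0 s, peak below
200 μV, and be separated by sub-threshold gaps of at least 78.1 ms
(candidates closer than that are merged). Spindle density is events/minute
of included NREM.

**Slow oscillations and SO–spindle coupling.** SO cycles are intervals
between consecutive positive-to-negative zero-crossings of the 3.5-Hz
low-passed trace with durations 0.8–5 s (0.2–1.25 Hz); cycles whose trough
is below the candidate mean trough and whose peak-to-peak amplitude exceeds
the candidate mean are kept. Spindles peaking inside an SO cycle are paired
with it, and the coupling phase is read from the Hilbert transform of the
0.2–1.25 Hz signal at the spindle peak (0 rad = SO positive peak). The
*coupling distance* is |phase|; per-channel summaries report the mean
distance, circular mean phase and a Rayleigh non-uniformity test.

**REM theta.** Welch power spectra (1024-sample Hamming segments, 50%
overlap, dB) per 30-s REM epoch in F3/F4 are averaged into six bands (delta
… beta2); the 12 channel×band cells are z-standardized and the two theta
z-scores averaged into `rem_theta`.

**Lateralization indices.** For each metric X,

    X_lat = (X_right − X_left) / ((X_right + X_left) / 2),

positive when right-dominant (frontal pair F4 vs F3).

**Memory scoring.** Per subject × retrieval × emotion,

    d' = z(hit rate) − z(false-alarm rate),

with hits = targets called old (recollected or familiar; recollection-only
mode available) and extreme rates replaced by 1/(2n). Difference scores
(immediate−12h, 12h−24h; neutral−emotional) feed the follow-up regressions.

**Statistics.** A two-way repeated-measures ANOVA (time × emotion) on d';
repeated-measures ANCOVAs entering each oscillatory/lateralization variable
as a continuous covariate while controlling sex, measurement location and
sleep duration (Model 1; plus ln-transformed BDI and GAD-7 in Model 2);
Bonferroni-corrected pairwise post-hocs; OLS follow-up regressions on
difference scores; and preliminary confounder screens (group ANOVAs,
Pearson correlations, chi-squared, |z| > 3 outlier flags).

## Worked example

```python
import numpy as np
from spindlelat import (SimulationSpec, simulate_night, analyze_night)

spec = SimulationSpec()                      # 20-min reduced night, 256 Hz
rec, hyp, art, truth = simulate_night(spec, subject_seed=42)
res = analyze_night(rec, hyp, art, subject="s00")

print(f"NREM minutes:            {res.nrem_minutes:.1f}")
print(f"frontal spindle density: {res.summary.spindle_density_frontal:.2f} /min")
print(f"frontal coupling dist.:  {res.summary.coupling_distance_frontal:.2f} rad")
print(f"spindle_lat:             {res.summary.spindle_lat:+.3f}"
      f"   (true {truth.spindle_lat:+.3f})")
```

prints, with this seed:

```
NREM minutes:            12.5
frontal spindle density: 2.92 /min
frontal coupling dist.:  0.94 rad
spindle_lat:             +0.137   (true +0.046)
```

i.e. ~3 detected fast spindles per NREM minute on the frontal pair and a
mean coupling distance of ~0.94 rad from the SO positive peak — both inside
the ranges reported for healthy young adults — with a right-leaning spindle
lateralization estimate of the injected ground truth (single reduced nights
estimate the index noisily; the cohort-level tests quantify this).

The same analysis is available from the shell:

```
spindlelat simulate --seed 1 --subjects 4 --out data/
spindlelat detect --edf data/s00.edf --hypnogram data/s00_hypnogram.txt \
    --artifacts data/s00_artifacts.tsv --out out/s00/
spindlelat score --responses data/responses.csv --out out/
spindlelat stats --summaries summaries.csv --scores out/scores.csv --out out/
```

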