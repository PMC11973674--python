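# Methods

This note documents the models, parameter choices and numerical decisions
behind `coiegm`, and what the synthetic validation does and does not
establish about real recordings.

## Signal model of the synthetic generator

Each simulated lesion recording holds three synchronous 1-kHz channels in
mV around one ablation delivery (default 30 s pre + 600 s post). Beats
occur at a fixed heart rate (default 80 bpm) with ±3% uniform RR jitter,
so the QRS detector is exercised against physiological variability.

Per heartbeat:

* **ECG** — a Mexican-hat QRS complex (1.0 mV, ~60 ms span), a small
  Gaussian T wave (0.25 mV, σ = 40 ms, 280 ms after R) and a small P wave
  (0.08 mV, σ = 12 ms) at the atrial time.
* **Bipolar iEGM** — a derivative-of-Gaussian biphasic spike (1.5 mV,
  4 ms nominal width) at the atrial time, 120 ms before the R peak. The
  narrow width puts ≥95% of its energy above 63 Hz (verified by FFT).
* **Unipolar iEGM** — a wider biphasic deflection (0.2 mV, 30 ms) plus a
  raised-cosine COI plateau (1.5 mV, 100 ms) starting at the end of the
  deflection. ~84% of the plateau's energy lies in 1–16 Hz. The
  deflection amplitude is deliberately small relative to the plateau so
  that the LF band tracks the COI level: the deflection's LF leakage is
  an additive term that does not scale with injury and would otherwise
  bias normalized dynamics.

White Gaussian amplifier noise (default 0.02 mV SD) is added per channel;
channels clip at a ±10 mV rail. For PFA (only), the unipolar channel is
clamped at the rail from ablation to +30 s, reproducing amplifier
saturation; the bipolar channel is unaffected.

### Ablation dynamics

Two closed-form trajectories scale the per-beat templates:

* **HF survival** (bipolar spike): 1 before ablation, then
  `plateau − (plateau − drop)·exp(−t/τ)`.
* **COI level** (unipolar plateau): `baseline` before ablation, then
  `floor + (jump − floor)·exp(−(t−30)/τ)` from the first valid reading at
  30 s. The level is undefined during the saturation window in the public
  API; internally the generator holds it at `jump` there (continuous at
  30 s), and on PFA records those samples are overwritten by the rail.

Group defaults (dimensionless multiples of the pre-ablation amplitude):

| group    | COI jump | COI floor | COI τ (s) | HF drop | HF plateau | HF τ (s) |
|----------|---------:|----------:|----------:|--------:|-----------:|---------:|
| PFA T+   | 1.73     | 0.7       | 150       | 0.2     | 0.2        | 70       |
| PFA T−   | 1.73     | 0.5       | 45        | 0.2     | 0.6        | 70       |
| RFA T+   | 1.0      | 0.8       | 100       | 0.2     | 0.2        | 70       |
| RFA T−   | 1.0      | 0.8       | 100       | 0.6     | 0.6        | 70       |
| SHAM     | 1.0      | 1.0       | —         | 1.0     | 1.0        | —        |

These encode the qualitative study conditions: a ~73% initial COI
increase after PFA with faster, deeper recovery for nontransmural
lesions; no initial COI increase after RFA; an immediate bipolar drop to
~20% with recovery toward ~60% only for nontransmural PFA; a shallower
drop (to ~60%) for nontransmural RFA; identity dynamics for sham catheter
placement. End-of-observation COI below baseline reflects the dissipating
contact-injury COI present before ablation.

Cohorts default to 38 lesions (21 PFA / 17 RFA) over 5 animals, assigned
round-robin. The transmural splits (PFA 15/6, RFA 8/9) follow the
dose-titration outcome of the study the defaults emulate. Each animal
receives one multiplicative log-normal amplitude factor (SD 0.2 on the
log scale) applied to the deterministic signal content — a true random
intercept for the mixed-effects machinery. Optional movement/contact
artifacts add 300-ms low-frequency transients of 12 mV (clipping at the
rail, as real artifacts typically do) to a deterministic fraction of
beats, with ground-truth indices.

## QRS detection

The ECG is high-pass filtered at 10 Hz (4th-order Butterworth, zero-phase
`sosfiltfilt`) and the first 50 samples are zeroed so a record starting
mid-QRS cannot poison the initialization. The detector thresholds the
5-point weighted slope `s(n) = −2x(n−2) − x(n−1) + x(n+1) + 2x(n+2)`;
each crossing opens a 100-ms search window whose maximum absolute
filtered amplitude is the R peak (earliest sample on ties), followed by a
200-ms refractory period. The threshold is `4/16` of a running statistic
of the last 8 per-beat maximum slopes, seeded from the first 2 s.

Two robustness choices matter at 1 kHz:

* the slope signal is smoothed with a centered 8-ms moving average —
  the raw operator spans only 4 ms and amplifies wideband noise enough
  that, on low-gain channels, noise alone can cross the threshold;
* the running statistic is a **median**, not a mean — an isolated false
  detection (e.g. on a P wave riding a noise excursion) contributes a
  small per-beat maximum slope which would drag a mean down and cascade
  into systematic double-detection; the median is unaffected by isolated
  outliers.

Both are exposed in `QRSDetectorParams`. On cohorts with default noise
the detector achieves sensitivity = PPV = 1.0 at 50-ms tolerance.

## Segmentation and exclusion

Windows, segments and rules use 0-based, half-open sample intervals; a
beat exactly on a segment boundary belongs to the later segment. The
10-s grid is anchored with one boundary at the ablation instant, so
segment centers sit at …, −15, −5, +5, +15, … s; partial segments at the
record edges are kept but only complete pre-ablation segments qualify as
baseline, and at least 20 s of pre-ablation recording is required.

A beat is contaminated on a channel when its window touches the ±10 mV
rail, exceeds 8× a centered 21-beat running median of per-beat
peak-to-peak, or overlaps a declared saturation interval (unipolar only).
Contamination is tracked **per channel**: post-PFA saturation invalidates
unipolar readings in [0, 30) s without touching the bipolar analysis,
which starts immediately after ablation. A segment is excluded on a
channel when strictly more than 20% of its beats are contaminated there
(exactly 20% is retained — the literal reading of the exclusion rule) or
when it holds no beats. Excluded segments appear as gaps, never zeros,
and are not interpolated.

## Wavelet multiresolution analysis

The decimated Daubechies-6 DWT (`pywt.wavedec`, symmetric half-sample
extension) is taken to 9 levels per segment slice; reconstructing each
level with all other coefficients zeroed yields an additive MRA whose
components sum back to the input (relative L2 error ~1e−16, asserted at
≤1e−8 for arbitrary lengths). Nominal dyadic bands are
`(fs/2^(k+1), fs/2^k)`; at 1 kHz the HF preset {1,2,3} spans 62.5–500 Hz
and the LF preset {6,7,8,9} spans ~0.98–15.6 Hz, matching the 63–500 Hz
and 1–16 Hz analysis ranges. The final approximation (<~1 Hz) is
excluded from the LF preset because the LF range starts at 1 Hz. Band
selectivity: a 100-Hz tone keeps ≥90% of its energy in the HF preset, an
8-Hz tone ≥90% in the LF preset, and a 40-Hz tone <50% in either.

Segments are decomposed individually (10-s blocks); the slice is extended
250 ms to the left so the atrial window of a beat near the segment start
remains inside the decomposed span.

## Features and normalization

The per-segment value is the median across usable beats of the
peak-to-peak amplitude inside the 150-ms atrial window, computed on the
band-reconstructed signal (or the raw channel for the `*_raw` series).
The median makes the value robust to sub-threshold corruption of a
minority of beats.

Two normalization conventions: `preablation` divides by a pre-ablation
segment value, and `post30s` divides by the first valid post-ablation
value. Where the baseline reference was ambiguous in the source material
("first" vs "last" pre-ablation value), the default is the **last**
pre-ablation segment — closest to treatment — with "first" available via
configuration. Normalized series are exactly 1 at the reference time and
invariant under channel gain changes; a missing or non-positive reference
raises rather than silently producing unusable values.

On noise-free synthetic lesions the full pipeline recovers the generating
trajectories (normalized HF vs HF survival; normalized LF vs the COI
ratio referenced at the first valid segment center) within 10% relative
error at every valid segment center — measured maximum ~6%, the residue
coming from trajectory curvature within 10-s segments and wavelet edge
effects.

## Statistics

`fit_lme` fits `value ~ t_rel_s * C(group)` with a per-animal random
intercept via statsmodels `MixedLM` under REML, over a configurable
window defaulting to 30–180 s post-ablation, with time continuous in
seconds (the scientific question is a slope difference). Significance of
the `time` and `time × group` fixed effects is reported from 1-df Wald
chi-square tests — equivalent in df to the ANOVA on those terms for a
two-level group factor. Singular or non-converged fits are returned
flagged, never silently dropped; on normalized synthetic cohorts the
random-intercept variance is legitimately ~0 because normalization
cancels the multiplicative animal gain by construction.

Calibration, measured by simulation on the long-table generator
(`simulate_long_table`, which carries a genuine per-animal intercept):
type-I error of the interaction test is 4.5% over 200 null replicates
(5 animals, 8+8 lesions, 15 timepoints); power exceeds 80% when the
slope difference accumulates 3 residual SDs over the analysis window;
the mean REML variance estimate over 50 seeds at cohort scale falls
within 50% of the generating animal variance.

Per-timepoint comparisons follow the gated branch: Shapiro-Wilk on each
group and median-centered Levene at α = 0.05; t test (pooled variance)
only when both normality checks and the variance check pass, Mann-Whitney
otherwise, with the branch reported. P-values are raw — no
multiple-testing correction across timepoints, deliberately mirroring the
reporting convention of the analysis this package operationalizes.
Recovery slopes are OLS fits over valid points in the window.

## Transmurality classifier

The score is the `post30s`-normalized unipolar LF value at the valid
timepoint nearest the 60-s decision time (±10 s; equidistant points
resolve to the earlier one); a recovery-slope score is available as an
option. The rule — nontransmural when the score falls strictly below a
threshold; a tie keeps the lesion-retaining transmural call — is
monotone in the score. Thresholds are calibrated by maximizing Youden's J
over midpoints of adjacent distinct training scores; tied optima resolve
to their midpoint, and indistinguishable score distributions (best J ≤ 0)
fall back to the pooled median. RFA and sham inputs are refused: the
source evidence shows no unipolar LF discrimination after RFA, and sham
has no ablation event.

This module deliberately extrapolates beyond group-level significance to
a per-lesion decision rule; any threshold is synthetic-data-calibrated
and carries no clinical validity.

## Problem sizes used in validation

The default test run simulates 21-lesion PFA cohorts with 90-s follow-up
for the statistics and classifier checks, full 630-s noise-free records
for trajectory recovery, twenty 60-s records for detector accuracy, and
200/100 replicate long-table simulations for type-I/power calibration.
The acceptance script simulates the full default cohort (38 lesions,
630-s records). All sizes are package choices balancing statistical
resolution against convenience; every check passes identically at larger
sizes.

## What the synthetic validation does not show

The generator reproduces the *phenomenology* of post-ablation iEGMs with
clean exponential dynamics, stationary beat morphology, white noise and
a single lesion per recording site. It does not model biophysics
(electroporation, thermal injury, wavefront propagation), far-field
ventricular contamination of iEGM channels, catheter micro-dislodgement
drift, arrhythmic beats, or the between-site variability of real contact
injury. Passing tests therefore establish correctness of the pipeline's
mechanics and its behavior under the stated signal model — not clinical
performance on porcine or human recordings. The classifier threshold in
particular must be re-calibrated on real data before any claim of
predictive value.
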