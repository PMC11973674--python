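# coiegm

Quantitative analysis of intracardiac electrograms (iEGMs) after cardiac
ablation, built around the **current of injury (COI)**: the slow baseline
shift that injured myocardium imprints on unipolar electrograms. After
pulsed field ablation (PFA) the COI rises sharply and then recovers over
minutes — and the *rate* of that recovery differs between lesions that end
up transmural and those that do not. This package turns that observation
into a reproducible signal-processing and statistics pipeline, aimed at
cardiac-electrophysiology researchers exploring intraprocedural lesion
assessment.

## What it computes

Given synchronous 1-kHz recordings of a surface ECG lead, a bipolar iEGM
and a unipolar iEGM around an ablation at time 0:

1. **QRS gating** — R peaks are detected on the ECG with a slope-threshold
   (So-Chan-style) detector after a zero-phase 10-Hz high-pass; the atrial
   analysis interval of each heartbeat is the 150-ms window
   `[R − 200 ms, R − 50 ms)`.
2. **Segmentation** — the record is tiled into non-overlapping 10-s
   segments anchored at the ablation instant. Segments with strictly more
   than 20% contaminated beats (rail clipping, amplitude outliers,
   amplifier saturation) are excluded; unipolar values are invalid until
   30 s post-ablation because PFA transiently saturates the unipolar
   amplifier.
3. **Wavelet sub-bands** — each segment is decomposed with a Daubechies-6
   DWT into an additive multiresolution analysis. Detail levels 1–3
   jointly span the 63–500 Hz high-frequency (HF) band that carries the
   sharp bipolar depolarization component; levels 6–9 span the ~1–16 Hz
   low-frequency (LF) band that carries the COI.
4. **Features** — per segment, the median over beats of the peak-to-peak
   amplitude inside the atrial window, for `bipolar_HF` (normalized to the
   pre-ablation value) and `unipolar_LF` (normalized to the first valid
   post-ablation value at +30 s).
5. **Statistics** — a linear mixed-effects model
   `value ~ time + group + time:group` with a per-animal random intercept
   (REML) over 30 s – 3 min post-ablation, Wald tests on the time and
   time×group effects, and gated per-timepoint comparisons (t test when
   both groups pass Shapiro-Wilk and median-centered Levene checks,
   Mann-Whitney otherwise).
6. **Transmurality call** — for PFA lesions only, the normalized LF value
   at 60 s is compared against a Youden-J-calibrated threshold: faster COI
   recovery (lower score) ⇒ nontransmural.

Because the underlying animal recordings are not publicly deposited, the
package ships a first-class synthetic generator (`coiegm.synthetic`) that
emulates the recorded phenomenology — atrial deflections, post-ablation
loss of the bipolar spike, modality- and transmurality-dependent COI
recovery, amplifier saturation, movement artifacts, per-animal amplitude
factors — with exact ground truth for every stage.

## Worked example

```python
from coiegm import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=7,
    cohort={"n_pfa": 12, "n_rfa": 0, "rfa_transmural": 0,
            "pfa_transmural": 7, "duration_post_s": 180.0},
)
result = run_pipeline(config)

comp = result.results["comparisons"]["pfa_transmurality_unipolar_LF"]
print("time-by-group interaction p:", f'{comp["lme"]["anova_pvalues"]["time_by_group"]:.2e}')
print("median LF recovery slope (1/s):",
      {g: round(s, 5) for g, s in comp["median_slope_per_s"].items()})
test_60s = min(comp["per_timepoint"], key=lambda r: abs(r["t_rel_s"] - 60.0))
print(f'{test_60s["test"]} test near 60 s: p = {test_60s["pvalue"]:.2e}')
cls = result.results["classifier"]
print("calibrated threshold:", round(cls["threshold"], 3),
      "| held-out balanced accuracy:", cls["balanced_accuracy"])
```

prints

```
time-by-group interaction p: 1.16e-19
median LF recovery slope (1/s): {'T+': -0.0025, 'T-': -0.00409}
t test near 60 s: p = 2.34e-11
calibrated threshold: 0.84 | held-out balanced accuracy: 1.0
```

Reading: the COI of simulated nontransmural (T−) lesions recovers ~1.6×
faster than transmural (T+) ones; the slope difference over 30 s – 3 min
is overwhelmingly significant; the two groups already separate at the
60-s timepoint; and a threshold on the 60-s normalized LF value
calibrated on half the lesions classifies the held-out half perfectly.

A command-line interface mirrors the stages
(`coiegm simulate | detect-qrs | segment | decompose | features | stats |
classify | run-all`); run `coiegm --help`.

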