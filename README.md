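# cwtcardio

Beat detection and stress analysis for wearable physiological streams:
single-lead ECG from a chest-strap pulsimeter (250 Hz) and skin-conductance
response (SCR) from a voltage-divider sensor (4 Hz).  Written for
biomedical-signal work where the recordings come from consumer-grade
wearables rather than clinical monitors: QRS detection that survives
baseline wander and amplitude changes, simple printed-rule anomaly flags a
clinician can audit, and per-subject stress classifiers.

What it does:

* **R-peak detection** by continuous wavelet transform (Coiflet-5),
  `C(a,b) = a^{-1/2} ∫ x(t) ψ*((t−b)/a) dt`, squared into a detection
  series and thresholded in normalized 5 s windows — peaks above 60 % of
  the per-window reference are R waves, peaks between 30 % and 60 % are
  provisional extrasystoles.
* **Anomaly rules** on the beat times `t(i)`: a premature beat satisfies
  `(t(i)−t(i−1))·2.2 < t(i+1)−t(i)`; an arrhythmic interval satisfies
  `RR(i) ≥ 1.3·RR(i−1)` or `1.3·RR(i) ≤ RR(i−1)`.
* **Heart-rate variability**: RR series, shape-preserving cubic Hermite
  (PCHIP) resampling, windowed mean/SD statistics.
* **SCR stress classification**: voltage-divider conversion
  (`Vo = R2/(Rs+R2)·Vcc`), protocol labeling (Stroop / annoying-sounds),
  and a per-user C4.5-style decision tree grown by information gain ratio.
* **Metrics**: confusion matrices (sample-level true negatives for beat
  scoring), sensitivity/specificity/accuracy/PPV, pooling and averaging,
  plus the published evaluation tables bundled as regression fixtures.
* **Synthetic generators** for annotated ECG (PQRST templates, premature
  beats with compensatory pauses, arrhythmia episodes, noise, wander) and
  labeled SCR (stimulus-locked responses), so the whole pipeline is
  testable without any external data.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import cwtcardio as cc

# 2 minutes of synthetic ECG at 80 bpm with six premature beats
spec = cc.ECGSimSpec(
    duration_s=120, hr_bpm=80, seed=3,
    extrasystoles=[(i, 0.45, 0.4) for i in (20, 45, 70, 95, 120, 145)],
)
record, truth_times, truth_classes = cc.gen_ecg(spec)

peaks = cc.detect_r_peaks(record)          # CWT + windowed thresholding
report = cc.classify_beats(peaks)          # amplitude band + timing rule

cm = cc.match_events(truth_times, peaks.times, tolerance_s=0.05,
                     n_samples=record.n)
print(f"beats: {len(peaks)}  sensitivity: {cc.sensitivity(cm):.4f}  "
      f"false positives: {cm.FP}")
print(f"extrasystoles flagged at: "
      f"{[float(round(t, 2)) for t in peaks.times[report.extrasystole_indices]]}")
```

Output:

```
beats: 159  sensitivity: 1.0000  false positives: 0
extrasystoles flagged at: [15.05, 33.8, 52.55, 71.3, 90.05, 108.8]
```

All 159 beats are recovered with no false alarms, and the six flagged
times are exactly the six premature beats the generator inserted (their
reduced amplitude puts them in the 30–60 % band, and their timing
satisfies the ×2.2 inequality).

The same pipeline is available from the shell:

```sh
cwtcardio simulate ecg --spec spec.json --out ecg.csv --truth truth.tsv
cwtcardio detect --in ecg.csv --out peaks.tsv
cwtcardio anomalies --peaks peaks.tsv --out report.json
cwtcardio stress train --scr scr.csv --schedule proto.json --out tree.json
```

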