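# spatialp300

Offline analysis pipeline for a **spatial-auditory P300 brain-computer
interface**, with a calibrated synthetic-data generator.

In the paradigm this package models, a listener hears 100 ms noise bursts
from six azimuths (30, 90, 150, -150, -90, -30 degrees) — rendered through
earphones by convolving the noise with per-direction impulse responses —
and attends one direction. Attended (target, ~20% of trials) stimuli evoke
a P300: a positive ERP deflection, largest over central/posterior scalp,
peaking near 384 ms at Pz, versus an earlier, smaller positivity (~217 ms)
for unattended stimuli. The pipeline decides per trial whether the stimulus
came from the attended direction.

The analysis chain:

1. **Simulate** (or load) 64-channel, 256 Hz oddball sessions
   (`synth`) and render directional stimuli (`stimulus`);
2. **Preprocess**: third-order Butterworth band-pass 1-7 Hz, epochs
   -100..1100 ms with baseline subtraction, rejection of trials exceeding
   60 uV (`preprocess`);
3. **Characterize ERPs**: grand averages, positive-peak latency/amplitude,
   per-sample Mann-Whitney significance masks, per-direction tables
   (`erp`);
4. **Extract features**: 10-sample block means, per-electrode max-abs
   normalization — 28 x 64 = 1792 features for the full window; 6/19/64
   channel sets and 500 ms sliding windows (`features`);
5. **Classify** with a linear soft-margin SVM, min (1/2)|a|^2 + C sum xi
   s.t. y_i(a.x_i + b) >= 1 - xi_i: balanced training on half the targets,
   C grid-searched over 2^-16..2^2 on a held-out set, tested on a third
   set, repeated with re-randomized splits; bootstrap trial-averaging of
   k = 1..10 epochs before feature extraction (`classify`);
6. **Report**: summary statistics, Wolpaw information transfer rate,
   behavior-accuracy correlations (`report`).

Estimators follow scikit-learn conventions (`BandpassFilter`,
`ErpFeatureExtractor`, `SoftMarginLinearSVM` expose
`fit`/`transform`/`predict` and `get_params`), with functional wrappers for
one-shot use.

## Worked example

```python
import spatialp300 as sp

protocol = sp.ProtocolConfig(sessions=6)           # each direction targeted once
recordings = sp.simulate_subject(protocol, sp.ErpModel(), sp.NoiseModel(), seed=11)
epochs, report = sp.preprocess_sessions(recordings)
print(f"kept {int(epochs.kept_mask.sum())}/{report.n_total} trials "
      f"({report.rejection_rate_pct:.1f}% rejected)")

target = sp.grand_average(epochs.kept(), "target")
peak = sp.positive_peak(target, "Pz")
print(f"target ERP at Pz: peak {peak.amplitude_uv:.1f} uV at {peak.latency_ms:.0f} ms "
      f"(n={target.n_trials} trials)")

results = sp.run_experiment(
    epochs.kept(), sp.SplitConfig(n_repetitions=3, seed=5), k_range=(1, 5, 10),
)
print(results.groupby("k_averaged")["overall_accuracy"].mean().round(1))

acc = results[results.k_averaged == 1]["overall_accuracy"].mean() / 100
print(f"single-trial ITR: {sp.itr_wolpaw(P=acc, N=2, T=1.1).bits_per_minute:.1f} bits/min")
```

Output:

```
kept 875/900 trials (2.8% rejected)
target ERP at Pz: peak 2.9 uV at 398 ms (n=172 trials)
k_averaged
1     63.4
5     92.8
10    97.3
Name: overall_accuracy, dtype: float64
single-trial ITR: 2.8 bits/min
```

Reading the numbers: ~2.8% of trials are rejected by the 60 uV screen
(planted frontal blink artifacts). The causal 1-7 Hz filter attenuates and
delays the 5.2 uV / 384 ms target template to ~2.9 uV near 400 ms in the
grand average. Single-trial accuracy sits in the 60-80% band typical of
this paradigm, and bootstrap trial-averaging raises it steeply — averaging
k same-class epochs shrinks noise variance by 1/k while the ERP template is
preserved. The ITR converts accuracy and decision time into bits/minute.

A thin CLI wraps the same functions:

```bash
spatialp300 simulate --sessions 6 --target-direction 90 --seed 1 --out data/
spatialp300 render --direction 150 --seed 3 --out stim_150.wav
spatialp300 experiment --sessions 6 --channels 64 --reps 10 --seed 1 --out results.tsv
```

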