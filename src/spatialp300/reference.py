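"""Published per-subject summary tables from the six-direction spatial-auditory
oddball study this pipeline models.

These printed numbers are inputs: the behavioral and ERP columns parameterize
the synthetic generator's defaults, and reproducing their across-subject
averages is a worked example for :func:`spatialp300.report.summarize`.
Seven subjects took part in the earphone (virtual-direction) experiment; six
of them also completed the loudspeaker control experiment.
"""

# Localization test: percent of responses reporting the presented direction.
LOCALIZATION_CORRECT_PCT = (97.9, 85.0, 98.8, 88.8, 91.7, 85.0, 99.6)
LOCALIZATION_CORRECT_PCT_LOUDSPEAKER = (100.0, 100.0, 99.6, 99.2, 99.6, 99.6)

# Target-counting task: per-subject mean |reported - true| / true, percent.
COUNTING_ERROR_PCT = (1.1, 5.7, 1.6, 5.7, 4.1, 18.9, 0.3)

# Amplitude-threshold artifact screening: percent of trials excluded.
ARTIFACT_REJECTION_PCT = (3.7, 1.6, 0.3, 3.0, 3.9, 8.8, 2.2)

# Positive-peak statistics of the averaged ERP at Pz, per subject.
TARGET_PEAK_LATENCY_MS = (375, 356, 364, 375, 383, 488, 344)
TARGET_PEAK_AMPLITUDE_UV = (7.8, 3.8, 5.0, 7.6, 4.0, 2.6, 5.4)
NONTARGET_PEAK_LATENCY_MS = (270, 192, 282, 200, 177, 219, 181)
NONTARGET_PEAK_AMPLITUDE_UV = (4.6, 3.9, 2.5, 3.3, 3.9, 1.1, 3.8)

# Across-subject mean accuracy (percent) by trial-averaging count, earphone
# experiment: target and non-target rows for k = 1..10.
ACCURACY_BY_K_TARGET_PCT = (67.5, 72.9, 77.6, 83.0, 84.0, 87.1, 87.3, 88.1, 90.0, 89.7)
ACCURACY_BY_K_NONTARGET_PCT = (70.2, 74.3, 76.7, 80.8, 82.0, 84.0, 85.1, 86.4, 87.9, 88.8)
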