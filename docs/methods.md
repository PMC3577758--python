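# Methods

`spatialp300` implements an offline analysis pipeline for a spatial-auditory
P300 brain-computer interface: an oddball experiment in which a listener
attends one of six virtual sound directions and a linear classifier decides,
trial by trial, whether the presented stimulus came from the attended
(target) direction. Because no public recordings exist for this paradigm at
this exact protocol, the package pairs the analysis code with a synthetic
generator that emulates the study conditions, so every stage is testable
end to end.

## Protocol model

A session is 150 trials, each a 100 ms noise-burst stimulus followed by a
1000 ms inter-stimulus interval (1100 ms trial period; 281.6 samples at
256 Hz, pinned to a 282-sample integer spacing). Stimulus directions are
drawn per trial: the session's fixed target direction with probability 0.2,
otherwise uniformly among the remaining five of {30, 90, 150, -150, -90,
-30} degrees azimuth. An "exact" mode instead places exactly
round(0.2 x 150) = 30 targets at shuffled positions; the stochastic mode is
the default since the protocol is described only as a random sequence with
~20% targets. A default subject completes 12 sessions (two per direction);
the worked examples and the acceptance script use 6 (one per direction) to
keep desk-scale runs short — a scale choice, stated here once.

## ERP model

Each event adds a deterministic template to the background:

- **Target**: positive P300-like Gaussian bump, peak 5.2 uV at 384 ms
  (width sigma = 60 ms), preceded by an N2-like negativity (-2 uV at
  250 ms, sigma = 30 ms).
- **Non-target**: smaller, earlier positivity, 3.3 uV at 217 ms
  (sigma = 55 ms), with a small negativity (-1.2 uV at 140 ms,
  sigma = 20 ms).

The peak latencies/amplitudes are the across-subject averages of the
published per-subject table this package models; the Gaussian shape and the
component widths are design choices (no functional form is published) that
make peak latency and amplitude exactly controllable. The positive
component is rescaled so the template value at the nominal latency equals
the nominal amplitude exactly after the negative component's tail is added;
the N2 widths were chosen narrow enough that the template's argmax stays at
the nominal latency on any sampling grid containing it.

Spatially, templates are scaled by a scalp gain map, a Gaussian falloff
(sigma = 0.07 m) over standard 64-electrode positions centered at Pz —
gain 1 at Pz, largest over central/posterior sites. Per-direction gains
attenuate target amplitudes toward the rear (1.0 at +/-30, 0.95 at +/-90,
0.8 at +/-150 degrees), reproducing the published rear-direction amplitude
decrease; non-target gains are flat.

## Noise model

Background noise is Gaussian with a 1/f^beta spectrum (beta = 1) and is
spatially correlated across electrodes: channels are mixed by the Cholesky
factor of a Gaussian correlation kernel (scale 0.12 m) over scalp
positions. Real background EEG is strongly coherent between neighboring
electrodes; with independent channels a 64-channel classifier averages
noise away unrealistically fast, and channel-subset comparisons (64 vs 19
vs 6) lose their meaning. Setting `spatial_scale_m = 0` recovers
independent channels.

The broadband noise SD defaults to 11 uV. This value was calibrated once so
that single-trial classification accuracy on the default synthetic subject
lands in the 60-80% band the real experiment occupies (measured ~63-70%
across seeds), then frozen. At 10-trial averaging the synthetic subject
reaches ~96-97%, higher than the published 89.5%: the generator's ERP
templates are identical across trials, whereas real single-trial ERPs vary
in latency and shape, so averaging is more effective here. Passing tests on
this generator therefore demonstrates correctness of the pipeline's
machinery, not expected field performance on recorded EEG.

Artifacts: with probability 0.03 per trial, a 200 ms-wide, 200 uV Gaussian
bump is added on the frontal channels (Fpz, Fp1, Fp2, AF7, AF8), emulating
eye blinks. After band-pass filtering these exceed the 60 uV screen and are
rejected at a rate comparable to the published 3.4%.

Not modeled: eye-movement dynamics, volume-conducted ERP spread beyond the
smooth gain map, trial-to-trial ERP latency jitter, non-stationary noise,
subject-specific head geometry.

## Preprocessing

Third-order Butterworth band-pass, 1-7 Hz, applied causally
(forward-only) by default — what an online system could compute; a
zero-phase option exists but is off by default since the published
description does not name the phase convention. Epochs span -100..1100 ms
around onset (samples -26..281 at 256 Hz, half-open convention); the
-100..0 ms per-channel mean is subtracted, making each baseline segment
exactly zero-mean. Events whose window crosses a recording edge are
excluded and counted, not fatal.

Artifact rejection drops any trial whose maximum absolute amplitude, over
all channels and the full epoch window, *strictly exceeds* 60 uV ("exceeded"
read literally: a 60.0 uV peak survives). The screen runs after filtering
and baseline subtraction, following the listed order of the published
procedure; the report counts per-channel exceedances so frontal
localization of artifacts is observable. Rejection is idempotent.

## ERP statistics

Grand averages are plain means over kept trials matching a condition (and
optionally a direction). The positive peak is the argmax over a search
window (default 0-1100 ms, the full analysis window; published latencies
fall well inside any sensible choice), ties broken toward the earliest
sample. Target/non-target differences are tested per time sample with a
two-sided Mann-Whitney U (tie-corrected rank sum; exact null for group
sizes <= 20 without ties, normal approximation otherwise), masked at
p < 0.01 with no multiple-testing correction — mirroring the per-timepoint
display convention. Note the causal filter both attenuates and delays
peaks: on filtered synthetic data the target grand-average peak sits near
3 uV at ~400 ms rather than the 5.2 uV / 384 ms template values, which are
recovered exactly on unfiltered noise-free data.

## Features

Per trial and electrode, the analysis window's samples are reduced by
averaging consecutive 10-sample blocks: the full 0-1100 ms window has 282
samples of which the first 280 form 28 blocks, giving 28 x 64 = 1792
features; the 500 ms windows (128 samples) use the first 120 samples, 12
blocks. Each electrode's block vector is normalized by its maximum absolute
value (per trial, per channel — the only scope requiring no training-set
statistics; an all-zero channel is left at zero). Channel subsets: the
6-set {Fz, Cz, Pz, PO7, PO8, Oz}, and the 19-set adding {FCz, CPz, PO2,
C3, C4, P3, P4, P7, P8, PO3, PO4, O1, O2}. "PO2" is not a standard 10-20
label and is kept verbatim with a documented alias to POz. Temporal
variants: seven 500 ms windows starting at 0, 100, ..., 600 ms.

## Classification

Linear soft-margin SVM: minimize (1/2)|a|^2 + C sum xi subject to
y_i(a.x_i + b) >= 1 - xi_i, xi_i >= 0. The solver is sklearn's libsvm SMO
at tolerance 1e-6 (tests verify objective and predictions against an
independently solved primal QP). Decisions are sign(a.x + b) with 0
classified as +1 (arbitrary, documented).

Three-way split: floor(T/2) targets plus an equal number of randomly chosen
non-targets train the model (balanced training); the remainder is split
equally at random into a C-searching set and a test set, an odd remainder's
extra sample going to the test set. C is grid-searched over 2^-16..2^2
(19 values), selected by overall accuracy on the C-searching set, ties to
the smallest C (strongest regularization). The analysis is repeated
(default 10 times) with re-randomized splits, including re-drawn non-target
training subsamples, and accuracies are averaged.

Bootstrap trial-averaging: for each kept trial, k same-class epochs are
drawn (without replacement within a replicate, fresh draws across
replicates) and averaged *before* feature extraction; output sample counts
match the single-trial data. Targets are averaged within their stimulus
direction; non-targets are pooled across directions, whose per-direction
counts are small. k = 1 returns the original trials.

## Reporting

`summarize` is mean + sample SD (n-1; SD 0 for n = 1); table reproduction
rounds half-away-from-zero to the printed precision. The information
transfer rate uses the standard bits-per-selection formula
B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), scaled by 60/T; defaults
N = 2 (target/non-target decision) and T = 1.1 k seconds (k averaged
trials at one 1.1 s trial each), both overridable. Published ITR values for
this paradigm are not reproducible from the accuracy tables under any
obvious (N, T) choice, so ITR is exposed as a parameterized computation
rather than pinned to a target value; below-chance accuracies floor at 0
bits. Correlations between accuracy and behavior are Pearson
product-moment with the usual t-based two-sided p.

## Stimulus rendering

Stimuli are 100 ms Gaussian white-noise bursts band-passed to 100 Hz-15 kHz
(4th-order zero-phase Butterworth) and convolved per ear with a directional
impulse response. Measured individual transfer functions are the gold
standard; since measuring them needs hardware, the module accepts
user-supplied stereo IR WAV files and ships a spherical-head surrogate:
Woodworth interaural delay ITD = (a/c)(sin|theta| + |theta|) with
a = 0.0875 m, c = 343 m/s, implemented as a fractional-delay truncated
sinc; contralateral level shadow growing to 6 dB at +/-90 degrees; and a
mild high-frequency roll-off on both ears for rear directions, standing in
for the pinna cues that disambiguate front from back (a bare sphere is
front-back symmetric). The nominal 65 dB SPL level is metadata only. The
audio sampling rate defaults to 44.1 kHz (unspecified in the source
protocol).

## Numerical conventions and degenerate inputs

Explicit seeds everywhere (numpy Generator; no global state). Confusion
rows must sum to 1 within 1e-9. Epoch/baseline indices use
round(t x fs / 1000) with half-open sample ranges. Empty grand-average
selections, single-class training sets, sub-2-trial Mann-Whitney groups,
zero-variance correlation inputs, and bootstrap pools smaller than k raise
errors; empty direction-table cells are flagged rows (NaN), not errors;
failed cells inside the experiment factorial are recorded as NaN rows.

## Known limitations

The generator's trial-invariant templates overstate the benefit of
trial-averaging relative to real EEG (see above). The spherical-head IR is
a geometric surrogate, not a measured transfer function, and its rear cue
is a coarse spectral tilt. EDF/BDF I/O is not provided; sessions
round-trip via .npy + CSV, and `SessionRecording.to_mne_raw()` bridges to
MNE for users with recorded data.
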