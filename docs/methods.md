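# Methods

`hybridbci` models the software half of a two-channel wireless EEG
brain–computer interface of the kind used for hands-free wheelchair
control by people with tetraplegia: a head-mounted amplifier/ADC streams
256 Hz count data from bipolar derivations P3–T4 (parietal, "CH1") and
O2–T3 (occipital, "CH2"); an embedded processor extracts band-power
features, classifies them with a small neural network, and a state
machine driven by eyes-closed alpha bursts selects between a mental-task
BCI and an SSVEP BCI and maps classifier output to steering commands.
Because no public recordings exist for this configuration, the package
includes a synthetic generator that emulates the statistical structure of
each signal class, so that every downstream stage can be exercised and
validated without hardware.

## ADC front end

The converter is modelled as a differential 12-bit ADC with full scale
FS = 1.2 V, so one count spans LSB = FS/2¹² ≈ 293 µV at the converter
pins, or 0.146 µV referred to the electrodes through the total analog
gain of 2000 (quoted as 0.15 µV at two significant figures). Counts are
`round(v·gain/LSB) + mid_code` with `mid_code = 2048`, clipped to
[0, 4095]; clipping is silent but the saturated fraction is reported on
request, and the inverse mapping round-trips in-range signals to within
±½ input-referred LSB. A configurable electrode DC offset (default
450 counts) places eyes-open baseline activity in the 2400–2600 count
band, the regime in which a fixed count threshold separates eyes-closed
activity.

## Synthetic EEG

Each channel is the sum of two zero-mean noise processes built in the
frequency domain (1/f amplitude weighting by default, white selectable)
plus task-specific deterministic components:

* **rhythm component**, 5 µV RMS by default, whose θ (4–7 Hz), α
  (8–13 Hz) and β (14–30 Hz) content is multiplied by per-task,
  per-channel gain triples. The default signatures are *orthogonal*:
  arithmetic boosts CH1 θ ×3, figure rotation CH1 β ×3, letter composing
  CH2 β ×3, counting CH2 θ ×3. These are engineering choices that make
  the classes separable at the default noise floor, not claims of
  physiological fidelity.
* **unshaped noise floor**, `background_amplitude` (default 5 µV RMS).
  This is the difficulty dial: it carries no class information, so
  raising it dilutes the signatures and classification accuracy falls
  monotonically toward chance. (A single background scaled and
  band-shaped at once cannot play this role — the signature would grow
  with the noise.)
* **SSVEP**: a sinusoid at the stimulus frequency (6, 13 or 16 Hz;
  fundamental only by default) at 10 µV on the occipital channel and
  half that parietally.
* **eyes closed**: a 10 Hz alpha carrier on CH2 (0.3× on CH1) whose
  amplitude is `alpha_burst_amplitude` (20 µV) plus an excursion of
  `eyes_closed_baseline_shift` counts (250, ≈ 37 µV) modulated at 1.2 Hz
  between 75 % and 100 % of its peak. The floor is kept high so *every*
  alpha cycle peaks above the eyes-open count range: detection latency is
  then bounded by one carrier cycle, and the modulation (rather than a DC
  step) survives the 0.5 Hz high-pass. Occipital counts reach ≈ 2900–3000
  against a baseline ceiling of ≈ 2650, reproducing the regime in which a
  threshold near 2700 separates the two states.

Records are generated per 13 s session (first 3 s reserved as
preparation time and dropped at feature extraction, leaving a 10 s
analysis span) or from an arbitrary scripted timeline with a continuous
sample clock. All randomness derives from a single integer seed mixed
with the task identity and segment index, so identical configurations
are bit-identical.

## Feature pipeline

A 1 s (256-sample) window is taken every 0.25 s — 37 overlapping windows
per 10 s span — and each window is processed causally, as a streaming
embedded implementation would: 3-sample centred moving average (shrunken
at the edges), then a second-order Butterworth band-pass 0.5–100 Hz
(bilinear-transform design, single forward pass; poles are checked
against the unit circle), then a 256-point rectangular-window FFT. With
fs = 256 Hz each bin is exactly 1 Hz; the one-sided PSD P[k] = |X[k]|²
(k = 0…128) is reduced to the θ, α and β bins — 4 + 6 + 17 = 27 values
per channel, 54 per window. δ (0–3 Hz, dominated by ocular artifact) and
everything above 30 Hz are discarded. PSD values are kept in raw |X|²
units; the classifier's min–max normalization absorbs any global scale.

Numerical notes: windows are filtered after extraction (matching the
described processing order), so each carries its own filter transient;
the DC offset leaks a small broadband transient into every window, which
is identical across classes and removed by normalization.

## Classifier

Features are scaled per-feature to [0, 1] by min–max normalization
fitted on the training split only; test values outside the training
range are clipped, and features constant in training map to 0.5. The
network is a single hidden layer with log-sigmoid activations in both
layers, trained on one-hot targets under mean squared error with
Levenberg–Marquardt: Δw = (JᵀJ + λI)⁻¹Jᵀe with the full analytic
Jacobian of all per-sample output errors. λ starts at 10⁻³, is divided
by 10 on an accepted step and multiplied by 10 on rejection (up to 12
escalations per epoch, after which training is considered converged);
one epoch is one accepted step, so training MSE is non-increasing by
construction. A validation split provides early stopping: training halts
after `patience` (default 3) consecutive validation-MSE rises, and the
weights of the best-validation epoch are returned. The hidden size is
selected by sweeping 4–20 neurons and keeping the lowest validation MSE
(ties to the smaller net). Weights initialize uniformly in [−0.5, 0.5]
scaled by 1/√fan-in from the run seed.

The default data split is *session-blocked*: whole sessions are assigned
to train/validation/test (2 + 2 + 2 of the 6 sessions per task, i.e.
74 + 74 + 74 windows per task). Overlapping windows from one session are
strongly correlated; letting them straddle splits inflates test accuracy,
so the stratified per-window split is available but not the default.

## Controller

The decision layer runs on the 0.25 s window clock with five modes:
`NORMAL_OFF`, `BCI_CONTROL`, `HYBRID_SELECTION`, `MENTAL_BCI`,
`SSVEP_BCI`. Eyes closure is detected by comparing the occipital
channel's maximum count in the 1 s window against a per-subject
threshold (strict inequality); `calibrate_threshold` sets it at the
midpoint between the baseline's 99th percentile and the median
per-second eyes-closed peak, refusing when the margin is under
20 counts. Wake-up from `NORMAL_OFF` uses this raw threshold alone; once
on, the threshold can be combined with a trained eyes-closed classifier
(AND by default, configurable).

Closure-duration routing uses half-open bands centred on the nominal
1 s / 2 s selections, quantized to the 0.25 s step: [0.75, 1.5) s →
mental-task mode, [1.5, 2.5) s → SSVEP mode, ≥ 2.5 s → off (and 2.5 s
of sustained closure turns the system on). In a BCI mode, the per-window
class must repeat on `confirm_windows` (default 4 = 1 s) consecutive
updates before its command (left / forward / right) is emitted; by
default the controller then returns to `BCI_CONTROL` awaiting the next
selection (`latch_mode` keeps it in place). Steering commands are never
produced while the system is off — an invariant checked exhaustively
over flag sequences in the test suite.

Because the full-window maximum keeps exceeding the threshold for up to
window − step after the eyes actually reopen, the streaming runner
erodes the trailing edge of each detected closure run by
window/step − 1 updates (runs no longer than that vanish, acting as a
debounce), so the accumulated run length tracks the true closure
duration the bands are calibrated against. `step()` itself is a pure
function of the flag sequence.

## Metrics

Binary intentional-control accuracy is (TP+TN)/(TP+TN+FP+FN); multiclass
accuracy is the confusion-matrix trace over its total. Throughput uses
the Wolpaw information transfer rate B = V·[log₂N + P·log₂P +
(1−P)·log₂((1−P)/(N−1))] bits/min, with the 0·log 0 limits taken as 0.
B is zero exactly at chance and non-negative everywhere (below chance it
rises again — consistently wrong selections carry information); a
floored accessor exists for callers that treat sub-chance operation as
zero. Summary tables interleave per-subject accuracy (%) and bit rate,
rounded half-up to integers for display with full precision retained;
when recomputing published tables from integer accuracies, per-cell bit
rates can differ by ±1 from values derived from unrounded accuracies.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the pipeline is internally consistent:
the spectral chain matches closed-form oracles, the trainer recovers
signatures it is entitled to recover (≥ 90 % three-class test accuracy
at the default noise floor, degrading monotonically to chance as the
floor rises), and the controller routes and guards modes exactly. The
generator does not model inter-subject variability, electrode impedance
drift, ocular/muscle artifacts or mains interference, and its class
signatures are idealized; synthetic accuracies therefore say nothing
about accuracies attainable on human EEG, and published human results
are used only as fixed numeric anchors for the metric arithmetic.

## Problem sizes

Default experiments use the protocol scale throughout: 6 sessions × 37
windows = 222 units per task, split 74/74/74; classifier experiments in
the test suite train networks of 4–8 hidden neurons for up to 30 epochs,
which completes in seconds on one core.
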