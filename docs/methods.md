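# Methods

This note records the scientific and numerical choices behind `prefall`:
what is modeled, which parameters matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Problem formulation

A falling process is divided into three stages. *Non-fall* covers ordinary
activities of daily living (ADLs). *Pre-impact fall* is the interval in
which the person transitions from a controlled to a dangerous state — the
descent before ground contact, typically a few hundred milliseconds. *Fall*
is the interval containing the impact and the state transition around it.
Everything recorded after the fall stage (lying on the ground, getting up)
is cut off before labeling, since post-incident data says nothing about
prediction.

Recordings are 200 Hz, six channels: tri-axial accelerometer (g) and
tri-axial gyroscope (°/s). Raw SisFall-style files carry nine channels (two
accelerometers + gyroscope) as integer ADC counts; conversion to physical
units is the linear map `physical = raw · 2·range / 2^bits`. Which of the
two accelerometers feeds the model is configurable; the default is the
wide-range device (±16 g), because impacts reach several g and may clip a
narrow-range sensor.

### Windowing and labels

Trials are segmented into 256-sample windows (1.28 s) with stride 128 (50%
overlap). Stride is a package choice: 50% overlap is the standard
compromise between dataset size and redundancy, and it keeps descent
intervals represented in more than one window for the longer fall types.
Each window's label is the stage of its **final** sample. This rule is
causal: at inference time the window end is "now", so a pre-impact label
means "the person is falling *now*", which is the semantics a protective
device needs. A majority-overlap rule is available as an alternative. Trials
shorter than one window are skipped with a warning rather than padded —
padding would invent sensor data.

A structural consequence of the final-sample rule is worth stating plainly:
a window whose final sample lies only a few samples past the loss of
balance contains almost no descent signal, yet carries the pre-impact
label. Such boundary windows are the dominant error source for every model
family, and they bound the pre-impact sensitivity attainable on any cohort,
synthetic or real; per-fold pre-impact sensitivity varies more than the
other two classes for this reason. The original labeling literature notes
the same difficulty for short falls relative to the window width.

## Architectures

All families consume `[256 × 6]` windows and emit a 3-way softmax.

* **CNN** — three blocks of conv(k=3, 64 ch) → batch norm → ReLU → max
  pool(k=3, stride 2), then flatten → FC 1920→512 → ReLU → FC 512→3. The
  canonical temporal lengths 256 → 127 → 62 → 30 and the 1920-wide flatten
  are mutually consistent only with per-block convolution paddings
  (1, 0, 1) under floor-division pooling; that padding pattern is therefore
  the default, and `shape_trace` reproduces every dimension symbolically.
* **LSTM** — two stacked LSTM layers (hidden 64) over the raw sequence,
  final hidden state → ReLU → dropout 0.5 → FC → softmax. The baseline's
  exact sizes are not pinned anywhere, so the recurrent half mirrors the
  ConvLSTM's (matched recurrent capacity makes the comparison fair).
* **ConvLSTM** — four conv blocks (width 64, padding 1) compress the window
  to a 14-step, 64-channel sequence; two stacked LSTM layers (hidden 64)
  read it with dropout 0.5 between and after; FC + softmax on the last
  step. The default equals the hyperparameter-tuning winner (width 64,
  4 conv blocks, 2 LSTM layers, dropout 0.5).

Recurrent heads read the final time step rather than a temporal average —
again the causal, streaming-inference choice. Batch normalization uses
batch statistics in training and running averages (momentum 0.1) at
inference, the standard contract.

The layers are implemented directly on NumPy (channels-last layout;
convolution as one im2col matrix product; pooling by elementwise max over
shifted strided slices; LSTM with explicit backpropagation through time).
Every layer's gradient is verified against central finite differences in
the test suite, and the symbolic shape trace is checked against shapes
measured on real forward passes across random configurations.

## Training

Batch 64, Adam at learning rate 5·10⁻⁴ (no schedule, no weight decay — the
standard companion to focal loss at a fixed rate), 200 epochs at full
scale. Loss is focal: `FL(p_t) = −α_t (1−p_t)^γ log p_t`, batch-averaged,
with γ = 2 (the canonical value) and α set to inverse class frequency
normalized to mean 1, since non-fall windows dominate any realistic cohort.
At γ = 0 and unit α the loss reduces exactly to cross-entropy (tested).
Probabilities are clamped at 1e−7 inside the loss, so it never produces
NaN; a non-finite loss aborts training with diagnostics. Inputs are
standardized per channel with training-set statistics — accelerometer and
gyroscope units differ by two orders of magnitude, and no optimizer setting
compensates for that.

Epoch selection is sensitivity-first: among the three epochs with the
highest summed test sensitivity over the classes, the one maximizing the
non-fall + pre-impact sum is reported (earliest on ties). **This rule reads
test-fold sensitivities**, reproducing the published procedure literally;
it is optimistic relative to selection on a separate validation split, and
reported numbers should be read with that in mind.

The train-side learning curve is accumulated from the training batches
themselves (dropout active), the usual running definition; test-side
metrics come from a proper inference pass each epoch, and each epoch's
one-vs-rest confusion counts are stored so fold metrics at the selected
epoch need no retraining.

Determinism: models are pure functions of (config, seed); data order,
dropout masks and fold assignment all derive from explicit seeds; two runs
with the same configuration produce bit-identical reports.

## Evaluation

Metrics are one-vs-rest per class (sensitivity, specificity, accuracy).
Cross-validation is subject-wise: elderly subjects are shuffled into five
groups, young subjects likewise (as evenly as possible), and each fold
pairs one elderly group with one random young group, so no person
contributes windows to both sides of any split — the leakage check is
enforced at window granularity. With the canonical 15 elderly + 23 young
geometry this yields 3 elderly per test fold and young groups of 5/5/5/4/4
(~80/20 split). Reported summary is the mean of per-fold metrics
(macro-over-folds); pooled-confusion summaries are available behind a flag.
Undefined metrics (a class absent from a test fold) propagate as missing
values, never as zeros.

Latency is the wall-clock mean of single-window forward passes (batch size
1, warm-up excluded), the streaming deployment scenario. It is
hardware-dependent; only within-machine comparisons between families are
meaningful.

## The synthetic cohort generator

The generator exists so that every downstream stage is testable without an
external download. It is a *statistical* emulation — piecewise kinematic
phase templates, per-subject random effects, white Gaussian sensor noise —
not a biomechanical simulation.

A fall trial is walk prefix → descent → impact + settling → lying tail
(truncated). During descent the acceleration magnitude decays from 1 g to a
free-fall floor drawn from 0.25–0.6 g while the gravity direction swings
toward the final lying orientation; descent duration is drawn per fall type
from 300–800 ms, within the sub-800 ms envelope typical of real falls. The
gyroscope shows a rotation burst that reaches its 100–300 °/s peak within
~40 ms of balance loss and sustains through the descent; the abrupt onset
reflects the biomechanics of induced falls, where trunk angular velocity is
the classic early pre-impact trigger, and it is what makes stage membership
decidable from a window's final samples at all. Impact is a 3–6 g spike
with damped ringing; settling rests at 1 g in the new orientation. ADL
templates (walk, sit-down, stand, jog) keep acceleration magnitude within
0.5–2.5 g; walking is a cadence-locked oscillation around 1 g.

Per-subject effects — amplitude gain, walking cadence, timing jitter, with
elderly subjects slower and lower-amplitude — are drawn once per subject,
making subjects genuine statistical units for subject-wise splits. Phase
boundaries in annotations coincide exactly with the generative phase
switches. A two-threshold rule (free-fall floor then impact peak) separates
simulated fall from ADL trials with >99% accuracy at default noise, i.e.
the learning task is solvable by construction.

Default scale: 6 young + 5 elderly subjects (five elderly so the default
cohort supports five-fold subject-wise splits with an elderly subject in
every test fold), 4 fall + 4 ADL templates, 3 trials per subject per
template — 264 trials, ~1300 windows, with realistic class imbalance
(~73/9/18%). This trains all three families in minutes on one CPU core;
tests and examples use 20 epochs at this scale, which is where the
ConvLSTM's held-out curves flatten.

**What passing tests do and do not show.** Synthetic signals are cleaner
and lower-dimensional than real falls: no near-falls or recoveries, no
sensor drift or re-orientation of the device, four stylized fall types
instead of fifteen, and a noise model without motion artifacts. Success on
the synthetic cohort demonstrates that the pipeline — labeling, windowing,
architectures, loss, splits, selection rule — is implemented correctly and
can recover known structure; it does not certify performance on real-world
falls. The real-data experiment is available via `scripts/run_sisfall.py`
for users with a SisFall copy.

## Numerical details and edge cases

* All arithmetic in float64; softmax is max-shifted; focal loss clamps
  `p_t` at 1e−7.
* Pooling uses floor division; ties in the max take the earliest index.
* Forget-gate biases initialize to 1; other LSTM weights uniform
  ±1/√hidden; conv/dense weights uniform Glorot-style.
* Degenerate inputs: `fall_end = 0` yields an empty trial that downstream
  segmentation skips; a training set missing a class raises rather than
  silently training a two-class model; an empty epoch history cannot be
  selected from.
* Quantization on write to the SisFall dialect is round-to-nearest ADC
  count (≤ half a step per sample).

## Known limitations

* The epoch-selection rule peeks at test sensitivity (faithful to the
  published procedure, flagged above).
* Boundary windows under the final-sample rule put a ceiling on pre-impact
  sensitivity (discussed under *Windowing and labels*).
* The generator does not model the full SisFall activity taxonomy or
  device-orientation variability; see the scope note above.
* Latency numbers are not comparable across machines and say nothing about
  embedded-hardware feasibility.
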