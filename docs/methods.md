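# Methods

This note documents the models and procedures implemented in `tactypes`,
the assumptions behind the synthetic-data generator, the numerical choices
made where the design was genuinely open, and the known limitations.

## 1. Preprocessing

Raw Vm traces are conditioned in this order:

1. **50-µs moving average** (5 samples at 100 kHz), shrinking windows at the
   edges so output length equals input length.
2. **Artifact blanking**: samples in [t − 0.1 ms, t + 1 ms) around every
   stimulation pulse are replaced by linear interpolation between the
   boundary samples; overlapping spans are merged first. The 0.1-ms
   pre-margin absorbs artifact energy smeared backwards by the smoothing
   step. This stands in for the original adaptive-filter + blanking
   combination, whose exact implementation is unpublished.
3. **Quality control**: the Vm amplitude histogram (0.25-mV bins, Gaussian-
   smoothed) yields a lower (Down) and upper (Up) mode. A recording is
   included when the Down mode is below −55 mV, the Up–Down peak-to-peak
   difference exceeds 10 mV, and — if spike-like transients are present —
   their amplitude exceeds 25 mV. Unimodal histograms fall back to the
   5th–95th percentile span for the peak-to-peak criterion and are flagged.
4. **Spike removal**: candidate spikes are upward transients whose 0.2-ms
   slope of the 0.5-ms-smoothed trace exceeds 35 mV/ms (spikes rise an
   order of magnitude faster than the sharpest synaptic events, which stay
   under ~15 mV/ms in this data model). A generic spike waveform is
   estimated by iterative align-and-average over the detections and
   subtracted at every occurrence; with fewer than three detections the
   spikes are reported but left in place.

**Window normalization** follows the fixed order: 1-ms moving average →
decimation to 1 kHz → subtraction of a centered 100-ms moving average
(shrinking at the edges) → min–max scaling to [0, 1]. Flat windows (range
< 1e−9) are flagged degenerate, filled with 0.5, and excluded from
clustering. Two consequences worth knowing:

* The pipeline is invariant to affine transformations of the input
  (offsets die in the moving-average subtraction, gains in the scaling),
  but it is *not* idempotent: re-normalizing an already normalized curve
  changes it, because a scaled curve again has a non-constant local mean.
* For 1200-ms statistics windows the normalization constants come from the
  full extent, not the 350-ms sub-window.

## 2. Response-type clustering

The similarity rule and greedy extraction are described in the README. Two
points were genuinely open and fixed as follows:

* A leader's candidate group contains only its **direct** matches — no
  transitive closure.
* Ties between equally large candidate groups resolve to the leader with
  the lowest repetition index. Extraction order assigns type ids
  (0 = largest); group sizes are non-increasing because removals can only
  shrink later candidate groups.

The parameter-sensitivity grid re-clusters one cell at every
(threshold, overshoot) combination and reports the number of types, the
ungrouped proportion, the grouped proportion (types relative to the grid
maximum), and the **cluster agreement** between 8-neighboring grid cells:
for each cluster of the center cell, the largest fraction of its members
contained in a single cluster of the neighbor; the mean over center
clusters is one directed comparison, averaged over available neighbors.
The "max" variant averages each comparison's best per-cluster value.
Ungrouped responses are excluded on both sides; neighbors without clusters
contribute nothing.

## 3. Kruskal–Wallis specificity and its shuffle null

At every 1-ms sample of the 0–1200 ms window, each type with ≥ 2 members is
compared against all other responses of its cell (two-group Kruskal–Wallis
with tie correction; ungrouped responses count toward "the rest"). No
correction across samples is applied — the label-shuffle null serves as the
multiple-comparisons control instead, as a deliberate design choice. The
implementation ranks each cell's window matrix once and reuses the ranks
across types and shuffles, which makes 50+ shuffles cheap; it is verified
column-by-column against `scipy.stats.kruskal` in the test suite.

## 4. PCA + kNN separability

Principal components are fitted on the **class-mean** curves only (centered
on their mean), keeping the smallest number of components explaining ≥ 95 %
of the mean-curve variance. Individual responses are projected onto that
basis and decoded by repeated random half-splits (40 iterations): each test
response takes the relative-majority label of its k nearest training
responses (Euclidean metric; k = 4 within a cell, k = 9 across patterns or
neurons), with class ties resolved by the single nearest neighbor. Splits
that leave a class without training examples are resampled. The confusion
matrix pools counts over iterations and is row-normalized, so rows sum to
one exactly; accuracy is the diagonal mean and per-class F1 scores come
from the pooled counts (micro, per class). Within-cell tasks include
"ungrouped" as a class; cross-scope tasks exclude it.

## 5. ECoG brain states

1000-ms segments with 875-ms hop are mean-detrended; the periodogram power
over (0, 12] Hz is summed per segment (no extra tapering). Segments
strictly below the recording's median compound power, in runs of at least
two, are desynchronized; ties at the median stay synchronized. Stimulus
onsets map to the latest segment starting at or before them (so an onset in
the 125-ms overlap belongs to the later segment). The type/state
association pairs each type's desynchronized fraction with its own cell's
overall fraction and applies a two-sided paired t-test, once over all types
and once restricted to types with more than nine members. By construction,
the member-weighted mean of per-type fractions (ungrouped included) equals
the cell fraction exactly.

## 6. EPSP measurement, templates, and gating

The manual point-and-click measurement of the original workflow is replaced
by an automated detector with exposed parameters: the onset is the first
post-pulse time where the 0.5-ms slope of the 1-ms-smoothed trace exceeds
the pre-pulse mean + 3 SD (100-ms baseline) for at least 0.5 ms, searched
1–25 ms after the pulse; the peak is the maximum within 30 ms of onset;
amplitude = V(peak) − V(onset). No onset within 25 ms, or a truncated
post-pulse window, yields "no response".

EPSP **templates** hold 5–20 equally spaced (offset, voltage, tolerance)
checkpoints over 1.5–28 ms from onset, built from the onset-aligned average
of ≥ 100 events on the 1-ms-smoothed trace; tolerances are 2× the
across-event SD with a 0.2-mV floor. Matching slides derivative-triggered
candidate onsets (±1.5 ms around each trigger) and accepts when all
checkpoints pass — either as-is or as a uniformly scaled-up template
(scale 1–3×), so that larger EPSP-like events are never omitted; matches
closer than 4 ms merge to the earliest.

The **response-fraction gate** for an in-pattern pulse counts occurrences
with a template match 4–18 ms after the pulse, against a baseline match
fraction measured in twelve 14-ms bins preceding every pattern onset. A
pulse is significant only if its fraction exceeds baseline mean + 2 SD *and*
at least five occurrences responded; without pattern onsets the gate fails
closed. Only pulses separated from both neighbors by ≥ 10 ms are eligible
(first/last pulses use their single available gap). Order effects across
the five-pulse single-stimulation chunks and between-neuron differences use
two-sided Wilcoxon rank-sum tests.

## 7. The synthetic-data generator

The generator emulates the study's recording regime; its defaults are the
stated experimental conditions (8 patterns × 100 repetitions separated by
1.8 s, 20 five-pulse chunks per channel at 300-ms spacing, Vm at 100 kHz,
ECoG at 1 kHz) plus documented signal choices:

* **Up/Down background**: two-state semi-Markov square wave (Down −72 mV,
  Up −58 mV; exponential-ish dwells ~0.45/0.7 s) smoothed over 20 ms, plus
  Ornstein–Uhlenbeck noise (SD 0.5 mV, τ 15 ms) and white measurement noise
  (0.1 mV). Stimulation transiently suppresses the state flips (factor 0.9
  under an envelope decaying ~60 ms after the pattern), reflecting that
  evoked volleys override the ongoing slow oscillation; this also keeps the
  response windows analyzable at the small default evoked gain (12 mV).
* **Response-type templates**: each type is a binary level code over
  sixteen ~21-ms regions of the stimulation window. Codes are complement
  pairs of short-run Hadamard-16 rows, so any two types disagree over at
  least half the window, every region carries both levels (each type always
  differs from the pooled rest of its cell), and per-type staggering of the
  region boundaries (3.5 ms) keeps any two types from crossing levels at
  the same instant. Critically, the code curve is the **post-pipeline
  target**: the planted raw template is its pre-image under the centered
  100-ms-average subtraction (computed with a cached pseudoinverse), so the
  requested pairwise separation (default 0.42 normalized units, the scale
  the clustering consumes) holds exactly after normalization. Raw-scale
  separation does not survive offset removal — enforcing it there would
  compress between-type contrast below the clustering thresholds.
* **Post-stimulus off-response**: every trial (all types and ungrouped
  draws) carries the same stereotyped hyperpolarizing dip + rebound
  ~60–105 ms after stimulus offset. Because it dominates the extremes of
  the full-extent (1200-ms) windows, the min–max normalization constants
  are trial-invariant, and the post-stimulus tail carries no type signature
  — matching the observation that separability collapses to chance after
  the stimulus ends. Without such a shared landmark, per-window scaling
  constants alone would encode type identity into the tail indefinitely.
* **Ungrouped responses** are modeled as rare latent types: each draw is a
  fresh random short-run binary code with jittered boundaries, so two draws
  almost never pair-match under the clustering rule.
* **Single-pulse EPSPs** are hierarchical: per-neuron mean amplitude,
  latency, and time-to-peak are drawn so the pooled distribution across
  neurons matches 7.7 ± 4.8 mV, 11.1 ± 3.1 ms, 9.8 ± 5.6 ms, while
  within-neuron scatter follows the per-neuron CVs 0.43 / 0.28 / 0.29.
  Both levels are published population statistics; a single-level model
  cannot reproduce both at once. Events are alpha-function kernels peaking
  at the drawn time-to-peak (floored at 4 ms — faster rises would be
  spike-like); amplitudes floor at 0.3 mV.
* **In-pattern responses** attach an EPSP to each pattern pulse with
  probability 0.75, modulated by a planted per-(pattern, pulse) lognormal
  factor (σ = 0.4) — the "mosaic" that the between-neuron comparisons
  detect. Spontaneous EPSPs arrive at 1 Hz (2.5 ± 1 mV).
* **Stimulus artifacts** are 1-ms biphasic ±30 mV transients at every
  pulse; **spikes** are stereotyped 40-mV waveforms at 0.05 Hz.
* **ECoG**: pink noise, attenuated ×0.4 in desynchronized epochs, plus a
  slowly frequency-modulated 1.5–3.5 Hz oscillation during synchronized
  epochs. States alternate with exponential dwells (synchronized mean 8 s;
  desynchronized dwell derived from the 20 % target fraction).
* All randomness flows from one seed through named sub-streams per
  component, so partial reconfiguration leaves other components' draws
  unchanged, and identical configurations are bit-reproducible.

Raw-session evoked responses are stamped with a 5-ms onset ramp (an
instantaneous onset would masquerade as a spike); the fast windows-only
path (`simulate_window_set`) has no such ramp and carries type information
from the first sample, which is the path used for per-timepoint
separability claims.

### What the generator does *not* emulate

Real recordings have state-dependent response variability (the same type
looks different in Up vs Down states), electrode drift, seal instability,
correlated network events, and far messier ungrouped responses. Passing
tests on synthetic sessions therefore demonstrates that the analysis chain
is implemented correctly and is well-calibrated under its own null models —
not that real recordings would yield any particular type count or accuracy.
The published real-data headline numbers (≈3.8 types/pattern, ≈60 %
within-cell accuracy, ≈37 % ungrouped) are data-dependent and are treated
as report schema only.

## 8. Problem sizes and numerical choices

The shipped tests and the acceptance script run desk-scale problems chosen
to keep estimates stable: four (neuron, pattern) cells of 4 types × 80
repetitions (+20 % ungrouped) for the Kruskal–Wallis calibrations, 50 label
shuffles, 5 simulated neurons × 100 single-pulse trials (≈490 measured
events) for the amplitude-CV loop, and 1–2 short full-signal sessions for
the end-to-end and determinism checks. Degenerate inputs are handled
explicitly throughout: flat windows 0.5-fill and never cluster, classes
with fewer than two members are dropped from decoding tasks, cells with a
single type yield empty specificity curves, unimodal Vm histograms flag the
QC fallback, and gates without baselines fail closed. Numerical tolerances:
normalization degeneracy at 1e−9, p-values clipped into (0, 1], confusion
rows exact to 1e−9, template pre-compensation via pseudoinverse with
rcond 1e−8.

## 9. Known limitations

* The greedy extraction is order-dependent only through its documented
  tie-break; no global optimality is claimed beyond per-step maximality.
* The pre-compensated templates are an analysis-scale construct; their raw
  waveforms are smooth but not biophysically derived.
* The EPSP detector's thresholds (3 SD, 0.5-ms persistence, 25/30-ms
  windows) are package choices, exposed in `DetectorParams`; recall is
  bounded (~95 %) by the ±2 SD tolerance band against the heavy-tailed
  amplitude distribution.
* Cross-neuron decoding and the within-pattern EPSP mosaic analyses are
  exercised at small neuron counts; their real-data scale (13 neurons,
  52 eligible pulses) is reachable but slow on one core.
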