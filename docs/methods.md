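# Methods

This note documents the model implemented by `eplff`, the calibrated
default parameters, and the synthetic benchmark conditions used by the
test suite and by `scripts/acceptance.py`.

## Model overview

The classifier is a feedforward spiking network patterned on the
external plexiform layer of the olfactory bulb.  One *mitral cell* (MC)
per chemosensor converts preprocessed input into a spike-phase code
under a 40 Hz gamma clock; a large population of *granule cells* (GCs)
reads coincidences among MC spikes through plastic excitatory synapses;
the binary GC spiked/not-spiked vector of a presentation is the code
used for classification.

### Preprocessing (glomerular layer)

1. **Sensor scaling.**  Each sensor's response is divided by its maximum
   over a validation split (10% of the first batch, class-stratified).
   The scale is fitted once and frozen; degraded later batches pass
   through the same factors.
2. **Concentration tolerance.**  The scaled vector is divided by its sum
   over sensors.  The output is invariant to any positive rescaling of
   the input, which removes most concentration-driven variance.  The
   pre-normalization sum is retained — it is the only place
   concentration information survives and is the regressor used for
   concentration estimation.

### Input currents and contrast normalization

MC input currents are `input_gain` × the *unit-L2-norm* direction of the
normalized vector.  The extra L2 step is a contrast normalization:
broadly tuned odorants have individually small sum-normalized entries,
and without it they would drive far fewer spikes than sharply tuned
odorants of identical signal quality.  Both steps are scale-invariant,
so concentration tolerance is preserved.  The default gain (6.5) is
calibrated so that the strongest sensors fire within the first ~2 ms of
the 25 ms gamma cycle and sensors well below the array maximum stay
silent.

### Spiking dynamics

- **Gamma clock:** shunting inhibition `r_shunt(t) = −3.8·cos(2πft/1000) + 5`
  at `f = 40` Hz; integration is forward Euler at 0.01 ms.
- **MCs:** leaky integrate-and-fire, `τ = 5` ms, threshold 0.5, membrane
  resistance divided by the shunt.  Stronger inputs cross threshold at
  earlier phases (*spike precedence coding*).  Each MC fires **at most
  once per gamma cycle**: the phase code assigns one phase per cycle,
  and uncapped repeat firing blurs the coincidence structure the GCs
  read (it inflates total drive without adding timing information).
- **GCs:** LIF with `τ = 2` ms driven by double-exponential AMPA-like
  conductances (`g_max = 0.01`, decay 2 ms, rise 1 ms, reversal +70).
  One unit-weight presynaptic spike peaks the membrane at ≈ 0.45 × the
  base threshold, so even the most excitable GCs need at least two
  near-coincident inputs to fire.
- **Threshold heterogeneity:** per-GC thresholds are drawn uniformly
  from 0.55–5× the base value.  The wide band spreads coincidence
  requirements from 2-way up to strong many-way coincidence, so the
  active code fraction varies slowly with overall drive — an emergent
  soft k-winners-take-all — instead of saturating or vanishing when
  drive changes.

### Plasticity

STDP is gated by postsynaptic GC spikes and pairs each GC's first spike
with each presynaptic MC's first spike of the same gamma cycle.  The
default learning rate is *saturating*: one causal pairing drives a
weight to `w_max`, one acausal or unpaired GC spike drives it to 0, so
after a single training shot every synapse holds one of at most three
values (0, `w_0`, `w_max`).  The default sets `w_max = w_0 = 1`
(depression only).  Potentiation headroom (`w_max > w_0`) is supported
but is not the default: with binary code readout it adds no
separability, and in calibration it caused over-generalization —
distractor odorants recruited the potentiated synapses of stored
templates, degrading both none-of-the-above rejection and cross-class
separation.

### Classification

Templates are the GC codes of plasticity-frozen presentations recorded
immediately after each training shot.  Test codes are classified to the
nearest template by Hamming distance normalized over the union support
(Jaccard distance); best distance > 0.5 yields *none of the above*.
Union normalization matters: with thousands of mostly silent GCs a
length-normalized distance can never reach 0.5 and rejection would be
vacuous.  A binary-cosine overlap criterion is available as an
independent check and agrees with the Hamming rule on ≥ 99% of benchmark
samples.

### Concentration estimation

Per odorant, a quadratic calibration `C = a·x² + b` is least-squares
fitted over the training shots, where `x` is the summed sensor-scaled
response.  Estimation runs after classification and returns nothing for
rejected samples.

### Reset learning

Sensor drift is mitigated by resetting all synapses to `w_0`, clearing
the template store, and retraining (few shots per class) on the new
batch, with the sensor scale and every other parameter frozen from the
first batch's validation fit.

## Synthetic benchmark

The generator draws per-odorant affinity profiles (6 strongly sensitive
sensors at 0.4–1.0, baseline 0.1 elsewhere) with a monotone saturating
Hill response, multiplicative sensor noise, and slow drift.  Design
points that matter:

- **Separation is enforced in two coordinate systems.**  Candidate
  profiles must subtend the required angle both as raw affinity vectors
  and as high-concentration response vectors after per-sensor max
  scaling, because the empirical scaling is a diagonal transform that
  does not preserve angles.
- **Nonzero baseline affinity** keeps every sensor responsive to every
  odorant so no sensor's empirical scale collapses toward zero (which
  would blow up that sensor's scaled response for any odorant that does
  excite it).
- **Distractors** (for none-of-the-above testing) are drawn at ≥ 60°
  from every trained profile, with candidate active sensors proposed
  preferentially where trained profiles are weakest — a genuinely novel
  odorant excites the under-used corners of the array.
- **Noise** is multiplicative (5% of the clean response by default),
  since chemosensor noise grows with the response.
- **Aging** (`aging_drift`): per-sensor monthly decay factors evenly
  spaced across 0.96–1.0 and assigned to sensors in seeded random order,
  plus 0.015 rad/month random rotation of the response axes.
  Heterogeneous decay is the damaging ingredient: a uniform gain loss is
  removed exactly by the concentration-tolerance normalization, whereas
  sensors fading at different rates warp the response *directions*.  The
  even spacing guarantees every seed realizes the nominal spread —
  i.i.d. draws can by chance land nearly uniform and produce an almost
  harmless condition.  Over a 21-month two-batch study this cripples a
  classifier trained on fresh sensors (accuracy can collapse entirely)
  while remaining recoverable by reset learning under the frozen
  original scale.

## Study conditions

The benchmark protocols (tests and `scripts/acceptance.py`) use: 6
odorant classes at ≥ 30° pairwise separation, 400-sample batches with
log-uniform concentrations in 10–1000 ppmv, 5% relative noise, 10%
validation split, sequential one-shot training (the drift-mitigation
study trains 5 shots per class in both arms, since drift recovery is a
few-shot protocol, and uses 200-sample batches), 1200 granule cells
(the structural one-shot saturation check uses the full 16 × 4800
default), and three seeds per protocol.  The concentration-recovery
study uses 4 classes with a pure power-law response (`hill = 0.5`, no
saturation), making the summed response an exactly invertible quadratic
function of concentration; with noise disabled the estimator must
recover concentrations to machine precision.
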