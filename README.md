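# eplff

An olfactory-bulb-derived spiking neural network for online few-shot
classification on chemosensor ("electronic nose") arrays.

The model reproduces the feedforward external-plexiform-layer circuit:
glomerular preprocessing (per-sensor scaling plus an unsupervised
concentration-tolerance normalization), gamma-clocked leaky
integrate-and-fire mitral cells whose spike *phase* encodes input
strength (precedence coding), spike-timing-dependent plasticity on the
mitral-to-granule-cell projection, and classification of the binary
granule-cell spike code by nearest stored template with an explicit
*none-of-the-above* outcome.  It learns a new odorant from a single
presentation without forgetting previously trained ones, estimates
concentration with a per-odorant quadratic calibration, and mitigates
long-term sensor drift by *reset learning* (re-initializing the synaptic
weights and retraining on the degraded array).

See [docs/methods.md](docs/methods.md) for the model equations, the
calibrated defaults, and the synthetic benchmark design.

## Worked example

```python
import numpy as np

from eplff import (
    BatchSpec, EPLffClassifier, concentration_tolerance, generate_dataset,
    make_distractor, make_profiles, mc_spike_phase, sample_response,
)

# 1. Synthesize a 16-sensor array and three odorants at >= 30 deg separation.
profiles = make_profiles(3, min_pairwise_angle=30.0, seed=42,
                         labels=["acetone", "toluene", "ammonia"])
batch = generate_dataset(profiles, [BatchSpec(n_samples=90, batch_id=1)], seed=42)[0]
X, y = batch.feature_matrix(), np.array(batch.labels())
print("features:", X.shape)
# features: (90, 16)

# 2. Concentration tolerance is exactly scale invariant.
x = X[0]
print(np.max(np.abs(concentration_tolerance(10 * x) - concentration_tolerance(x))))
# 2.7755575615628914e-17

# 3. Stronger input -> earlier spike phase (precedence coding).
print(mc_spike_phase(2.0).first, mc_spike_phase(6.0).first)   # ms into the cycle
# 2.11 0.54

# 4. One-shot training: a single presentation per odorant.
clf = EPLffClassifier(n_gc=800, random_state=0)
train_idx = [int(np.flatnonzero(y == lab)[0]) for lab in sorted(set(y))]
test_idx = [i for i in range(len(y)) if i not in train_idx]
clf.fit(X[train_idx], y[train_idx])
print(clf.score(X[test_idx], y[test_idx]))
# 1.0   (87 held-out samples)

# 5. A genuinely novel odorant is rejected as none-of-the-above.
distractor = make_distractor(profiles, min_angle=60.0, seed=7)
novel = np.stack([sample_response(distractor, c, seed=s).features
                  for s, c in enumerate((30.0, 100.0, 300.0))])
print(list(clf.predict(novel)))
# ['none_of_the_above', 'none_of_the_above', 'none_of_the_above']
```

All printed values above are the actual outputs of this script.

`EPLffClassifier` follows scikit-learn conventions (`fit`,
`partial_fit` to add classes online, `predict`, `score`,
`get_params`/`set_params`); the underlying circuit is equally usable
through module-level functions (`build_network`, `train_shot`, `infer`,
`classify`, `simulate_cycle`, ...) for finer control.

## Command-line interface

The `eplff` command runs the full experiment protocols from one YAML
config; every run archives its config and generated odorant profiles in
the output directory so it can be reproduced from its artifacts alone:

```sh
eplff generate       --config cfg.yaml --seed 1 --out runs/gen    # write synthetic batches as CSV
eplff online         --config cfg.yaml --seed 1 --out runs/online # sequential few-shot learning
eplff reset-learning --config cfg.yaml --seed 1 --out runs/reset  # drift mitigation study
eplff gc-sweep       --config cfg.yaml --seed 1 --out runs/sweep  # accuracy vs granule-cell count
eplff concentration  --config cfg.yaml --seed 1 --out runs/conc   # concentration-estimation MAE
```

A minimal online-protocol config (run with `eplff -v online` to see
per-stage logging):

```yaml
data:
  n_classes: 6
  n_samples: 200
  noise_relative: 0.05
network:
  n_gc: 1200
protocol:
  shots_per_class: 1
  validation_fraction: 0.1
  repeats: 1
nota:
  min_angle: 60.0
  n_samples: 20
```

which prints, among other things:

```
INFO eplff.protocols: stage 6 (odorant_5): accuracy 1.0000 over 176 samples
INFO eplff: repeat 0: distractor NOTA rate 1.000
mean final accuracy: 1.0000
```

The full config schema (data source — synthetic generator or sensor
files in the sparse drift format —, network, protocol, drift, NOTA,
sweep and concentration sections) is documented in the module docstring
of `eplff/cli.py` and in `eplff --help`.  Exit status is 0 on success
and 2 on any configuration error.

## Layout

- `src/eplff/preprocess.py` — sensor scaling, concentration tolerance
- `src/eplff/spiking.py` — gamma clock, LIF neurons, synaptic kernels, cycle simulation
- `src/eplff/plasticity.py` — STDP rule and weight reset
- `src/eplff/network.py` — network assembly, training shots, inference
- `src/eplff/classify.py` — distance metrics, template store, NOTA classification, concentration models
- `src/eplff/synthetic.py` — odorant profiles, noise, drift, dataset generation
- `src/eplff/datasets.py` — sparse drift-file parsing, CSV IO, protocol splits
- `src/eplff/protocols.py` — online, reset-learning, GC-sweep and concentration protocols
- `src/eplff/estimators.py` — scikit-learn-style `EPLffClassifier`
- `src/eplff/cli.py` — the `eplff` command
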