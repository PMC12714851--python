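# neuroedge

An end-to-end toolkit for EEG-based mental-state monitoring on edge
infrastructure:

- **`neuroedge.eeg_io`** — EDF and delimited-matrix recording I/O, built-in
  128-channel cap and 3-electrode wearable montages.
- **`neuroedge.preprocess`** — ocular-artifact regression, per-channel
  standardization, zero-phase band-pass/notch filtering, spatial
  referencing, montage alignment, windowed segmentation, and
  consistency/quality scoring.
- **`neuroedge.tst_model`** — a temporal-shift transformer classifier
  (causal depthwise temporal convolution, feature-block time shifting,
  sinusoidal positional encoding, multi-head self-attention, position-wise
  FFN) with a pure-numpy training loop (hand-derived gradients, Adam,
  seeded and deterministic), confusion-matrix metrics, and ROC/AUC.
- **`neuroedge.stackelberg`** — a leader–follower resource-allocation game
  with pluggable utilities, closed-form/grid/swarm bilevel solvers, and
  game validation.
- **`neuroedge.npo`** — a population-based optimizer with inertia-weight
  velocity updates and an optional nomadic clan-migration layer.
- **`neuroedge.edge_sim`** — a six-component latency budget model
  (24–46 ms end-to-end by default), device-to-node offloading policies,
  and threshold alerting.
- **`neuroedge.synth_data`** — seeded synthetic EEG cohorts with
  class-dependent band power and known ocular contamination, plus game
  instances with analytically known equilibria.
- **`neuroedge.cli` / `neuroedge.pipeline`** — a typer CLI and stage
  orchestration.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a full
synthetic end-to-end run (generate → contaminate → preprocess → segment →
train → evaluate) that takes a few minutes on one CPU core; everything else
finishes in seconds.

## CLI

```bash
neuroedge generate-data --out data/ --seed 0 --n-subjects 4
neuroedge preprocess --data-dir data/ --out reports/
neuroedge train --out runs/bench --seed 0
neuroedge allocate --out runs/alloc --n-followers 3 --seed 0
neuroedge simulate-latency --out runs/lat --n-devices 8 --seed 0
neuroedge run --stages allocate,simulate-latency --seed 0 --out runs/full
```

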