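# san — segmented attractor network simulator

A simulator for studying associative memory in a lifelong-learning
setting with a *segmented attractor network* (SAN): neurons represent
categorical features grouped into sets, memories are stored as binary
Hebbian weights (`v_on`) between cross-set feature pairs, and recall is
pattern completion from partial input with winner-per-set readout and
randomized tie breaking.

Included:

- **Dataset model** (`san.schema`) — categorical datasets as CSV (one
  memory per row, one set per column), per-set uniqueness factors
  `U_i = M_i / I_tot`, mean pairwise Hamming distance.
- **Synthetic generator** (`san.synth`) — datasets with exact per-set
  distinct-feature counts, optional planted common features with exact
  frequency, and an 8-set profile matching the 700-memory
  European-heads-of-state reference dataset (328/190/29/22/24/117/9/59
  distinct features per set).
- **Network core** (`san.network`) — weight grid with zero intra-set
  blocks, association, synchronous output pass `f = E + WᵀE`, recall
  with iterative tie resolution.
- **Learning behaviors** (`san.behaviors`) — predictive association
  (threshold `P_th`), erasure of over-connected neurons (`R_th`),
  passive weight decay (`D_rate`), and the threshold-sizing rule
  `R_th = I_tot · f_sim · v_on`.
- **Metrics** (`san.metrics`) — hit-rate surface stratified by mean
  input uniqueness, unique memory ratio (UMR), per-memory recall
  occurrence counts.
- **Simulator** (`san.simulate`) — the five-phase loop: per time step,
  optional forgetting → association → optional prediction → optional
  erasure → full recall evaluation of every shown memory under every
  k-of-n input combination. Evaluation is vectorized and never mutates
  the weights; runs are fully determined by two seeds (presentation
  order, tie breaking).

## CLI

```sh
# generate a synthetic dataset
san synth --spec examples/synth.yaml --out data.csv

# run a simulation from a YAML config
san run --config examples/run.yaml --dataset data.csv --out runs/demo

# summarize a finished run
san metrics --run runs/demo
```

Run config keys: `dataset` (CSV path) or `synth` (generator spec),
`v_on` (default 0.001), `e_mag` (default 1.0), `k_input` (input sets per
recall trial, default n/2), `eval_every`, `seed_sequence`, `seed_ties`,
and a `behaviors` mapping:

```yaml
behaviors:
  predictive: {enabled: false, p_th: 6}     # thresholds in multiples of v_on
  erase:      {enabled: false, r_th: 400}
  forgetting: {enabled: false, d_rate: 0.015}
```

Outputs per run: `hit_rate.csv` (long form: t, combo, hits, trials),
`umr.csv`, `occurrences.csv`, `predictions.json`, `erasures.json`, and a
`manifest.json` sufficient to reproduce the run bit-for-bit.

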