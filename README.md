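# dtgcn

Dynamic temporal graph convolutional network for EEG seizure detection and
classification, with a synthetic-EEG test bench.

The model combines three stages:

1. **Seizure-attention reconstruction** — a multi-head self-attention module
   reconstructs each clip over its time steps; per-step reconstruction errors
   act as anomaly scores. A threshold `tau` is searched over 50 uniform
   candidates against per-time-step ("fine-grained") seizure labels, and the
   reconstruction loss is augmented with the mismatch between labelled and
   predicted seizure-step counts.
2. **Dynamic graph learning** — short windows of the reconstructed signal are
   fused with the recurrent hidden state, diffused over a predefined
   electrode-distance graph, and turned into a time-varying directed
   inter-channel adjacency (averaged over the last `n` steps, top-k
   sparsified).
3. **Graph-convolutional GRU** — a GRU whose linear maps are replaced by graph
   convolutions on the learned adjacency; the final hidden state feeds a
   softmax head for detection (2-class) or seizure-type classification
   (4-class: CF / GN / AB / CT).

Because no GPU frameworks are assumed, the trainable model runs on a small
reverse-mode autodiff engine (`dtgcn.nn`) built on NumPy, with an Adam
optimizer and float32/float64 modes. Gradients are verified against finite
differences in the test suite.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` contains the end-to-end acceptance criteria
(equation-level oracles, analytic identities, threshold search, sparsity
contract, gradient checks, synthetic end-to-end learning, ablation and
connectivity directions, sweep grids). The heavy end-to-end tests train
scaled-down models on synthetic data and take a few minutes on one CPU.

## Command line

```sh
# generate a synthetic clip dataset (HDF5 + ground-truth sidecar)
dtgcn simulate --seed 7 --out data/ --n-records 100

# train seizure detection (or --task classification)
dtgcn train --seed 0 --data data/ --out run/ --epochs 15 --lr 1e-2

# evaluate a checkpoint on the held-out test split
dtgcn evaluate --checkpoint run/checkpoint.npz --data data/ --out eval/

# per-class mean dynamic connectivity and difference matrices
dtgcn analyze --checkpoint run/checkpoint.npz --data data/ --out analysis/ --plot

# hyperparameter grids: K in {1,5,10,20,50}, n in {1,2,4,8,16},
# lambda in {0.1,0.3,0.5,0.7,0.9}
dtgcn sweep --param n --data data/ --out sweeps/
```

A YAML config file (`--config`) can override `model`, `train` and `synth`
sections; see `tests/test_cli.py` for the schema.

### Ablations

`dtgcn train --no-seizure-attention` bypasses the attention reconstructor
(`X' = X`, no reconstruction loss); `--static-dist-graph` replaces the
learned dynamic adjacency with the static electrode-distance graph.

## Package layout

| module | role |
| --- | --- |
| `dtgcn.nn` | reverse-mode autodiff engine + Adam |
| `dtgcn.eeg` | EEG records/clips, resampling, slicing, distance graph, EDF/HDF5 I/O |
| `dtgcn.edf` | minimal EDF reader/writer |
| `dtgcn.attention` | self-attention reconstruction, threshold search, constrained loss |
| `dtgcn.graphs` | windowing, diffusion, dynamic adjacency, averaging, top-k |
| `dtgcn.model` | graph-convolutional GRU, heads, objective, checkpoints |
| `dtgcn.synthetic` | synthetic EEG generator (10-20 layout, seizure classes, planted coupling) |
| `dtgcn.train` | training loop, metrics, ablations, sweeps, connectivity analysis |
| `dtgcn.cli` | `dtgcn` command-line interface |
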