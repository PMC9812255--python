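# stgcn-eeg

Spatial-temporal graph convolutional networks for two-class classification
of multichannel EEG from functional-connectivity graphs.

## What this is for

Cortical disconnection shows up in resting-state EEG as altered *functional
connectivity* — statistical dependence between the signals at different
scalp sites.  This package implements a classifier that uses both sides of
that picture at once: each 0.25 s window of a 23-channel recording is
described by its raw channel dynamics `X` (25 samples x 23 channels) **and**
by a 23 x 23 adjacency matrix `W` of pairwise coupling strengths, and a
spatial-temporal graph convolutional network (ST-GCN) consumes the pair.
It is aimed at researchers studying disease- or state-related connectivity
differences (the motivating case is dementia vs healthy ageing) who want a
fully scripted, reproducible pipeline from raw recordings to accuracy
tables and connectivity maps — including a ground-truth simulator, since
clinical recordings usually cannot be shared.

## The model

Six estimators can populate `W` for a window: Pearson correlation (PC),
magnitude squared coherence (MSC), imaginary part of coherency (IPC),
wavelet coherence (WC), phase locking value (PLV) and phase lag index
(PLI).  All produce symmetric, nonnegative, zero-diagonal matrices with no
thresholding.

The network is built from spectral graph convolutions.  With
`L = I − D^{−1/2} W D^{−1/2}` the normalised graph Laplacian, a graph
filter is a polynomial in `L`; the package implements the Chebyshev
recurrence `T_k(L̃)` on the rescaled Laplacian and, inside the network,
its tied first-order renormalised form

```
S = D̃^{−1/2} (W + I) D̃^{−1/2},      y_t = S X_t Θ
```

applied to every time frame in parallel.  Each of the two ST-Conv blocks
computes

```
temporal conv (Kt = 3) → graph conv + ReLU → temporal conv → layer norm
```

shortening 25 → 21 → 17 time steps; a flatten + dense + sigmoid head
yields the class-1 probability.  Training is Adam on binary cross-entropy
with best-validation-loss checkpointing.  A temporal-only baseline
(`T-CNN`, identical but without the graph unit) isolates the contribution
of `W`.  The layers are implemented directly on numpy with hand-derived
gradients, so everything is dependency-light and bit-reproducible.

The simulator generates labelled cohorts of band-structured oscillator
signals whose phases follow a Kuramoto dynamic on a configurable coupling
graph, with a plantable group difference (weaker posterior coupling in the
patient-like group) — so estimator recovery and classifier behaviour can
be validated against ground truth.  See `docs/methods.md` for the model,
the estimator conventions, and the simulation conditions in detail.

## Worked example

```python
import numpy as np
from stgcn_eeg import (CohortConfig, make_two_group_benchmark, build_dataset,
                       FULL, STGCN, ModelConfig, average_adjacency,
                       group_difference, top_pairs)

# a small two-group cohort with a posterior coupling deficit planted in
# the patient-like group
cfg = CohortConfig(n_subjects=(2, 2), n_epochs=1, eye_states=("EC",), seed=7)
recordings, truth = make_two_group_benchmark(cfg, effect=0.6)

# full-band filtering, decimation to 100 Hz, 25-sample windows, and one
# wavelet-coherence adjacency matrix per window
ds = build_dataset(recordings, band=FULL, fc_method="WC")

split = ds.split(train_frac=2/3, k=10, seed=7)
train_idx, val_idx = split.fold_split(0)
model = STGCN(ds.X, ds.y, W=ds.W,
              config=ModelConfig(channels=(8, 16), epochs=30, seed=7))
res = model.fit(train_idx, val_idx)
res.evaluate(split.test_ids)
print(res.summary())
```

prints

```
ST-GCN classification results
========================================
blocks: 2  Kt: 3  widths: (8, 16)
nodes: 23  window: 25  flatten dim: 6256
train/val sizes: 115/13
epochs run: 30  checkpoint epoch: 18
best val loss: 0.0523
final train acc: 1.000  val acc at checkpoint: 1.000
test accuracy: 0.906
```

i.e. on held-out windows the graph model recovers the planted group
difference with 90.6% accuracy at this small cohort size.  The group
difference also localises: averaging `W` per group and ranking pairwise
differences

```python
hc = average_adjacency(ds.W, ds.minis, group="HC-like")
ad = average_adjacency(ds.W, ds.minis, group="AD-like")
print(top_pairs(group_difference(hc, ad), k=3))
# [(18, 20), (16, 22), (14, 20)]
```

returns posterior channel pairs — (18, 20) is T6-O2 vs P4-O2 — from the
planted set.

A command-line interface covers the same pipeline for file-based runs:

```
stgcn-eeg simulate --out cohort/ --seed 1 --effect 0.6
stgcn-eeg build-dataset --in cohort/ --out ds --band full --fc wc --seed 1
stgcn-eeg train --dataset ds --checkpoint model --epochs 30 --widths 8,16
stgcn-eeg evaluate --checkpoint model --dataset ds
```

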