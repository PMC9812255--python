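# Methods

This note documents the models, estimators and simulation conditions the
package implements, the defaults it ships with, and what the in-silico
validation does and does not establish.

## Problem setting

Two-class classification of resting-state scalp EEG (patient-like vs
control-like) from short multichannel windows.  A recording is reduced to
23 bipolar derivations (differences of neighbouring electrode potentials,
which remove the common reference and attenuate volume-conducted zero-lag
correlation), band-pass filtered, decimated to a 100 Hz working rate, and
cut into non-overlapping windows of M = 25 samples (0.25 s).  Each window
is one classification sample, described by two objects:

* `X` — the 25 x 23 window of channel time series;
* `W` — a 23 x 23 symmetric, nonnegative functional-connectivity adjacency
  matrix computed from that same window, with zero diagonal and no
  thresholding.

## Functional-connectivity estimators

Six pairwise measures can populate `W`:

| measure | domain | statistic |
|---|---|---|
| PC  | time | Pearson correlation of amplitudes (signed; rectified into W) |
| MSC | frequency | band mean of &#124;Sxy&#124;² / (Sxx·Syy), Welch averaged |
| IPC | frequency | band mean of &#124;Im Sxy/√(Sxx·Syy)&#124; |
| WC  | time-frequency | Morlet cross-spectra, time-smoothed, band-time mean |
| PLV | phase | &#124;mean exp(i Δφ)&#124; of Hilbert phases |
| PLI | phase | &#124;mean sign(Δφ)&#124; of Hilbert phases |

Estimator choices that the window length forces:

* **Welch configuration (MSC/IPC).**  Sub-segments of 12 samples with 50%
  overlap give three averaged periodograms inside a 25-sample window — the
  minimum averaging below which coherence is identically 1.  The coarse
  8.33 Hz bin grid cannot place a bin center inside narrow clinical bands;
  band averaging uses bins whose center falls inside the band (DC
  excluded) and falls back to the single nearest non-DC bin when none does.
* **Wavelet coherence.**  Morlet wavelets (center-frequency parameter 6)
  on 8 log-spaced frequencies per band.  Cross-spectra are smoothed in
  time over max(7 samples, 2 oscillation periods), capped at the window —
  smoothing proportional to scale, as is standard for wavelet coherence;
  a fixed short smoother would leave every slow scale biased to 1.
  Frequencies whose smoothing window does not fit at least twice into the
  segment yield a single smoothed estimate (coherence ≡ 1, the wavelet
  analogue of the cone of influence) and are excluded from the band grid
  when the band allows it; for a 25-sample window at 100 Hz this limits
  the informative grid to ≥ 16 Hz.  Narrow low bands (Delta/Theta/Alpha)
  have no resolvable scale at this window length; their per-window WC is
  computed on the nominal grid but is close to degenerate, which is a
  property of the estimator at this window length, not of the data.
* **Phase measures.**  The Hilbert transform is edge-dominated on 25
  samples, so the analytic signal is computed once per band-filtered 12-s
  epoch and per-window phases are sliced out (phases are per-sample, so
  slicing is exact).
* **Signed measures.**  Degree normalisation requires nonnegative weights,
  so PC (and the signed coherency under IPC) enter `W` as absolute values;
  the signed matrices are retained for analysis.

## Spectral graph convolution

For nonnegative symmetric `W` with degrees `D`, the normalised Laplacian
`L = I − D^{−1/2} W D^{−1/2}` has spectrum in [0, 2].  Chebyshev
polynomials of the rescaled Laplacian give K-hop-localised spectral
filters without eigendecomposition; the package implements the general
recurrence (`graphops.chebyshev_filter`, verified against explicit
eigendecomposition filtering) and uses in the network the first-order
renormalised form

    S = D̃^{−1/2} (W + I) D̃^{−1/2},   D̃ = diag(rowsums of W + I),

which is the K=2 Chebyshev filter with tied coefficients and the assumed
λmax ≈ 2, after adding self-loops.  Isolated nodes are safe after
renormalisation (D̃ii ≥ 1); the raw Laplacian uses the zero-on-zero
degree convention.

## Network architecture

The classifier stacks two spatio-temporal blocks:

    temporal conv (Kt=3, valid) → graph conv (Θ via S) → ReLU
    → temporal conv (Kt=3, valid) → layer normalisation

Each block shortens the window by 2(Kt−1): 25 → 21 → 17 time steps.  The
trunk output is flattened and mapped by a single dense unit and sigmoid to
the class-1 probability; training minimises binary cross-entropy with
Adam, and the parameters of the epoch with the lowest validation loss are
kept (the reported test accuracy always comes from that checkpoint).

The temporal-only baseline (`T-CNN`) is identical except that the graph
convolution is removed and the adjacency input is ignored.

Design points that the source description leaves open, resolved here:

* **Block count** 2 (the architecture diagram's configuration; a
  conflicting prose mention of three blocks exists), configurable.
* **Channel widths** default (16, 32); the benchmark runs use (8, 16)
  (see problem sizes below).
* **Layer normalisation** is taken over the whole (time, node, channel)
  feature map of each sample with a per-channel affine.  Normalising per
  node was tried and discarded: it erases the relative inter-node
  amplitude structure that the graph convolution creates, which is the
  main pathway by which `W` influences the prediction.
* **Optimiser** Adam, lr 1e-3, batch 64, 100 epochs default, weight decay
  available but 0 by default.
* **Networks are implemented directly on numpy** with hand-derived
  backward passes (verified against finite differences); the models are
  small enough that this is fast and exactly reproducible on one thread.

## Synthetic cohorts

No clinical recordings ship with the package, so a generator produces
surrogate cohorts with the study's structure: 19 patient-like and 20
control-like subjects, three artefact-free 12-s epochs per eye state
(closed/open), 23 channels at 100 Hz.

Each channel is a sum of five cosine oscillators, one per clinical band
(2, 6, 10, 20, 40 Hz) with ~1/f amplitude decay (1, 1/3, 0.2, 0.1, 0.05).
Oscillator phases follow a Kuramoto dynamic on a per-group coupling graph
κ ∈ [0, 1]^{23×23}:

    dφ_i = 2π f_i dt + 2π g Σ_j κ_ij sin(φ_j − φ_i) dt + σ √dt ξ,

integrated by Euler at 20× the sampling rate (stability is validated
against the per-step coupling magnitude), plus per-channel 1/f background
(scale 0.05) and white observation noise (sd 0.05).

The default physical scales were calibrated once, at design time, so that
the generator realises the qualitative regime the benchmark is meant to
emulate — strongly synchronised pairs versus decoherent pairs *within a
0.25 s analysis window* — and then frozen:

* **Relative frequency jitter 0.2** — each channel's oscillator b is
  detuned by a factor 1 + N(0, 0.2).  Proportional detuning makes the
  phase slip between two uncoupled channels over one wavelet kernel
  duration scale-invariant (detuning ∝ f, kernel ∝ 1/f), so uncoupled
  pairs decohere at every resolvable scale.  Without any detuning,
  same-frequency oscillators hold constant phase offsets and every
  synchronisation null breaks.
* **Coupling gain g = 35 Hz** — κ = 0.6 (the control group's posterior
  coupling) locks pairs through the detuning; κ = 0 drifts freely.
* **Phase noise σ = 1 rad/√s** — keeps spectral lines narrow enough that
  locked pairs reach high wavelet coherence while contributing steady
  decoherence to unlocked pairs.

The two-group benchmark plants the group difference of the study's
qualitative finding — weaker posterior coupling in the patient-like group
— on 10 fixed pairs among the 9 posterior derivations (temporal, parietal,
occipital), chosen with small per-channel degree for integrator stability:
control κ = 0.6, patient κ = 0.6 − effect (default effect 0.6, i.e.
patient coupling 0).  With effect 0 the groups are exchangeable by
construction.  No baseline coupling is placed elsewhere: pilot runs showed
that even a weak nearest-neighbour ring creates indirect partial
synchronisation that blurs the planted contrast.

What the generator does **not** emulate: volume conduction and its
zero-lag correlation structure, amplitude dynamics and cross-frequency
coupling, artefacts, non-stationarity across a recording session, and
realistic 1/f-dominated broadband spectra.  Passing the in-silico
benchmark therefore shows that the pipeline and models recover a planted
cross-channel phase-coupling difference at the study's window length — not
that they would attain any particular accuracy on clinical data.

## Validation problem sizes

The end-to-end benchmark uses deliberately compact conditions: 4 subjects
per group, one eye state, two 12-s epochs per subject (768 windows; 2/3
train/validation with a 10-fold partition, 1/3 held out), wavelet-coherence
adjacency on the full band, networks with widths (8, 16) trained for 30
epochs, five seeded replicates for each arm (planted effect: graph model
and temporal baseline; null: graph model).  The full-structure cohort (39
subjects, both eye states) is used where only counts matter.  These sizes
are the package's validation defaults; all are configurable.

Because windows from the same epoch can land in both train and test under
the window-level split (the study's own design), a small optimistic bias
is possible even under the null via epoch-level idiosyncrasies (each
epoch's realised detunings are fixed); the null arm of the benchmark
measures exactly this and lands near chance, bounding the effect.

## Known limitations

* Per-window wavelet coherence at 0.25 s / 100 Hz carries a substantial
  small-sample bias (white-noise floor ≈ 0.6–0.8 depending on scale); all
  group contrasts ride on top of it.
* The subject-hand-out split is implemented and tested but the shipped
  benchmark uses the window-level split; cross-subject generalisation of
  the classifier on synthetic cohorts is not part of the acceptance runs.
* MSC/IPC on 25-sample windows rest on three Welch sub-segments; their
  variance is high and narrow bands alias onto a single coarse bin.
* The EDF writer targets the plain continuous-EDF subset (one data-record
  layout, 16-bit quantisation over the per-channel range).
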