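# Methods

## Overview

`specembed` identifies peptides from HCD MS/MS spectra by embedding every
spectrum into a shared 256-dimensional unit-sphere latent space and
searching by cosine similarity.  Three sources feed the same space:
experimental library spectra, predicted spectra of database peptides, and
query spectra.  This note records the model, the simulator, the numerical
choices, and what the desk-scale experiments do and do not demonstrate.

## Vectorization

A peak at m/z *x* falls into bin ⌊(x − mz_min)/w⌋ for bin width *w*
(half-open bins, index non-decreasing in m/z).  Defaults: w = 0.1 Da over
[0, 2000) Da → 20 000 bins, zero-padded at the high-m/z end to 20 480 so
the length survives six halvings.  The m/z range is fixed so that 0.1-Da
bins give exactly 20 000 dimensions; peaks ≥ 2000 Da are dropped.
Within-bin intensities are summed (conserving ion current; `max` is a
config option) and the vector is divided by its base peak (L2 is a config
option).  The binned vector and its element-wise reversal form the two
encoder input channels.  Meta information rides in a 7-vector: charge
one-hot (1–4), neutral precursor mass / 5000 Da (clipped at 1; 5000 Da
keeps tryptic precursors inside [0, 1]), NCE / 100, and an NCE-present
flag (absent NCE → 0 with flag 0; the MGF key carrying NCE is
configurable since dialects differ).

Peptides are one-hot encoded as 30 × 20 binary matrices (rows = positions,
zero-padded past the sequence); sequences longer than 30 are rejected.
`C` denotes carbamidomethyl-cysteine throughout (fixed +57.021464 Da).

## Encoder, peptide branch, decoder

Six residual blocks of dilated 1-D convolutions (kernel 7; dilations 32,
16, 8, 4, 2, 1 so early blocks see wide receptive fields and deep blocks
narrow ones; channels ⌊16·1.5^b⌉ = 16…122; each block: conv–ReLU–conv,
1×1-projected residual, ReLU, stride-2 average pooling).  The pooled map is
flattened into a dense layer (84 units at full size); the meta vector
passes a sigmoid-activated linear layer (32 units); a **linear shortcut**
(ReLU, 32 units) taps the raw binned vector directly.  The three are
concatenated into the final dense layer and L2-normalized to the 256-dim
embedding.  Full-size encoder: ≈4.30 M parameters.

The shortcut is a deliberate design choice: raw binned vectors are already
highly discriminative, and giving the network a one-layer path to exploit
that makes optimization converge in a few epochs where the convolutional
stack alone needs far longer; the stack then refines what the linear path
cannot express.  For the same reason the model square-root-compresses
binned intensities at its input (`intensity_power` = 0.5, applied inside
the model so the vectorization contract and all "raw cosine" analyses stay
on plain binned vectors).

Peptide branch: 600 → 512 → 256 dense (ReLU between), L2-normalized.
Decoder (auxiliary): 256 → 256 → input-length dense, trained with MSE
against the clean (un-noised, compressed) binned vector, weight 0.1 — it
discourages embeddings that discard spectral detail.

Kernel size, dilation schedule, hidden widths and the decoder shape are
our choices; the architecture contract is the block count, the shrinking
receptive fields, the ~1.5× channel growth, the sigmoid meta projection
and the 256-dim normalized latent space.

## Training

Additive-margin softmax on cosine logits between spectrum embeddings and
the peptide-branch anchors of the batch's unique peptides (each unique
peptide = one class; cross-modal anchors keep the model usable for unseen
peptides via predicted spectra).  Defaults s = 30, m = 0.35 — the regime
recommended for am-softmax — with margin-zero reduction to plain softmax
cross-entropy verified analytically in the tests.  Per-peptide replicate
cap 10; one replicate per multi-replicate peptide held out for validation;
singleton peptides dropped from both roles.  Gaussian noise
(σ = 0.01 × base peak, clipped at 0) is added to inputs each epoch,
training only.  Rectified Adam (β = 0.9/0.999; momentum-SGD fallback while
the rectification term is undefined; plain Adam behind a flag), default
learning rate 0.0072, batch 32.  The returned weights are those of the
epoch with the best held-out top-1 retrieval accuracy against all
training-class anchors.  One model per precursor charge; spectra of other
charges are parsed but routed out of search unless a matching model is
supplied.  All randomness flows from a single integer seed; runs are
bit-reproducible single-threaded.

The network is pure numpy with a small tape-based reverse-mode autodiff
engine (conv1d via im2col, float32 parameters, float64 softmax head),
checked against finite differences in the test suite.

## Synthetic data

The simulator makes the pipeline runnable with no downloads and defines
the study conditions for the desk-scale experiments.

* **Peptides**: uniform residues with a K/R C-terminus ("tryptic-like"),
  lengths 8–20 by default within the global 6–30 window.
* **Theoretical spectra** (the predicted-spectrum stand-in): all b/y
  fragments (b_k = Σ first k residues + proton; y_k = Σ last k + water +
  proton; charge-z m/z = (m + (z−1)·proton)/z), intensities from a
  Gaussian bell over cleavage position (mid-sequence strongest, width
  0.25·L) with the y-series weighted 1.5× the b-series — a crude but
  recognizable HCD caricature.  Fragment masses are verified against an
  independent calculator to 1e-4 Da.
* **Replicates**: log-normal multiplicative intensity jitter (σ = 0.8),
  peak dropout (p = 0.2, never dropping the last peak), m/z jitter
  (σ = 0.005 Da), and 15 uniform-m/z noise peaks up to 0.15 × base peak.
  These defaults were calibrated once so that same-peptide replicate pairs
  span a broad raw-cosine range (roughly half below 0.5) — the regime in
  which latent-space amplification matters — and then frozen.
* **Benchmarks**: a library of one noisy replicate per peptide, queries as
  fresh replicates of library peptides plus a floor(fraction × n) block of
  foreign-peptide queries drawn disjoint from the library; ground truth
  travels in a separate map, query spectra are unannotated.

What the simulator does **not** emulate: learned sequence-specific
fragment intensities, neutral losses, isotope envelopes, a/c/x/z ions,
co-isolation/chimeras, retention time, or precursor-mass error (replicate
precursors are exact, so the 10-ppm window is exercised by construction
only through decoys and mass-coincident peptides).  Passing desk-scale
tests therefore demonstrates the *mechanics* — metric learning separates
classes, FDR control calibrates, hybrid merging helps — not performance on
real instrument data.

## Digestion

Cleavage after K/R, suppressed before proline by default (the common
search-engine convention; a flag disables it), up to 2 missed cleavages,
length 6–30, fixed carbamidomethyl-C; peptides deduplicate by sequence
with accession merging and minimum missed-cleavage count.  N-terminal
methionine removal is not applied.  I/L are kept distinct; an
I/L-collapsed ambiguity report is available.  The implementation is
checked for exact equality against an independent substring-enumeration
oracle on random proteins.

## Search and FDR

Candidates must match the query's charge and precursor m/z within a ppm
tolerance (default 10 ppm, applied on m/z).  The top cosine hit among
targets and decoys is reported; ties break toward the decoy
(conservative), then lexicographically.  Queries with no candidate are
excluded from the FDR denominator.  Decoys are 1:1 interior shuffles
(first and last residues fixed, so length, composition, terminal residues
and mass are preserved), re-predicted and re-embedded; collisions with
target sequences are re-shuffled up to 20 times, then dropped.  Decoy
generation by sequence shuffle + re-prediction (rather than perturbing
experimental peaks) is a deliberate choice: it produces decoys in exactly
the same embedding regime as database entries.

FDR above a score threshold = decoys/targets (the +1 variant is a flag);
q-values are the running minimum of FDR from high scores downward; the
peptide level collapses to the best score per bare sequence first (a flag
keys on sequence + charge).  The reported cutoff is the lowest threshold
with q ≤ α (default α = 0.01).

Hybrid libraries union experimental and predicted entries keyed by
(peptide, charge); experimental vectors win where both exist.  The indexed
search is tested for exact agreement with a dense linear-scan oracle.

## Desk-scale experiment sizes

The reduced configuration used by the tests and the acceptance script:
0.5-Da bins over [0, 1000) Da padded to 2048; base_channels 4 (≈0.4 M
parameters); 100 peptides × 6 replicates; 30 epochs; benchmarks of 500
queries (FDR calibration, 50 % foreign) and 300 queries (hybrid, 50 %
experimental coverage).  These sizes keep a full run to a few minutes on
one CPU while leaving every stage statistically meaningful.

## Known limitations

* Desk-scale only out of the box: full-scale (20 480-bin) training works
  but is impractical without a GPU framework; the full-size encoder is
  instantiated only for architectural checks.
* Charges 1+/4+ are parsed but have no trained models by default.
* No variable modifications; MSP blocks carrying them are skipped.
* The theoretical-spectrum generator is a stand-in for a learned intensity
  predictor; any callable `(peptide, charge) -> Spectrum` can replace it
  (`predictor=` argument) to upgrade database/hybrid mode.
* FDR estimates at very small decoy counts are coarse; the D/T estimator
  reports 0 when no decoy outscores a threshold.
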