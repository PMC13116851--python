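# Methods

## Model

A specimen is a set of `N` named anatomical views. One shared-weight encoder
maps every view to an embedding `v_i ∈ R^D`; sharing is deliberate — it
caps parameter growth with the number of views and makes the per-view
compute cost a single constant, which is what makes the FLOPs accounting
below exact. The encoder is a registry behind one contract:

* `feature-mlp` — a two-layer MLP (hidden 64, ReLU) over precomputed
  per-view feature vectors; the default for the synthetic studies.
* `reference-tiny` — three strided convolutions (3→16 s4, 16→32 s2,
  32→64 s2) followed by learnable-query cross-attention pooling
  (`n_queries` queries attend over the spatial positions, outputs
  concatenated and projected to `D`). Random initialisation; a production
  backbone can be registered under the same contract.

Images are resized to `input_size` (224×224 default, bilinear), scaled to
[0, 1] and channel-normalised (0.5/0.5 for randomly initialised backbones).
Training-time image augmentation applies random flips, rotation within
±60°, colour jitter and random erasing, each with configurable probability;
feature-mode training applies Gaussian feature jitter instead (below).

Fusion tokens are `e_i = v_i + PE_i` with a learnable per-view-slot
positional vector `PE_i`: views are an unordered set, so `PE` encodes *which
view* a token is, not a sequence position — the fused output is invariant to
token order. One transformer encoder block (8-head self-attention, residual
connections, feed-forward ratio 4, no normalisation layers at this scale)
processes the active tokens; inactive tokens are masked out of the attention
keys and of the mean pool, so a view gated to exactly zero is
indistinguishable from a view that was never supplied. The pooled vector
feeds a linear softmax classifier, and — during training only — a linear
projection head whose output carries the contrastive loss.

## Gates

Each view owns a logit `α_i`. Training samples

```
s = σ((log u − log(1−u) + α_i)/β),  u ~ U(0,1)
z_i = clip(s·(ζ−γ) + γ, 0, 1),      ζ = 1.1, γ = −0.1
```

The stretch places positive probability on exactly 0 and exactly 1 while the
sampler stays differentiable in `α` wherever the clip is inactive. Closed
forms used throughout (and verified by Monte-Carlo in the tests):

```
P(z > 0) = σ(α − β·log(−γ/ζ))                (retention probability)
P(z = 0) = 1 − P(z > 0)
P(z = 1) = σ(α − β·log((1−γ)/(ζ−1)))
E[L0]    = Σ_i P(z_i > 0)                     (the sparsity penalty)
```

With the default stretch both interior log-odds equal `log 11`, so at
`α = 0, β = 0.67` the retention probability is 0.8329 and both boundary
masses are 0.1671.

The temperature anneals linearly from 0.67 to 0.1 over the sampling phase
(the endpoints are fixed; linear is the simplest monotone schedule and is
configurable). One noise draw is taken per view per forward pass, shared
across the batch. At test time gates are replaced by the deterministic mask
`P(z_i > 0) > 0.5` (threshold configurable); dropped views are not encoded
at all.

## Objective and optimisation

```
L_total = L_CE + λ_contrast·L_contrast + λ_sparsity·E[L0]
```

* `L_CE`: mean negative log-probability of the true species (probabilities
  clamped at 1e-12, clamping logged).
* `L_contrast`: supervised contrastive loss, τ = 0.1, weight 0.2, computed
  on the projection of the fused specimen representation (the loss targets
  specimen-level sibling-species separation; per-view variants are a
  different design). Anchors without an in-batch positive are skipped, so
  batches are assembled from same-class pairs (a class-balanced pair
  sampler; odd leftovers simply become skipped anchors).
* `E[L0]`: the expected retained-view count, weighted by the swept
  `λ_sparsity`.

AdamW (decoupled weight decay) trains everything except the gate logits,
under a cosine-annealing-with-warm-restarts factor. The gate logits form
their own plain-SGD group with a larger learning rate and no weight decay:
an adaptive optimiser would normalise the near-constant penalty gradient to
full step size whatever `λ` is, erasing the trade-off the sweep exists to
trace, and weight decay would drag every logit toward the 50/50 point
regardless of the data.

Training ends with a hard-selection fine-tuning phase: over the last
`freeze_fraction` (default 0.2) of the epochs the gates are frozen to the
deterministic mask, sampling noise and the sparsity penalty are switched
off, and the surviving configuration trains to convergence. The reported
per-λ accuracy is therefore the accuracy of the selected view subset as a
properly trained model, not of a model still subject to gate churn.

Two stages mirror the intended workflow: `train_single_view` fits the shared
encoder with one linear head per view and benchmarks every view alone (the
best row is the single-view baseline); `train_fusion` trains the full gated
model, optionally from the stage-1 encoder, fine-tuning everything (the
production defaults — lr 1e-6, weight decay 5e-3, 300 epochs, warm restarts
of period 10 doubling per cycle — are fine-tuning settings for a pretrained
backbone and live in `TrainConfig`).

## Sweep, FLOPs, selection

One independent, freshly initialised training run per λ (default grid
{0.1, …, 0.5}), all under the same seed policy, plus a λ = 0 baseline
trained with the gates pinned open — the ungated all-view fusion model.
FLOPs cover the per-view encoder only and are linear in the retained views:
`cost(k) = k · per_view_cost`, with the per-view cost measured analytically
from the encoder geometry or derived as `baseline/N` when a measured
baseline is supplied. Report cells are rounded to 2 decimals half-up, and
the drop/saved columns are computed *from the rounded cells*, which is the
convention that makes the published reference tables internally consistent
(8 views at 11.31 G → 5 views at 7.07 G → 37.49 % saved). Where the rounded
convention and a printed cell disagree (two cells of the 11-view reference
sweep), the computed value is used.

The recommended configuration minimises the view count among records whose
accuracy drop from the all-view baseline is at most the margin (1.0 pp
default); ties break by lower FLOPs, then higher accuracy, then lower λ —
the accuracy term keeps the selection on the Pareto frontier of qualifying
records. If nothing qualifies, the baseline is returned. Labels follow the
report convention: all-view (N views), single-view (1), recommended (the
selected record), reduced (qualifying but larger), aggressive (beyond the
margin, more than one view).

## Synthetic data

The generator emulates a multi-view survey: `C` classes × `V` views, with a
planted informative subset `S`. Class identity is distributed over `S`
through an integer code — class 0 is all-zero, classes 1..|S| flip one digit
each, remaining classes take constant codes — so the code is injective over
all of `S` and, whenever `C ≥ |S| + 1`, every view in `S` is necessary.
`S` is then the *unique minimal sufficient subset*, which is what makes
Jaccard-against-`S` recovery a well-posed benchmark. In feature mode, view
`j` of a class-`c` specimen is a fixed direction of norm `signal_strength`
determined by the code digit (plus an optional class-shared component
controlled by `redundancy_rho`), in Gaussian noise of sd `noise_sd`; views
outside `S` are pure noise. In image mode the digits are rendered as
positioned bars in small RGB images, nuisance views share one
class-independent template, and the dataset can be written as the same
manifest-CSV + image-folder layout the real-data reader consumes.

Reference study conditions: feature mode, `C = 6`, `V = 8`, `S = {0, 3, 5}`,
signal 3, noise 1, 240 train / 60 validation, stratified. At these
conditions a logistic-regression oracle on the true subset reaches ≈ 93–98 %
validation accuracy, single informative views reach ≈ 55–70 % (their
code digit only partially separates the classes), and nuisance views sit at
chance — the geometry the gating mechanism must discover. What the
generator does **not** emulate: photorealistic anatomy, inter-lab
colour-temperature variation, occlusion structure, specimen damage, or
label noise; passing the synthetic studies shows the selection machinery
recovers a planted minimal subset under realistic noise, not that any
particular accuracy transfers to real surveys.

## Desk-scale settings

The estimator defaults are the settings of the synthetic reference studies:
embedding 32, one fusion block, 200 epochs with a single cosine cycle,
lr 5e-3 (AdamW, weight decay 1e-4), gate lr 0.3 (SGD), batch 60,
Gaussian feature jitter of sd 0.8 during training. The jitter is the
feature-space analogue of the image augmentation pipeline; without it the
tiny network overfits 240 specimens and run-to-run validation variance
(±10 pp on 60 samples, where one sample is 1.67 pp) swamps the 1-pp margin
rule. One full sweep (baseline + 5 λ values) takes ≈ 30 s on one CPU; the
10-seed recovery study ≈ 6 minutes.

## Numerical choices and degenerate inputs

* All computation is float64 on a small reverse-mode autodiff tape; the
  clip in the gate sampler propagates zero gradient in the clipped region.
* Softmaxes are computed with a detached max shift (identical values and
  gradients, no overflow).
* Noise components of the gate sampler must lie strictly inside (0, 1);
  u = 0 or 1 is rejected (the logit is undefined there).
* Accuracy is reported as a percentage rounded to 2 decimals half-up;
  `predict_topk` breaks probability ties by class index (stable sort).
* An all-suppressed model (every gate closed) cannot fuse; evaluation then
  falls back to the training-majority class, which is the rate such a model
  degenerates to. If every gate samples shut in a single training step, the
  view with the largest logit is kept for that step.
* A batch of one specimen is rejected by the contrastive loss; a manifest
  with duplicate (specimen, view) rows, missing columns, or no rows is
  rejected at read time; unreadable images and specimens missing views are
  collected into load reports (batch training uses complete specimens
  only — single-specimen prediction handles absent views as inactive
  tokens).

## Known limitations

* Gating is global (one mask for the task), not instance-conditional; group
  sparsity and straight-through variants are out of scope.
* The all-view baseline trains without gates; with many pure-noise views it
  can trail the pruned configurations — on real surveys, where most views
  carry some signal, the gap direction may differ.
* FLOPs accounting ignores the fusion block (its cost is shared and small
  relative to per-view encoding, and the linear-in-views convention is what
  the reference tables use).
* Confidence scores from the softmax head are not calibrated.
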