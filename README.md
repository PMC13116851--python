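# viewgate

Differentiable minimal-view selection for multi-view fine-grained specimen
identification.

## The problem

Species-level identification of disease vectors (mosquitoes, flies) relies on
minute diagnostic structures — mesonotum chaetotaxy, hypopleural setae, wing
venation — so imaging pipelines photograph each pinned specimen from several
standardised anatomical *views*. Capturing and encoding every view is
expensive, and many views carry little diagnostic signal for a given
taxonomic task. `viewgate` learns **which views matter**: it trains a
multi-view classifier with stochastic Hard-Concrete gates on the views,
sweeps the sparsity pressure to trace the accuracy-vs-compute Pareto
frontier, and recommends the smallest view subset whose accuracy stays
within a margin of the all-view model.

## The model

Each view image (or precomputed view feature vector) is embedded by one
**shared-weight encoder** into `v_i ∈ R^D`; a learnable view-slot positional
vector gives the fusion token `e_i = v_i + PE_i`. A per-view gate
`z_i ∈ [0, 1]` is sampled from the stretched, clipped binary-concrete
(Hard-Concrete) distribution

```
z_i = clip( σ((logit(u) + α_i)/β) · (ζ − γ) + γ, 0, 1 ),   u ~ U(0,1)
```

with stretch `ζ = 1.1, γ = −0.1` (so exact 0/1 have positive mass) and
temperature `β` annealed 0.67 → 0.1. Gated tokens `z_i ⊙ e_i` are fused by a
transformer block (8-head self-attention, masked to active views, mean-pooled)
and classified by a linear softmax head. Training minimises

```
L_total = L_CE + λ_contrast · L_contrast + λ_sparsity · L_L0
L_L0    = Σ_i σ(α_i − β·log(−γ/ζ))          (expected number of kept views)
```

where `L_contrast` is the supervised contrastive loss (τ = 0.1,
λ_contrast = 0.2) on the fused representation. A grid search over
`λ_sparsity ∈ {0.1, …, 0.5}` produces one retained-view set per weight; FLOPs
are linear in the retained views (dropped views are never encoded); the
**recommended configuration** is the fewest-view entry within 1 percentage
point of the all-view baseline.

## Worked example

The synthetic generator plants a known informative subset `S` (here views
{0, 3, 5} of 8, across 6 species, 240/60 train/val): any single view in `S`
only partially separates the classes, any proper subset of `S` leaves at
least two species indistinguishable, and `S` itself is sufficient — so `S`
is the unique minimal diagnostic set the sweep should rediscover.

```python
from viewgate import SyntheticSpec, generate, SparsitySweep, GatedMultiViewClassifier

spec = SyntheticSpec(seed=0)               # 6 species x 8 views, S = {0, 3, 5}
ds = generate(spec)
sweep = SparsitySweep(GatedMultiViewClassifier(), random_state=0)
sweep.fit(ds.X_train, ds.y_train, X_val=ds.X_val, y_val=ds.y_val)
print(sweep.dataframe_.to_string(index=False))
```

```
  λ  Number of Parts  Accuracy (%)  Accuracy Drop (%)  FLOPs (G)  FLOPs Saved (%) Configuration
0.0                8         95.00               0.00        0.0              0.0      All-view
0.1                3         95.00               0.00        0.0             62.5       Reduced
0.2                3         96.67              -1.67        0.0             62.5   Recommended
0.3                1         61.67              33.33        0.0             87.5   Single-view
0.4                1         61.67              33.33        0.0             87.5   Single-view
0.5                1         60.00              35.00        0.0             87.5   Single-view
```

The recommended row retains exactly `['view_00', 'view_03', 'view_05']` —
the planted subset — at 96.67 % versus the 95.00 % all-view baseline, for a
62.5 % cut in encoding cost (the FLOPs column rounds to 0.00 G because the
reference feature encoder costs only ~6·10⁻⁶ G per view; the Saved column is
computed from the unrounded costs). A negative drop means the reduced model
*beat* the baseline: the pruned views were pure nuisance.

The same selection rule runs on any precomputed sweep table. On the published
8-view fly survey sweep shipped with the package:

```bash
python - <<'PY'
from viewgate.benchmarks import fly_sweep_table
fly_sweep_table().to_csv("fly.csv", index=False)
PY
viewgate select --sweep-csv fly.csv
# recommended: lambda=0.4 parts=5 accuracy=86.11 flops=7.07
```

i.e. 5 of 8 anatomical parts, a 0.93-pp drop from the 87.04 % baseline, and
37.49 % of the 11.31 G cost saved.

## Command line

`viewgate` exposes `simulate`, `train-single`, `train-fusion`, `sweep`,
`select`, `predict` (top-3 species with confidences, CSV) and `report`,
driven by a YAML run config (strictly validated; every run writes a config
snapshot, seed record, loss log and gate-trajectory CSV).

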