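# dama

Supervised community detection on static graphs with propagation-aware
influence modelling, adaptive neighbourhood sparsification, and gated
multi-hop attention.

Community detection — recovering the densely connected modules of a
network — underpins the analysis of social groups, protein-interaction
modules and citation fields. Purely structural detectors (modularity
maximisation, stochastic block models) ignore how *information decays*
as it propagates through a static topology. This package implements a
model that injects that propagation structure into a graph neural
classifier, in three stages:

1. **Influence matrices.** A potential-based influence matrix scores each
   node pair by common-neighbourhood overlap damped exponentially with
   shortest-path distance,
   `p_ij = |Γ(v_i) ∩ Γ(v_j)| · exp(−λ d_ij)` (λ = 0.3), and the
   information-flow matrix blends it with the adjacency,
   `IFM = β·P + γ·A`.
2. **Adaptive sparse sampling.** Per node, hop neighbourhoods Γ(1)..Γ(K)
   (K = 3) are grown under a dynamic threshold
   `r(k) = μ · AVG{a_jh}` over frontier→neighbour influence intensities;
   only neighbours reaching the threshold are retained, and expansion
   stops early when the layer-mean intensity stagnates. This prunes
   low-influence (often noisy, cross-community) connections.
3. **Gated multi-hop attention.** Per-hop multi-head attention with a
   learnable distance decay `Φ(d) = exp(−λ d)` aggregates the retained
   members into hop embeddings (8 heads × 16 dims), which a dual gate —
   a per-node prior `softmax(W_r·[deg, max a])` modulated by a batch
   feedback gate `tanh(W_f·Std(H))` — fuses for an MLP classifier.
   Training minimises cross-entropy plus a κ-weighted L1 gate penalty
   (Adam, lr 1e-3, weight decay 1e-4, 200 epochs, 80/20 transductive
   split).

Evaluation reports accuracy, NMI, macro-F1 and ARI on the test mask and
Newman modularity `Q = (1/2m) Σ_ij (A_ij − k_i k_j/2m) δ(c_i, c_j)` of
the predicted whole-graph partition.

The neural network runs on NumPy via a small in-repo reverse-mode
autodiff engine — no deep-learning framework is required.

## Worked example

Train and evaluate on a synthetic LFR-style benchmark (300 nodes,
average degree 8, 20% cross-community mixing), three seeded repeats:

```python
from dama.pipeline import RunConfig, run_pipeline
from dama.training import TrainConfig

cfg = RunConfig(
    dataset={"kind": "lfr", "n": 300, "avg_degree": 8, "mu_mix": 0.2,
             "min_community": 15, "max_community": 40, "seed": 7},
    train=TrainConfig(epochs=200), repeats=3, seed=7)
res = run_pipeline(cfg)
print(res["aggregate"])
```

Output (abbreviated):

```
accuracy:   mean 0.978  std 0.008
nmi:        mean 0.977  std 0.008
f1_macro:   mean 0.975  std 0.010
ari:        mean 0.955  std 0.020
modularity: mean 0.703  std 0.002
```

Mean test accuracy/NMI near 0.98 means the classifier recovers the
planted communities almost perfectly from 80% labelled nodes; the
predicted-partition modularity (0.703) sits at the ground-truth
partition's own value for this mixing level, i.e. the predicted
communities are as internally dense as the planted ones.

The same pipeline is scriptable from the shell:

```sh
dama generate --kind lfr --n 300 --avg-degree 8 --seed 7 --out scratch/lfr
dama train --seed 7 --repeats 5          # default planted-partition config
dama sweep --mu 0.5 --mu 1.0 --lam 0.3 --repeats 5 --out sweep.csv
dama ablate --repeats 5                  # full vs no-IFM / no-ASS / no-MSG
```

Real datasets are loaded from local files (`read_edge_list`,
`load_linqs_bundle` for citation bundles in the linqs text format);
nothing is downloaded.

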