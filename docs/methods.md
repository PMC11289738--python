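# Methods

This note documents the modelling choices, numerical conventions, and known
limitations of `pathpred`, in the spirit of the model documentation shipped
by mature scientific packages.

## Data model

A pathway network is G = (V, E, F, H, X): entities V (nodes), reactions E
(hyperedges), attributes F, the binary incidence matrix H with
role-restricted variants H_s (input roles) and H_t (output roles), and the
binary attribute matrix X. H is the elementwise OR of H_s and H_t; an
entity may legitimately hold both roles in one reaction (catalysts,
regenerated cofactors), in which case H stores a single 1. Row/column
order is declaration order and is immutable for a network's lifetime, so
matrices, embeddings and rankings all index consistently; masking
operations return new networks and never mutate.

Matrices are stored as scipy CSR (real pathway networks have ~10³–10⁴
nonzeros in 10⁶–10⁷-cell matrices) but all semantics are dense {0,1}.
Isolated entities (degree 0) are legal; every degree normalisation uses the
pseudo-inverse convention 1/0 → 0, so an isolated node's embedding row is
exactly zero rather than NaN.

## Representation models

The three layer models share one scheme: a propagation matrix P applied per
layer, Z⁽ˡ⁺¹⁾ = σ(P Z⁽ˡ⁾ Θ⁽ˡ⁾), with Z⁽⁰⁾ = X.

* HGNN: P = D_v^(−1/2) H W D_e^(−1) Hᵀ D_v^(−1/2)
* HGNN⁺: P = D_v^(−1) H W D_e^(−1) Hᵀ
* GCN: P = D^(−1/2) A D^(−1/2) with A = H Hᵀ taken exactly — integer
  co-membership weights, the natural diagonal (A_vv = node degree), no
  added identity and no thresholding.

Design choices where the formulation is open:

* **Layers are bias-free**; the only bias in the package is in the
  attribute classifier. This keeps the zero-input fixed point (X = 0 ⇒
  Z = 0) exact, which the explainer's empty-coalition baseline relies on.
* **Depth defaults to 2** — enough to mix second-order hypergraph
  neighbourhoods while training in seconds at desk scale.
* **Hidden activation is the rectifier; the final layer is linear.**
  A squashed final layer would bound the inner-product scores away from
  confident probabilities.
* **First-layer width is |F|** (Θ⁽⁰⁾ ∈ ℝ^|F|×D, later layers D×D), since
  the layer input is X.
* **Hyperedge weights W = diag(w) are trainable**, parameterised as
  w = exp(ρ) with ρ initialised to 0 (W = I) so positivity is structural.
  GCN has no hyperedge weights.

The MF model is Ĥ = μ + b_z 1ᵀ + 1 b_rᵀ + Z Rᵀ. μ ("global average
rating") is fixed to the mean of the training incidence cells before
optimisation; biases and factors are trained. The all-ones matrices of the
model statement are broadcast shapes, never materialised. MF link rankings
use the reaction's column of sigmoid(Ĥ) directly, since the model already
learns a hyperedge factor.

## Training

Both tasks minimise mean elementwise binary cross-entropy. The printed
cross-entropy H(p, q) = −Σ p log q instantiates as the binary form because
the targets are multi-label incidence/assignment columns, not one-hot
distributions. Probabilities are clamped to [1e−12, 1−1e−12] before logs.

* **Link tasks.** Message passing uses the (train-masked) H; labels are the
  columns of H_s (input task) or H_t (output task). Per epoch, all
  reaction readouts are computed at once through a row-normalised
  membership matrix, scored against all nodes, and the full |E|×|V| BCE is
  the loss — no negative sampling, since desk-scale and database-scale
  matrices both fit in memory. Readouts during training use the direction's
  own members; a reaction with no members on that side contributes a zero
  readout (scores 0.5). At prediction time the readout falls back to all
  known members when the directional set is empty, which keeps queries for
  one-sided reactions meaningful. The held-out candidate never contributes
  to its own query embedding (it is absent from the train network), which
  is the leakage control.
* **Attribute task.** A linear classifier m_v = sigmoid(W z_v + b) is
  optimised jointly with the representation model against the rows of X.
  Held-out assignment cells are removed from the input features **and**
  masked out of the loss mean, so they are neither visible nor penalised as
  negatives. With `model="mf"` the embeddings are free parameters (the
  factorisation target would otherwise be the label matrix itself).
* **Optimiser.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), implemented in
  numpy together with the hand-derived adjoints of the layer stack,
  the readout/score head and the hyperedge-weight chain (validated against
  finite differences in the test-suite's oracle checks). The graph models
  take full-matrix steps; MF takes entry minibatches (default 128 cells)
  with *lazy* Adam — moment updates and bias corrections applied only to
  the rows a minibatch touches, under a global step counter — because
  full-array moments per 128-cell step would dominate runtime without
  changing the optimum.
* **Defaults** follow the benchmarked settings: embedding dimension from
  {64, 128, 256} (package default 128; 64 for MF, see Limitations),
  learning rate from {0.05, 0.01, 0.005} (default 5e−3), 200 epochs.
  Training aborts with a diagnostic if the loss becomes non-finite.
* **Determinism.** All randomness flows from named seeded substreams of
  `--seed` / `random_state`; identical seeds give bit-identical
  initialisations, splits and sampled explanations, and loss trajectories
  identical up to floating-point reduction order.

## Evaluation protocol

Held-out units are single relationships. The 8:1:1 random split draws
validation and test pairs without replacement in seeded order, skipping any
pair whose removal would leave a reaction with no members at all (the
readout would be undefined as a label source); sizes use floor rounding
with the remainder in training. "Five-fold" reporting is implemented as
five independent seeded re-splits with mean ± sample standard deviation —
true disjoint fold partitioning would contradict a 10% test share, so
repeats are the consistent reading.

NDCG@K uses binary gains with 1/log₂(rank+1) discounting and an ideal-DCG
normaliser of min(|relevant|, K) leading hits; ACC@K is the top-K hit
indicator. Multiple held-out pairs of one query in the same subset are
evaluated together as multiple relevant items. Cutoffs default to
K ∈ {1, 10}; the full-ranking value is additionally exposed as `NDCG@inf`.
Candidates already linked in the training network are excluded from every
ranking, so held-out items are always rankable.

The temporal protocol diffs two database versions and scores only
*additions* whose entity and reaction both exist in the older version;
additions involving new ids and removals are counted but never scored.

## Shapley explainer

The explained unit is one predicted link (reaction e, candidate c). The
player set is the reaction's current member nodes plus the attributes of
those members — one joint game, matching explanation outputs that rank
nodes and attributes on a single scale. (Two separate games, nodes then
attributes, would be an alternative reading; the joint game was chosen so
the efficiency identity covers the complete masking space.) Masking a node
removes only its membership in the query reaction — ablating its
participation in this prediction, not deleting the entity — while masking
an attribute zeroes one (entity, attribute) cell of X. Model parameters
are frozen throughout; only inputs are masked. Coalition values are scored
through the readout route (mean member embedding dotted with the candidate
embedding) for every model kind; for MF, whose node factor does not depend
on X, attribute players are structurally null while node players still act
through the readout. The empty coalition gives a zero readout and value
sigmoid(0) = 0.5, the reported baseline.

Exact Shapley values are computed by subset enumeration up to 16 players.
Above that, uniformly sampled player permutations average marginal
contributions under an evaluation cap (default 1024 value calls, each a
forward pass on a masked network); permutation sampling is unbiased and
preserves the efficiency identity Σφ = f(N) − f(∅) exactly, because each
permutation's marginals telescope. Coalition values are memoised, so the
value of a coalition depends only on its membership.

## Synthetic data generator

The generator plants the two signals the models exploit in real pathway
data: functional modules (co-occurring entities with shared attribute
pools) and reaction chaining (outputs feeding the next reaction's inputs).
Defaults: 4 modules × 50 entities / 40 reactions / 30 attributes; 2–4
inputs and 1–2 outputs per reaction; chain probability 0.6; cross-module
input probability 0.05; attribute noise 0.05; 2–4 attributes per entity.
This yields ~200 entities, ~160 reactions, 3–6 members per reaction, and a
~5% random top-10 hit rate — sparse enough that rankings are non-trivial,
small enough that a full 200-epoch training run takes ~1 s on one CPU.
"Noise" redirects an intended module-pool assignment to a uniformly random
attribute with the given probability, i.e. it corrupts individual
assignments rather than flipping independent cells of X (an independent
per-cell flip at any useful rate would swamp each entity's few real
attributes with ~|F|·p spurious ones and change the task, not just add
noise).

What the generator does *not* emulate: stoichiometry, hub entities with
heavy-tailed degrees, nested complexes, or semantically structured
attribute hierarchies. Passing the planted-signal tests therefore shows
that the models recover module- and chain-shaped co-membership structure —
the structure they are built to exploit — not that they match any
particular curated database's benchmark numbers.

The ablated configuration (chain 0, cross-module 0, attribute noise 0.5)
is shipped as a negative control. Note its limits: it removes chaining and
degrades attribute purity, but reactions still draw members from a single
module, so the incidence matrix retains strong co-membership block
structure and link prediction remains learnable at roughly the
module-size ceiling (~10/50 for top-10). A fully signal-free control would
need a single module or uniform cross-module membership.

## Known limitations

* **MF at desk scale.** With the default synthetic network (32 000
  incidence cells) the biased factorisation has more free parameters than
  cells at every benchmarked dimension, interpolates the training matrix
  exactly (BCE → 0), and transfers no signal to held-out cells. The
  package uses D = 64 for MF (its best setting) and documents that MF link
  accuracy at this scale is near chance; on database-scale matrices
  (10⁶–10⁷ cells) exact interpolation is impossible and the model behaves
  like an ordinary low-rank recommender.
* Layer-model training at the default learning rate moves the full-matrix
  BCE slowly (most cells are confident negatives); rankings stabilise long
  before the loss approaches its floor.
* The explainer's cost is one forward pass per coalition; explanations of
  reactions with many members and attributes are estimates under the
  evaluation cap, with seed-reproducible sampling error.
* No calibration of output probabilities, no early stopping, no
  hyperparameter search automation; the exposed grids are the benchmarked
  ones.
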