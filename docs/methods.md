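# Methods

## Model

The predictor treats lncRNA–disease association discovery as supervised link
prediction on a bipartite graph, under the guilt-by-association assumption:
similar lncRNAs associate with similar diseases and vice versa. Entities are
described only by similarity profiles derived from (a) the disease hierarchy
and (b) the known association matrix itself; no sequence or expression data
enter the model.

### Disease DAGs and semantic similarity

A disease's DAG contains the disease plus every vocabulary term owning a tree
number that is a strict segment-wise prefix of one of the disease's tree
numbers; a disease with several tree numbers gets the union of ancestor sets.
Edges link each node to the term owning the *nearest present* prefix, so the
graph stays connected when an intermediate hierarchy level has no vocabulary
entry (with a prefix-closed vocabulary this coincides with immediate-prefix
parenthood).

Model 1 (decay) assigns the root contribution 1 and each ancestor
`max(Δ · child contribution)` over its in-DAG children — the only
well-defined reading, since children outside the DAG have no contribution to
propagate. `Δ = 0.5` by default, the conventional value for this similarity
family. The recursion is evaluated children-first (memoized), so a node kept
by several paths carries the weight of its shortest path.

Model 2 (information content) assigns `−log(count(t)/n)` with the natural
logarithm; the base is a free choice that rescales all contributions by a
constant, which does **not** cancel in the similarity ratio (shared-node sums
over total sums weight nodes relatively), so it is fixed and documented here.
Membership counts are taken over the diseases of the dataset at hand, not the
whole vocabulary: the information content is then relative to the corpus the
model is trained on. A degenerate corpus in which every node appears in every
DAG makes both semantic values zero; self-similarity is defined as 1 there
(identical node sets) and 0 otherwise.

Similarity is the summed shared-node contribution from both sides divided by
the sum of semantic values. It is symmetric, lies in [0, 1], equals 1 exactly
for identical contribution maps, and equals 0 for ancestor-disjoint DAGs.

### GIP kernels and integration

The Gaussian interaction-profile kernel on binary profiles uses bandwidth
`α = α′ / mean squared profile norm` with `α′ = 0.5` for both axes. Division
is the canonical adaptive-bandwidth rule for this kernel; a `bandwidth_rule=
"multiply"` switch preserves the alternative literal reading for sensitivity
analysis. The kernel matrix is a valid RBF Gram matrix (positive
semi-definite; asserted to −1e−8 in tests), has unit diagonal by
construction, and decreases monotonically with Hamming distance at fixed
bandwidth. A profile set that is entirely zero leaves the bandwidth
undefined and is rejected.

Integration: `DS(i,j)` is the arithmetic mean of the two semantic
similarities when both diseases have vocabulary entries, otherwise the GIP
value. "Has semantic similarity" is interpreted as vocabulary presence
per pair (default); the stricter variant requiring a shared ancestor
(`rule="nonzero"`) is available. Since lncRNAs carry no ontology, RS is the
GIP kernel alone.

### Pair features

A pair (disease *i*, lncRNA *j*) is the concatenation of DS row *i* and RS
row *j*, disease half first. Values are already in [0, 1]; no further
scaling is applied before the extractor. Positives are the known pairs; an
equal-sized negative set is drawn uniformly without replacement from the
zero cells of the adjacency matrix, once, before cross-validation (the
training corpus is fixed, folds partition it).

### CNN feature extractor

The extractor is a compact 1-D convolutional network written directly on
numpy arrays: conv(valid, stride 1) → ReLU → non-overlapping max-pool
blocks, a dense ReLU layer whose activations are the extracted features, and
a linear-sigmoid head used only during training (binary cross-entropy,
Adam, seeded shuffling and He/Glorot-style seeded initialization; gradients
are hand-derived and verified against finite differences in the test
suite). Defaults: two blocks of (16 filters, width 8, pool 4) and
(32, 8, 4), 64 dense units, 30 epochs, batch 32, learning rate 1e-3. The
architecture is a pragmatic default, configurable rather than canonical.

To honor the evaluation contract the extractor is trained per outer fold on
that fold's training split only. The `identity` mode bypasses the network,
feeding raw similarity features to the ELM; it is both an ablation baseline
and the configuration used for the pipeline-level guarantees, which are
therefore independent of the CNN's stochastic training.

### Extreme learning machine

Input weights and biases are i.i.d. uniform[−1, 1], drawn per hidden unit
from a seeded generator — so hidden layers drawn with one seed nest, making
capacity monotone in the number of hidden nodes (tested). Output weights
solve `min ‖Hq − l‖²` via SVD-based least squares (LAPACK `gelsd`,
machine-precision rank tolerance); labels form a single {0, 1} column, with
an optional one-hot mode for multi-class reuse. Defaults: 500 hidden nodes,
sigmoid activation.

The evaluation pipeline applies a unit ridge (`l2 = 1.0`, solving
`(HᵀH + λI) q = Hᵀl`) by default. The sigmoid random-feature matrix H is
ill-conditioned — its smallest singular values sit roughly four orders of
magnitude below the largest — so the exact least-squares solution chases
sampling noise and generalizes measurably worse; λ = 1 is a tiny relative
regularization (λ/σ_max² ≈ 4e−6) that stabilizes the solve. `elm_fit`
itself defaults to the pure pseudoinverse (`l2 = 0`) so the closed-form
optimality properties (interpolation at N′ = N, normal-equation residuals)
hold exactly.

### Evaluation

AUROC is computed by the Mann–Whitney rank formulation (average ranks, ties
worth one half), which is exact and matches an exhaustive pair count to
1e−12. Point metrics (accuracy, sensitivity, specificity, precision, MCC)
are evaluated at threshold 0.5 on ELM scores; undefined ratios (zero
denominators) are reported as NaN with a warning rather than silently
clamped. K-fold assignment is stratified by label with a seeded shuffle, so
per-fold class balance (and hence per-fold metrics) is stable. LOOCV pools
all held-out scores into a single ROC — the only definition available when
each test set holds one sample — and the pooling is verified against a
deterministic scorer in the tests.

### Case-study ranking

`standard` mode trains on all positives and ranks every lncRNA for the
query; the query's known partners are flagged so both all-pair and
novel-only ranks can be reported. `new_disease` (cold-start) mode removes
the query's pairs *before* anything else is computed: adjacency, both GIP
kernels, the negative draw (from the reduced unlabeled set — the only
consistent choice) and all pair features are rebuilt, leaving the query
with an all-zero interaction profile so its representation rests entirely
on semantic similarity through the integration rule. Ties in the final
ordering are broken lexicographically by lncRNA id, making rankings fully
deterministic.

## Synthetic data

The generator emulates exactly the structure the method assumes and nothing
else. An ontology is a complete rooted tree (default depth 3, branching 3)
whose internal positions all carry vocabulary terms, guaranteeing prefix
closure. Each of `n_clusters` (default 4) disease clusters is anchored at a
deepest-level internal node — the placement that maximizes within-cluster
shared ancestry — and each covered disease receives one leaf tree number
under its cluster's anchor. A `vocab_coverage` fraction (default 0.9) of
diseases get vocabulary entries; the rest exercise the GIP fallback path of
the integration rule. lncRNAs are assigned clusters uniformly, and
associations are Bernoulli: probability 0.3 for matched disease–lncRNA
cluster pairs, 0.02 otherwise (defaults: 60 diseases, 120 lncRNAs).
Everything descends from one seed and is reproducible bit for bit.

What this does *not* emulate: the heavy-tailed degree distributions of real
association databases, literature ascertainment bias, correlated noise
between similar diseases, or multi-tree-number diseases. Passing the
planted-signal tests therefore shows the pipeline recovers block structure
expressed through its own similarity representations — it does not certify
performance on real catalogues, whose headline numbers additionally depend
on the specific database snapshot and negative draw.

## Problem sizes and numerical choices

The bundled tests and reference script run at desk scale by design: the
planted-signal check uses the default 60 × 120 instance (≈ 1300 samples,
178-dim features, 5 folds, under a second), unit tests use 15 × 25 worlds,
and the deterministic worked example is two diseases and nine vocabulary
terms. Identifier normalization is lowercase/trim/whitespace-collapse;
all entity indexes are lexicographic, so every matrix and ranking is
reproducible across runs. Matrix symmetry is exact by construction
(values are filled pairwise); kernel diagonals are set to exactly 1.

## Known limitations

- Disease representation requires tree numbers; diseases outside the
  vocabulary fall back to purely topological (GIP) similarity, which is
  uninformative for an entity with no known associations — cold-start
  ranking of a disease *absent from the vocabulary* is not meaningful.
- The ELM's random features make individual scores seed-dependent; only
  rank-level and cross-validated summaries should be interpreted.
- Negative "labels" are unlabeled pairs, not verified non-associations, so
  all point metrics are relative to the sampled negative set.
- The CNN is a capacity-limited extractor intended for these feature sizes;
  it is not a general-purpose deep-learning component.
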