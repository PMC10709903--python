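# Methods

`mmkge` learns embeddings for knowledge graphs whose entities carry
attributes of heterogeneous modalities, evaluates them on link prediction
with degree-stratified analysis, and feeds them into a drug–protein
interaction (DPI) classification harness. This note records the models, the
synthetic study conditions, the numerical choices, and what the desk-scale
experiments do and do not demonstrate.

## The model

A knowledge graph is a tuple G = (V, R, E, D, d): typed entities V,
relations R, directed triples E ⊆ V × R × V, and a *partial* attribute map
d : V_d → D defined on a subset V_d ⊆ V. Attributes come in three
modalities: amino-acid sequences (proteins), SMILES-like molecule strings
(drugs), and free-text descriptions (diseases).

Every entity resolves to exactly one embedding path in a shared space 𝒳:

- **Protein encoder** — frozen per-residue feature vectors are averaged over
  the sequence and linearly projected into 𝒳 by a trainable matrix P.
- **Molecule encoder** — a single-head self-attention layer
  softmax(QKᵀ/√d)V (no residual) over frozen per-character features with a
  BOS marker prepended; the BOS-position output is projected into 𝒳.
  Trainable: W_q, W_k, W_v, P.
- **Text encoder** — lowercased whitespace tokens, truncated to 64, mapped
  through a *trainable* token-embedding table, mean-pooled, projected.
  Both the table and the projection receive gradients, mirroring a fully
  fine-tuned text backbone; a pretrained transformer can be substituted
  behind the same forward/backward contract.
- **Lookup fallback** — entities without attributes take rows of a trainable
  matrix W_e; relations always take rows of W_r.

The frozen feature tables are seeded random stand-ins for large pretrained
sequence/molecule models; per-token features exported from a real model can
be loaded from TSV behind the same interface. Freezing preserves the
architecture in which only projections, attention weights, text embeddings
and lookup rows learn.

Three scoring functions f : 𝒳³ → ℝ are provided (higher = more plausible):
translation in ℝⁿ, f = −‖h + r − t‖_p (p ∈ {1,2}, default 2); the complex
bilinear product f = Re⟨h, r, conj(t)⟩; and complex rotation
f = −‖h ∘ r − t‖ with r_i = exp(iθ_i) parameterized by unconstrained phase
angles, so unit modulus holds by construction. Complex vectors of dimension
n are stored as 2n reals (real block, then imaginary block); for the
rotation scorer, encoders and W_e emit 2n reals while relations remain n
phases. The rotation norm treats the complex vector as 2n reals under L_p,
which coincides with the complex-modulus norm at p = 2.

## Training

For each observed triple, negatives are built by replacing the head or tail
(uniform side) with a uniform random entity, redrawn only while it equals
the entity it replaces; corrupted triples are not filtered against the
training set (optional flag). Three losses are supported: margin ranking
max(0, f̃ − f + m); binary cross-entropy −log σ(f) − Σ log(1 − σ(f̃_j)),
averaged over 1 + k terms; and cross-entropy of the positive among
{positive} ∪ negatives. Margin ranking pairs naturally with the
translational scorer, the two cross-entropies with the complex/rotation
scorers; other combinations run with a warning.

The verifiable core optimizer is plain SGD, θ ← θ − α ∇θ ℒ, with an L2
penalty (weight λ) on the embedding vectors of the positive triple applied
inside the gradient only — the reported loss stays unregularized. All golden
and reduction tests use this mode. An adaptive-moment mode ("adam",
β₁ = 0.9, β₂ = 0.999) is provided for practical runs because encoder
weights (projections, attention) receive gradients orders of magnitude
smaller than lookup rows; a single shared SGD rate trains encoders far too
slowly at desk scale. Encoder-model experiments therefore default to the
adaptive mode; pure-lookup runs use SGD.

Gradients are derived analytically per scorer, loss and encoder (chain
rule through mean pooling, the softmax attention, and the phase
parameterization) and verified against central finite differences in the
test suite. When the model contains no encoders, training takes a
vectorized batch path whose arithmetic agrees with the per-triple path to
machine precision; the RNG draw order (permutation per epoch; per triple
and negative: one side draw, then replacement draws) is identical in both
and is part of the documented contract.

**Two-stage pretraining.** Stage 1 trains an all-lookup model (attributes
ignored). Stage 2 initializes a fresh encoder-equipped model by copying the
relation matrix in full and the W_e rows of attribute-less entities;
stage-1 rows of attribute-covered entities are discarded, since those
entities are now embedded by freshly initialized encoders. Whether relation
rows should transfer is not fully settled in the literature this follows;
full transfer was chosen because relations are lookups in both stages and
discarding them would forfeit most of the stage-1 signal.

## Evaluation

Each test triple contributes two ranking queries (tail prediction and head
prediction) against all entities. MRR = (1/m) Σ 1/p_i and
H@k = (1/m) Σ 1[p_i ≤ k]. The default is the *filtered* setting — known
true triples (train ∪ valid ∪ test) are removed from the candidate list,
never the true entity itself — with a `raw` switch; ties take the mean of
the optimistic and pessimistic positions so constant scorers are not
inflated. Degree-stratified analysis groups ranks by the training-graph
degree (in + out; a self-loop counts 2) of the *predicted* entity; macro
MRR weighs each degree value equally. The cumulative-cutoff analysis
reports, for growing degree d, the difference in cumulative macro MRR
oriented as baseline − encoder (negative ⇒ the encoder model is ahead), and
the largest d at which the encoder model still leads.

Splitting is benchmark-decoupled: any triple whose endpoint set equals a
benchmark pair (any relation, either orientation) is removed before the
0.8/0.1/0.1 split. One uniformly chosen incident triple per entity is
pinned to the training set so every entity is trainable; the remainder is
shuffled and cut at the proportion boundaries. Splitting is uniform over
triples rather than stratified by relation — the simplest procedure
satisfying the coverage constraint.

## The DPI harness

Benchmark pairs are positives; negatives are sampled uniformly without
replacement from benchmark-drugs × benchmark-proteins, excluding positives
and pairs co-occurring as KG edges in either orientation, at ratio 1:10. A
pair's features are [drug embedding ‖ protein embedding]; a missing side is
imputed with the mean embedding of its entity type. Classifiers (logistic
regression, random forest, MLP) are evaluated with stratified 5-fold CV,
folds fixed by labels and seed so they are identical across embedding
sources. Per fold, 10 random-search trials are scored on a 10% validation
slice by AUPRC (AUROC is reported but not used for selection, since no
combination rule is defined when both are named), then the winner is refit
on the full training split. LR/RF use inverse-frequency class weights; the
MLP trains on a majority-undersampled 1:1 split. AUROC is the pairwise
concordance probability (ties ½); AUPRC is the area under the
precision–recall step curve; precision/recall/F1 use threshold 0.5.

## Synthetic study conditions

The generator produces a typed KG of 150 entities (80 proteins, 30 drugs,
20 diseases, 12 pathways, 8 gene disorders) and 2,000 unique triples over a
six-relation schema, with 68% attribute coverage of the eligible types.
Its latent structure is designed so that "attributes complement graph
structure" is literally true and measurable:

- Each entity has a latent class (24 classes) and a position z on the unit
  sphere in ℝ³ (class center + noise 0.15, renormalized). Relations carry
  class-compatibility tables; tails are sampled with weight
  popularity × compatibility × exp(β z_h·z_t) with sharpness β = 12, so
  links concentrate on compatible, nearby pairs and link prediction has
  high headroom over chance.
- Popularity follows rank^(−0.8) with the bottom 25% of ranks further
  down-weighted ×0.02 — an "understudied tail" giving genuinely sparse
  entities and a right-skewed degree histogram (mean ≫ median).
- Half of the edges headed by understudied entities ignore the latent
  structure entirely (popularity-only tails), emulating links contributed
  by high-throughput screens rather than by the entity's intrinsic profile.
  This is the mechanism that makes sparse neighborhoods unrepresentative:
  a lookup model misplaces a rare entity whose only edges are screen-like,
  while its attributes remain faithful.
- Attributes embed two signals with fidelity s (default 1): a class motif
  (12 residues / 8 characters / 4 keywords) and *positional anchors* — one
  dedicated letter (or word) per latent dimension repeated
  round(4·(z_j + 1)) times — so mean pooling can linearly recover both the
  class and the position. Backgrounds, class motifs and anchors use
  pairwise disjoint sub-alphabets; each insert is spliced contiguously at a
  random offset. With probability 1 − s the motif and anchors encode a
  random class/position instead. Chemical or biological plausibility of
  the strings is explicitly out of scope.

The latent ground truth (classes, positions, compatibilities, motifs) is
returned and serialized next to the KG for parameter-recovery experiments.
Benchmark pairs are drawn from class-compatible drug–protein combinations
with probability proportional to latent affinity, so they deliberately
include pairs that also occur as KG edges — the leakage that decoupling
must remove.

**What the generator does not emulate:** chemically valid molecules or
biologically plausible sequences; the exact degree sequence of any real
graph; multi-attribute entities; relation-specific attribute semantics.
Passing the trend tests shows the machinery extracts planted signal under
these conditions, not that any particular real-data performance level would
be reached.

## Problem sizes and experiment design

All experiments run on the default 150-entity / 2,000-triple conditions.
The lookup rotation model trains 50 epochs (cross-entropy, 16 negatives,
lr 0.1, λ = 1e−5, batch 128, dim 32); its filtered test MRR is compared
with the analytic random-ranking expectation E[1/rank] = H_k/k averaged
over the per-query candidate counts. The pretraining comparison trains both
arms for 4 encoder epochs under SGD after a 30-epoch stage 1. The
degree-cutoff experiment trains the encoder model for 20 epochs (adaptive
mode, 8 negatives) from a 50-epoch stage-1 transfer and compares against
the same stage-1 model as baseline, restricting the per-degree tables to
ranks whose predicted entity carries an attribute — the analogue of
focusing the degree analysis on the encoded entity type. Inductive checks
hold out attributed entities entirely from training and embed them at test
time from their payloads alone.

## Numerical choices and degenerate inputs

- Subgradient of |x| at 0 is 0; the L2-norm gradient at the origin is 0.
- Cross-entropy and binary cross-entropy are computed via log-sum-exp
  stabilization; no overflow for |f| ≤ 100.
- Ranking ties: realistic policy (mean of optimistic and pessimistic).
- Empty attribute payloads, unknown relations, single-entity corruption,
  empty test sets, non-finite losses, and single-class folds all raise
  immediately with descriptive messages.
- Unknown residues/characters map to a dedicated UNK feature row;
  out-of-vocabulary text tokens map to UNK embeddings.
- Xavier-style uniform initialization scaled by fan-in/fan-out throughout,
  all seeded; generation, splitting, corruption, fold assignment and
  training are deterministic given their seeds.

## Known limitations

- Encoders are shallow stand-ins; conclusions about *which* modality
  encodes best do not transfer to transformer-backed encoders.
- The adaptive-moment mode has no bias-correction-free warmup or schedule;
  it is adequate at desk scale but untuned for large graphs.
- The self-attention molecule encoder computes full attention but uses only
  the BOS query; long SMILES strings are quadratic in principle yet cheap
  here.
- Macro MRR at sparsely populated degree values rests on few ranks and is
  noisy; the cumulative curve mitigates but does not remove this.
- The DPI harness assumes binary labels and a closed candidate universe of
  benchmark entities.
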