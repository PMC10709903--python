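# mmkge — multimodal knowledge-graph embeddings

`mmkge` learns embeddings for biomedical knowledge graphs whose entities
carry attribute data of heterogeneous modalities — amino-acid sequences for
proteins, SMILES strings for drugs, free-text descriptions for diseases —
while still supporting the (common) entities that have no attributes at
all. It is aimed at computational biologists and machine-learning
researchers who want to study *when* attribute encoders help link
prediction, in particular on sparsely connected ("understudied") entities,
without GPU-scale infrastructure.

## The model

A knowledge graph is a tuple G = (V, R, E, D, d): typed entities V,
relations R, triples (h, r, t) ∈ E, and a partial attribute map
d : V_d → D on a subset V_d ⊆ V. Entities with attributes are embedded by
modality-specific encoders (mean-pooled frozen residue features for
protein sequences; single-head self-attention over frozen character
features for molecule strings; trainable mean-pooled token embeddings for
text, capped at 64 tokens); entities without attributes take rows of a
trainable lookup matrix W_e, and relations rows of W_r. Any of three
scoring functions consumes the embeddings:

- translation:  f(h, r, t) = −‖**h** + **r** − **t**‖        (ℝⁿ)
- bilinear:     f(h, r, t) = Re⟨**h**, **r**, conj(**t**)⟩   (ℂⁿ)
- rotation:     f(h, r, t) = −‖**h** ∘ **r** − **t**‖, |r_i| = 1  (ℂⁿ)

Training minimizes a margin-ranking, binary cross-entropy, or
cross-entropy loss over corrupted triples (random head/tail replacement)
by plain SGD, θ ← θ − α∇θℒ, with an optional adaptive-moment mode.
Link prediction is scored by MRR = (1/m) Σᵢ 1/pᵢ and H@k over filtered
candidate ranks, micro and stratified by the predicted entity's node
degree (incoming + outgoing edges on the training graph). A two-stage
pretraining strategy (train all-lookup first, then transfer W_r and the
attribute-less rows into the encoder model) cuts encoder training cost.
Entity embeddings also feed a drug–protein interaction (DPI) benchmark:
1:10 KG-filtered negative sampling, concatenated pair features with
type-mean imputation, and stratified 5-fold cross-validation of
LR/RF/MLP classifiers reporting AUROC/AUPRC/P/R/F1.

Because compiling a real multimodal KG requires large downloads, the
package ships a first-class synthetic generator: a typed schema over
proteins/drugs/diseases/pathways/disorders, heavy-tailed degrees with an
understudied tail, partial (68%) attribute coverage, and attributes that
provably carry link-relevant signal through planted class motifs and
positional anchor tokens. See `docs/methods.md` for the full model and the
study conditions.

## Worked example

```python
from mmkge.workflows import make_study, fit_lookup, evaluate_model
from mmkge.evaluation import expected_random_mrr

study = make_study(seed=1)                      # generate, decouple, split
state, scorer, kg = fit_lookup(study, seed=1)   # rotation scorer, lookup only
report = evaluate_model(state, scorer, study, kg, study.split.test)
print(f"filtered test MRR {report.mrr:.3f}  H@10 {report.hits_at(10):.3f}  "
      f"random {expected_random_mrr(report):.4f}")
```

```
filtered test MRR 0.523  H@10 0.896  random 0.0400
```

The model ranks the held-out endpoint of a test edge at reciprocal rank
0.52 on average — 13 times the analytic chance level for the same
candidate sets (H_k/k ≈ 0.04 for k ≈ 150 candidates) — and places the true
entity in the top 10 for 90% of queries. The same `Study` object drives
the encoder models, the pretraining comparison, the degree-cutoff analysis
and the DPI benchmark (`mmkge.workflows`).

The command line mirrors the workflow for file-based use:

```bash
mmkge simulate --seed 1 --out data/
mmkge split --triples data/triples.tsv --benchmarks data/pairs.tsv --out splits/
mmkge pretrain --triples splits/train.tsv ... --out stage1.npz
mmkge train    --triples splits/train.tsv ... --pretrained stage1.npz --out model.npz
mmkge evaluate --checkpoint model.npz --test-triples splits/test.tsv ... --out report.json
mmkge benchmark --pairs data/pairs.tsv --kg splits/train.tsv --embeddings model.npz --out cv.json
```

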