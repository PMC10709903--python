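"""End-to-end experiment assemblies over the library primitives.

These glue functions run the standard desk-scale studies: generate a
synthetic attributed KG, decouple the benchmark, split, train lookup and/or
encoder models, and evaluate.  They are used by the test suite, the
acceptance script, and as worked examples; all sizes are arguments so the
same workflows scale up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dpi_benchmark import (
    assign_folds,
    build_labeled_pairs,
    compute_type_means,
    cross_validate,
    CVReport,
    feature_matrix,
)
from .encoders import EncoderRegistry
from .evaluation import (
    CumulativeDelta,
    cumulative_delta_cutoff,
    EvalReport,
    evaluate_link_prediction,
    expected_random_mrr,
)
from .kg_data import (
    AttributedKG,
    decouple_and_split,
    degree_map,
    SplitResult,
    Triple,
)
from .scoring import make_scorer, Scorer
from .synthetic_data import (
    generate_attributed_kg,
    generate_benchmark_pairs,
    LatentGroundTruth,
    SynthConfig,
)
from .training import LossSpec, pretrain_transfer, train, TrainState


@dataclass
class Study:
    """A generated KG with its benchmark pairs and decoupled split."""

    kg: AttributedKG          # restricted to entities surviving decoupling
    ground_truth: LatentGroundTruth
    pairs: list
    split: SplitResult
    degrees: dict[str, int]   # training-graph degrees

    @property
    def known_triples(self) -> list[Triple]:
        return self.split.train + self.split.valid + self.split.test


def make_study(
    seed: int,
    config: SynthConfig | None = None,
    n_pairs: int = 50,
) -> Study:
    """Generate, decouple against benchmark pairs, and split."""
    cfg = config if config is not None else SynthConfig(seed=seed)
    kg, gt = generate_attributed_kg(cfg)
    pairs = generate_benchmark_pairs(kg, gt, n_pairs, np.random.default_rng(seed + 1))
    split = decouple_and_split(kg, pairs, seed=seed)
    surviving = {e for t in split.train + split.valid + split.test
                 for e in (t.head, t.tail)}
    kept = AttributedKG(
        {v: kg.entity_types[v] for v in surviving},
        set(kg.relations),
        split.train + split.valid + split.test,
        {v: rec for v, rec in kg.attributes.items() if v in surviving},
    )
    return Study(kept, gt, pairs, split, degree_map(split.train))


def fit_lookup(
    study: Study,
    scorer_name: str = "rotate",
    dim: int = 32,
    epochs: int = 50,
    learning_rate: float = 0.1,
    reg_weight: float = 1e-5,
    num_negatives: int = 16,
    loss_kind: str = "cross_entropy",
    batch_size: int = 128,
    seed: int = 0,
) -> tuple[TrainState, Scorer, AttributedKG]:
    """Stage-1 style pure-lookup model on the training split."""
    lk = AttributedKG(dict(study.kg.entity_types), set(study.kg.relations),
                      study.split.train, {})
    scorer = make_scorer(scorer_name, dim)
    reg = EncoderRegistry(lk, scorer, seed=seed)
    state = TrainState(reg, learning_rate=learning_rate,
                       reg_weight=reg_weight, seed=seed)
    train(lk, reg, scorer, LossSpec(loss_kind, num_negatives=num_negatives),
          state, epochs=epochs, batch_size=batch_size)
    return state, scorer, lk


def fit_encoder_model(
    study: Study,
    scorer_name: str = "rotate",
    dim: int = 32,
    epochs: int = 20,
    learning_rate: float = 0.05,
    reg_weight: float = 1e-5,
    num_negatives: int = 8,
    loss_kind: str = "cross_entropy",
    batch_size: int = 128,
    seed: int = 0,
    pretrained: TrainState | None = None,
    optimizer: str = "adam",
) -> tuple[TrainState, Scorer, AttributedKG]:
    """Encoder-equipped model on the training split, optionally transferred.

    With ``pretrained`` (an all-lookup stage-1 state over the same split and
    scorer), relation rows and attribute-less entity rows are copied before
    encoder training starts.
    """
    train_kg = AttributedKG(dict(study.kg.entity_types), set(study.kg.relations),
                            study.split.train, dict(study.kg.attributes))
    scorer = make_scorer(scorer_name, dim)
    reg = EncoderRegistry(train_kg, scorer, seed=seed)
    if pretrained is not None:
        state = pretrain_transfer(pretrained, train_kg, reg)
        state.learning_rate, state.reg_weight, state.seed = (
            learning_rate, reg_weight, seed)
        state.optimizer = optimizer
    else:
        state = TrainState(reg, learning_rate=learning_rate,
                           reg_weight=reg_weight, seed=seed,
                           optimizer=optimizer)
    train(train_kg, reg, scorer, LossSpec(loss_kind, num_negatives=num_negatives),
          state, epochs=epochs, batch_size=batch_size)
    return state, scorer, train_kg


def evaluate_model(
    state: TrainState,
    scorer: Scorer,
    study: Study,
    model_kg: AttributedKG,
    triples: list[Triple],
    mode: str = "filtered",
) -> EvalReport:
    return evaluate_link_prediction(
        state.registry, scorer, triples, model_kg, mode=mode,
        filter_triples=study.known_triples, degrees=study.degrees,
    )


def learning_check(seed: int, epochs: int = 50) -> dict:
    """Lookup rotation model: filtered test MRR vs the analytic random MRR."""
    study = make_study(seed)
    state, scorer, lk = fit_lookup(study, epochs=epochs, seed=seed)
    report = evaluate_model(state, scorer, study, lk, study.split.test)
    random_mrr = expected_random_mrr(report)
    return {
        "mrr": report.mrr,
        "hits": report.hits,
        "random_mrr": random_mrr,
        "ratio": report.mrr / random_mrr,
    }


def pretraining_comparison(
    seed: int,
    lookup_epochs: int = 30,
    encoder_epochs: int = 4,
) -> dict:
    """Validation MRR after a fixed encoder-epoch budget, with and without
    stage-1 pretraining transfer.

    Both arms use the plain SGD mode: the benefit being measured is that
    encoders adapt to an informative fixed context instead of co-training
    against random lookup rows, which is a property of the update dynamics.
    """
    study = make_study(seed)
    stage1, _, _ = fit_lookup(study, epochs=lookup_epochs, seed=seed)
    pre_state, pre_scorer, pre_kg = fit_encoder_model(
        study, epochs=encoder_epochs, num_negatives=4, seed=seed,
        pretrained=stage1, optimizer="sgd")
    scr_state, scr_scorer, scr_kg = fit_encoder_model(
        study, epochs=encoder_epochs, num_negatives=4, seed=seed,
        optimizer="sgd")
    pre = evaluate_model(pre_state, pre_scorer, study, pre_kg, study.split.valid)
    scratch = evaluate_model(scr_state, scr_scorer, study, scr_kg, study.split.valid)
    return {"pretrained_mrr": pre.mrr, "scratch_mrr": scratch.mrr}


def degree_cutoff_experiment(
    seed: int,
    lookup_epochs: int = 50,
    encoder_epochs: int = 20,
    num_negatives: int = 8,
) -> CumulativeDelta:
    """Cumulative macro-MRR difference between the encoder model and the
    lookup baseline, scanned over node degree (low-degree benefit check).

    Mirroring the encoded-type focus of the degree analysis, only ranks whose
    predicted entity carries an attribute enter the per-degree tables.
    """
    from .evaluation import macro_mrr_by_degree

    study = make_study(seed)
    base_state, base_scorer, lk = fit_lookup(study, epochs=lookup_epochs, seed=seed)
    # the lookup baseline doubles as the stage-1 pretraining source
    enc_state, enc_scorer, enc_kg = fit_encoder_model(
        study, epochs=encoder_epochs, num_negatives=num_negatives, seed=seed,
        pretrained=base_state)
    base = evaluate_model(base_state, base_scorer, study, lk, study.split.test)
    enc = evaluate_model(enc_state, enc_scorer, study, enc_kg, study.split.test)
    covered = study.kg.covered_entities
    base_deg = macro_mrr_by_degree(
        [r for r in base.ranks if r.predicted_entity in covered])
    enc_deg = macro_mrr_by_degree(
        [r for r in enc.ranks if r.predicted_entity in covered])
    return cumulative_delta_cutoff(enc_deg, base_deg)


def inductive_check(
    seed: int,
    signal: float,
    n_holdout: int = 10,
    epochs: int = 8,
) -> dict:
    """Inductive MRR on held-out attributed entities vs the random baseline.

    Entities with attributes are removed from the graph used for training;
    their incident triples form the inductive test set, and at test time the
    held-out entities are embeddable only through their attribute payloads.
    """
    cfg = SynthConfig(seed=seed, coverage=1.0, signal=signal)
    kg, gt = generate_attributed_kg(cfg)
    rng = np.random.default_rng(seed + 7)
    covered = [v for v in sorted(kg.covered_entities)]
    holdout = set(np.array(covered)[rng.choice(len(covered), n_holdout,
                                               replace=False)].tolist())
    train_triples = [t for t in kg.triples
                     if t.head not in holdout and t.tail not in holdout]
    test_triples = [t for t in kg.triples
                    if (t.head in holdout) != (t.tail in holdout)]
    surviving = {e for t in train_triples for e in (t.head, t.tail)}
    test_triples = [t for t in test_triples
                    if {t.head, t.tail} - holdout <= surviving][:80]
    train_kg = AttributedKG(
        {v: kg.entity_types[v] for v in surviving}, set(kg.relations),
        train_triples, {v: r for v, r in kg.attributes.items() if v in surviving})
    eval_kg = AttributedKG(
        {v: kg.entity_types[v] for v in surviving | holdout}, set(kg.relations),
        train_triples + test_triples,
        {v: r for v, r in kg.attributes.items() if v in surviving | holdout})

    scorer = make_scorer("rotate", 32)
    reg = EncoderRegistry(train_kg, scorer, seed=seed)
    state = TrainState(reg, learning_rate=0.05, reg_weight=1e-5, seed=seed,
                       optimizer="adam")
    train(train_kg, reg, scorer, LossSpec("cross_entropy", num_negatives=8),
          state, epochs=epochs, batch_size=128)
    report = evaluate_link_prediction(
        reg, scorer, test_triples, eval_kg, mode="filtered",
        filter_triples=train_triples + test_triples)
    return {"mrr": report.mrr, "random_mrr": expected_random_mrr(report)}


def dpi_study(
    seed: int,
    embeddings: dict[str, np.ndarray],
    study: Study,
    ratio: int = 10,
    classifiers=("lr", "rf"),
    n_trials: int = 10,
) -> CVReport:
    """DPI cross-validation for a given embedding source on a study's pairs."""
    positives = [(p.x, p.y) for p in study.pairs]
    rng = np.random.default_rng(seed + 3)
    labeled = build_labeled_pairs(positives, study.known_triples, ratio, rng,
                                  allow_fewer=True)
    labeled = assign_folds(labeled, n_folds=5, seed=seed)
    means = compute_type_means(embeddings, study.kg.entity_types)
    X = feature_matrix(labeled, embeddings, means)
    return cross_validate(labeled, X, classifiers=classifiers,
                          n_trials=n_trials, seed=seed)
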