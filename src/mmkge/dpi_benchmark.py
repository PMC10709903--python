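"""Drug-protein interaction (DPI) classification harness.

Benchmark pairs are the positives of a binary classification task; negatives
are sampled uniformly from the combinatorial space of benchmark drugs x
benchmark proteins, excluding the positives and any pair that co-occurs (in
either orientation) as a KG edge, at a positive:negative ratio of 1:10.

A pair is represented by the concatenation [drug embedding || protein
embedding]; a missing side is imputed with the mean embedding of its entity
type.  Classifiers (logistic regression, random forest, MLP) are evaluated
with stratified 5-fold cross-validation; per fold, hyperparameters are tuned
by random search (10 trials) on a 10% validation slice of the training split,
selecting on AUPRC, then refit on the full training split.  LR/RF use class
weights inversely proportional to class frequency; the MLP trains on a
majority-undersampled (1:1) split.  Metrics: precision/recall/F1 at
threshold 0.5, AUROC (pairwise concordance, ties count 1/2), and AUPRC (area
under the precision-recall step curve), the latter preferred under the 1:10
imbalance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier

from .kg_data import Triple


@dataclass
class LabeledPair:
    drug: str
    protein: str
    label: int
    fold: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug, self.protein)


@dataclass
class PairFeatures:
    vector: np.ndarray
    drug_imputed: bool = False
    protein_imputed: bool = False


@dataclass
class FoldResult:
    classifier: str
    fold: int
    precision: float
    recall: float
    f1: float
    auroc: float
    auprc: float
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier, "fold": self.fold,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "auroc": self.auroc, "auprc": self.auprc,
            "hyperparameters": self.hyperparameters,
        }


@dataclass
class CVReport:
    folds: list[FoldResult]

    def mean(self, classifier: str, metric: str) -> float:
        vals = [getattr(f, metric) for f in self.folds if f.classifier == classifier]
        if not vals:
            raise KeyError(f"no folds for classifier {classifier!r}")
        return float(np.mean(vals))

    def to_dict(self) -> dict:
        return {"folds": [f.to_dict() for f in self.folds]}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def sample_negative_pairs(
    positives: Sequence[tuple[str, str]],
    kg_triples: Sequence[Triple],
    ratio: int,
    rng: np.random.Generator,
    allow_fewer: bool = False,
) -> list[LabeledPair]:
    """Uniform sample of unobserved drug-protein pairs, KG-filtered.

    The candidate universe is {benchmark drugs} x {benchmark proteins} minus
    the positives and minus any pair co-occurring as a KG edge in either
    orientation.  Sampling is without replacement, ``ratio`` negatives per
    positive.
    """
    if not positives:
        raise ValueError("no positive pairs")
    drugs = sorted({d for d, _ in positives})
    proteins = sorted({p for _, p in positives})
    pos_keys = {frozenset(p) for p in positives}
    kg_keys = {frozenset((t.head, t.tail)) for t in kg_triples if t.head != t.tail}

    candidates = [
        (d, p)
        for d in drugs
        for p in proteins
        if d != p and frozenset((d, p)) not in pos_keys
        and frozenset((d, p)) not in kg_keys
    ]
    wanted = ratio * len(positives)
    if len(candidates) < wanted:
        if not allow_fewer:
            raise ValueError(
                f"insufficient negative candidates: need {wanted}, "
                f"have {len(candidates)} (short by {wanted - len(candidates)})"
            )
        wanted = len(candidates)
    chosen = rng.choice(len(candidates), size=wanted, replace=False)
    return [LabeledPair(*candidates[i], label=0) for i in sorted(chosen.tolist())]


def build_labeled_pairs(
    positives: Sequence[tuple[str, str]],
    kg_triples: Sequence[Triple],
    ratio: int,
    rng: np.random.Generator,
    allow_fewer: bool = False,
) -> list[LabeledPair]:
    """Positives (label 1) followed by sampled negatives (label 0)."""
    pos = [LabeledPair(d, p, label=1) for d, p in positives]
    return pos + sample_negative_pairs(positives, kg_triples, ratio, rng, allow_fewer)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def compute_type_means(
    embeddings: Mapping[str, np.ndarray], entity_types: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Per-type mean embedding over entities with an available embedding."""
    groups: dict[str, list[np.ndarray]] = {}
    for ent, vec in embeddings.items():
        groups.setdefault(entity_types.get(ent, "other"), []).append(np.asarray(vec))
    return {t: np.mean(vs, axis=0) for t, vs in groups.items()}


def build_pair_features(
    pair: LabeledPair,
    embeddings: Mapping[str, np.ndarray],
    type_means: Mapping[str, np.ndarray] | None = None,
) -> PairFeatures:
    """[drug block || protein block], imputing a missing side by its type mean."""
    out: list[np.ndarray] = []
    flags = []
    for ent, type_key in ((pair.drug, "drug"), (pair.protein, "protein")):
        vec = embeddings.get(ent)
        if vec is None:
            if type_means is None or type_key not in type_means:
                raise ValueError(
                    f"no embedding for {ent!r} and no {type_key} type mean to impute"
                )
            vec = type_means[type_key]
            flags.append(True)
        else:
            flags.append(False)
        out.append(np.asarray(vec, float))
    return PairFeatures(np.concatenate(out), *flags)


def feature_matrix(
    pairs: Sequence[LabeledPair],
    embeddings: Mapping[str, np.ndarray],
    type_means: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    return np.stack([build_pair_features(p, embeddings, type_means).vector
                     for p in pairs])


def random_embeddings(
    entities: Sequence[str], dim: int = 128, seed: int = 0
) -> dict[str, np.ndarray]:
    """Chance-level baseline: a seeded normal vector per entity."""
    rng = np.random.default_rng(seed)
    return {e: rng.standard_normal(dim) for e in sorted(entities)}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    recall: float
    f1: float
    auroc: float
    auprc: float


def classification_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ClassificationMetrics:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # AUROC: probability a random positive outranks a random negative (ties 1/2)
    ranks = rankdata(scores)  # average ranks handle ties
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # AUPRC: precision-recall step curve swept over score thresholds
    order = np.argsort(-scores, kind="stable")
    sorted_scores, sorted_labels = scores[order], labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # evaluate only at the last index of each tied-score block
    block_end = np.append(sorted_scores[1:] != sorted_scores[:-1], True)
    precision_curve = tp[block_end] / (tp[block_end] + fp[block_end])
    recall_curve = tp[block_end] / n_pos
    auprc = float(np.sum(np.diff(np.concatenate([[0.0], recall_curve]))
                         * precision_curve))

    pred = scores >= threshold
    tp_ = int(np.sum(pred & (labels == 1)))
    fp_ = int(np.sum(pred & (labels == 0)))
    fn_ = n_pos - tp_
    precision = tp_ / (tp_ + fp_) if tp_ + fp_ else 0.0
    recall = tp_ / (tp_ + fn_)
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return ClassificationMetrics(precision, recall, f1, float(auroc), auprc)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def assign_folds(
    pairs: Sequence[LabeledPair], n_folds: int = 5, seed: int = 0
) -> list[LabeledPair]:
    """Stratified fold assignment, deterministic given the seed.

    Folds depend only on the pair list and seed, so they stay identical
    across embedding sources.
    """
    y = np.array([p.label for p in pairs])
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            pairs[i].fold = fold
    return list(pairs)


def _sample_lr(rng) -> tuple[dict, Callable]:
    hp = {"C": float(10 ** rng.uniform(-3, 2))}
    return hp, lambda: LogisticRegression(
        C=hp["C"], class_weight="balanced", max_iter=500
    )


def _sample_rf(rng, seed: int) -> tuple[dict, Callable]:
    hp = {
        "n_estimators": int([50, 100, 200][rng.integers(3)]),
        "max_depth": [None, 4, 8, 16][rng.integers(4)],
    }
    return hp, lambda: RandomForestClassifier(
        n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
        class_weight="balanced", random_state=seed,
    )


def _sample_mlp(rng, seed: int) -> tuple[dict, Callable]:
    hp = {
        "hidden": int([16, 32, 64, 128][rng.integers(4)]),
        "learning_rate_init": float(10 ** rng.uniform(-4, -2)),
        "alpha": float(10 ** rng.uniform(-6, -2)),
    }
    return hp, lambda: MLPClassifier(
        hidden_layer_sizes=(hp["hidden"],), learning_rate_init=hp["learning_rate_init"],
        alpha=hp["alpha"], max_iter=300, random_state=seed,
    )


def _undersample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Undersample the majority class to a 1:1 ratio (for the MLP)."""
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    major, minor = (neg_idx, pos_idx) if len(neg_idx) > len(pos_idx) else (pos_idx, neg_idx)
    keep = rng.choice(major, size=len(minor), replace=False)
    idx = np.sort(np.concatenate([minor, keep]))
    return X[idx], y[idx]


def cross_validate(
    pairs: Sequence[LabeledPair],
    X: np.ndarray,
    classifiers: Sequence[str] = ("lr", "rf", "mlp"),
    n_trials: int = 10,
    seed: int = 0,
) -> CVReport:
    """Per-fold tuning (random search on validation AUPRC), refit, and scoring."""
    y = np.array([p.label for p in pairs])
    folds = sorted({p.fold for p in pairs})
    if None in folds:
        raise ValueError("pairs must carry fold assignments (see assign_folds)")
    results: list[FoldResult] = []

    for fold in folds:
        test_mask = np.array([p.fold == fold for p in pairs])
        X_tr, y_tr = X[~test_mask], y[~test_mask]
        X_te, y_te = X[test_mask], y[test_mask]
        if len(set(y_te.tolist())) < 2 or len(set(y_tr.tolist())) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        X_fit, X_val, y_fit, y_val = train_test_split(
            X_tr, y_tr, test_size=0.1, stratify=y_tr, random_state=seed + fold
        )

        for clf_name in classifiers:
            clf_salt = {"lr": 1, "rf": 2, "mlp": 3}.get(clf_name, 9)
            rng = np.random.default_rng([seed, fold, clf_salt])
            best_auprc, best_factory, best_hp = -np.inf, None, {}
            for _ in range(n_trials):
                if clf_name == "lr":
                    hp, factory = _sample_lr(rng)
                elif clf_name == "rf":
                    hp, factory = _sample_rf(rng, seed + fold)
                elif clf_name == "mlp":
                    hp, factory = _sample_mlp(rng, seed + fold)
                else:
                    raise ValueError(f"unknown classifier {clf_name!r}")
                model = factory()
                if clf_name == "mlp":
                    Xu, yu = _undersample(X_fit, y_fit, rng)
                    model.fit(Xu, yu)
                else:
                    model.fit(X_fit, y_fit)
                val_scores = model.predict_proba(X_val)[:, 1]
                auprc = classification_metrics(val_scores, y_val).auprc
                if auprc > best_auprc:
                    best_auprc, best_factory, best_hp = auprc, factory, hp

            final = best_factory()
            if clf_name == "mlp":
                Xu, yu = _undersample(
                    X_tr, y_tr, np.random.default_rng([seed, fold, 7])
                )
                final.fit(Xu, yu)
            else:
                final.fit(X_tr, y_tr)
            te_scores = final.predict_proba(X_te)[:, 1]
            m = classification_metrics(te_scores, y_te)
            results.append(FoldResult(
                clf_name, fold, m.precision, m.recall, m.f1, m.auroc, m.auprc,
                hyperparameters=best_hp,
            ))
    return CVReport(results)
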