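"""Losses, negative sampling, the joint SGD loop, and pretraining transfer.

Training follows the classic corruption scheme: for each observed triple
(h, r, t) a negative is built by replacing the head or the tail with an
entity sampled uniformly at random, and a loss contrasts the scores of the
true and corrupted triples.  Parameters (encoder weights plus the lookup
matrices) are updated by plain stochastic gradient descent,

    theta <- theta - alpha * grad L,

with an L2 penalty on the embedding vectors of the positive triple applied
inside the gradient (the reported loss stays unregularized).  Everything is
deterministic given the seed; the RNG draw order is part of the contract:

    per epoch: one permutation of the triple order, then per triple and per
    negative: one integer draw for the corrupted side (0=head, 1=tail) and
    integer draws for the replacement, redrawn while it equals the entity it
    replaces.

A cheap *pretraining* stage can be run with attributes ignored (all-lookup);
``pretrain_transfer`` then copies its relation rows and its rows for
attribute-less entities into a fresh encoder-equipped model, discarding the
stage-1 rows of attribute-covered entities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoders import EncoderRegistry
from .kg_data import AttributedKG, Triple
from .scoring import Scorer

logger = logging.getLogger(__name__)

LOSS_KINDS = ("margin_ranking", "binary_cross_entropy", "cross_entropy")

#: loss families the original scorers were introduced with
PREFERRED_LOSSES = {
    "transe": ("margin_ranking",),
    "complex": ("binary_cross_entropy", "cross_entropy"),
    "rotate": ("binary_cross_entropy", "cross_entropy"),
}


@dataclass(frozen=True)
class LossSpec:
    kind: str = "margin_ranking"
    margin: float = 1.0
    num_negatives: int = 1

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss {self.kind!r}")
        if self.kind == "margin_ranking" and self.margin <= 0:
            raise ValueError("margin must be > 0 for margin ranking")
        if self.num_negatives < 1:
            raise ValueError("need at least one negative per positive")


@dataclass
class TrainState:
    """Mutable training state; the parameters theta live in the registry.

    ``optimizer`` selects between the plain SGD update rule (the verifiable
    core; all golden tests use it) and an adaptive-moment mode ("adam") for
    practical runs, which equalizes the very different gradient scales of
    encoder weights and lookup rows.
    """

    registry: EncoderRegistry
    learning_rate: float = 0.01
    reg_weight: float = 0.0
    seed: int = 0
    step: int = 0
    optimizer: str = "sgd"
    loss_history: list[float] = field(default_factory=list)
    moments: dict = field(default_factory=dict, repr=False)


_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


def apply_update(state: TrainState) -> None:
    """One optimizer step over all trainable parameters (gradients in place)."""
    lr = state.learning_rate
    if state.optimizer == "sgd":
        for _, p, g in state.registry.named_parameters():
            p -= lr * g
        return
    if state.optimizer != "adam":
        raise ValueError(f"unknown optimizer {state.optimizer!r}")
    state.step_adam = t = getattr(state, "step_adam", 0) + 1
    for name, p, g in state.registry.named_parameters():
        m, v = state.moments.setdefault(
            name, (np.zeros_like(p), np.zeros_like(p)))
        m *= _ADAM_B1
        m += (1 - _ADAM_B1) * g
        v *= _ADAM_B2
        v += (1 - _ADAM_B2) * g * g
        mhat = m / (1 - _ADAM_B1 ** t)
        vhat = v / (1 - _ADAM_B2 ** t)
        p -= lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)


@dataclass(frozen=True)
class CorruptedTriple:
    original: Triple
    side: str  # "head" | "tail"
    replacement: str

    @property
    def corrupted(self) -> Triple:
        if self.side == "head":
            return Triple(self.replacement, self.original.relation, self.original.tail)
        return Triple(self.original.head, self.original.relation, self.replacement)


# ---------------------------------------------------------------------------
# Losses (value + derivative w.r.t. the scores)
# ---------------------------------------------------------------------------

def margin_ranking_loss(f_pos: float, f_neg: float, m: float) -> float:
    """max(0, f_neg - f_pos + m): zero exactly when the margin is satisfied."""
    if m <= 0:
        raise ValueError("margin must be > 0")
    return max(0.0, f_neg - f_pos + m)


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # log(sigma(x)) = -log(1 + exp(-x)), stable for large |x|
    return -np.logaddexp(0.0, -x)


def binary_ce_loss(f_pos: float, f_negs: Sequence[float]) -> float:
    """Mean of -log sigma(f_pos) and -log(1 - sigma(f_neg_j)) over 1+k terms."""
    f_negs = np.asarray(f_negs, float)
    total = -_log_sigmoid(np.asarray(f_pos, float)) + np.sum(
        np.logaddexp(0.0, f_negs)
    )
    return float(total / (1 + f_negs.size))


def cross_entropy_loss(f_pos: float, f_negs: Sequence[float]) -> float:
    """-log softmax of the positive among {positive} + negatives."""
    f_negs = np.asarray(f_negs, float)
    if f_negs.size < 1:
        raise ValueError("cross-entropy needs at least one negative")
    z = np.concatenate([[f_pos], f_negs])
    zmax = z.max()
    return float(zmax - f_pos + np.log(np.sum(np.exp(z - zmax))))


def loss_and_score_grads(
    spec: LossSpec, f_pos: float, f_negs: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Loss value and dL/df for the positive and each negative score."""
    k = f_negs.size
    if spec.kind == "margin_ranking":
        hinge = f_negs - f_pos + spec.margin
        active = hinge > 0
        loss = float(np.sum(np.maximum(hinge, 0.0)) / k)
        g_neg = active.astype(float) / k
        return loss, float(-g_neg.sum()), g_neg
    if spec.kind == "binary_cross_entropy":
        denom = 1 + k
        loss = binary_ce_loss(f_pos, f_negs)
        sig = 1.0 / (1.0 + np.exp(-np.clip(f_negs, -500, 500)))
        sig_pos = 1.0 / (1.0 + np.exp(-np.clip(f_pos, -500, 500)))
        return loss, float((sig_pos - 1.0) / denom), sig / denom
    # cross entropy
    z = np.concatenate([[f_pos], f_negs])
    zmax = z.max()
    p = np.exp(z - zmax)
    p /= p.sum()
    loss = float(zmax - f_pos + np.log(np.sum(np.exp(z - zmax))))
    return loss, float(p[0] - 1.0), p[1:]


# ---------------------------------------------------------------------------
# Negative sampling
# ---------------------------------------------------------------------------

def corrupt_triple(
    triple: Triple,
    entities: Sequence[str] | AttributedKG,
    rng: np.random.Generator,
) -> CorruptedTriple:
    """Corrupt head or tail (uniform side) with a uniform replacement != original."""
    if isinstance(entities, AttributedKG):
        entities = sorted(entities.entities)
    n = len(entities)
    if n < 2:
        raise ValueError("cannot corrupt: need at least two entities")
    side = "head" if rng.integers(2) == 0 else "tail"
    original = triple.head if side == "head" else triple.tail
    replacement = entities[rng.integers(n)]
    while replacement == original:
        replacement = entities[rng.integers(n)]
    return CorruptedTriple(triple, side, replacement)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _loss_and_grads_batch(
    spec: LossSpec, f_pos: np.ndarray, f_negs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched loss values and score gradients: f_pos (B,), f_negs (B, k)."""
    k = f_negs.shape[1]
    if spec.kind == "margin_ranking":
        hinge = f_negs - f_pos[:, None] + spec.margin
        active = hinge > 0
        loss = np.sum(np.maximum(hinge, 0.0), axis=1) / k
        g_neg = active.astype(float) / k
        return loss, -g_neg.sum(axis=1), g_neg
    if spec.kind == "binary_cross_entropy":
        denom = 1 + k
        loss = (np.logaddexp(0.0, -f_pos)
                + np.sum(np.logaddexp(0.0, f_negs), axis=1)) / denom
        sig_pos = 1.0 / (1.0 + np.exp(-np.clip(f_pos, -500, 500)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(f_negs, -500, 500)))
        return loss, (sig_pos - 1.0) / denom, sig / denom
    z = np.concatenate([f_pos[:, None], f_negs], axis=1)
    zmax = np.max(z, axis=1)
    p = np.exp(z - zmax[:, None])
    p /= p.sum(axis=1, keepdims=True)
    loss = zmax - f_pos + np.log(np.sum(np.exp(z - zmax[:, None]), axis=1))
    return loss, p[:, 0] - 1.0, p[:, 1:]


def _train_lookup_fast(
    registry: EncoderRegistry,
    scorer: Scorer,
    loss: LossSpec,
    state: TrainState,
    triples: list[Triple],
    entities: list[str],
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    on_epoch_end=None,
) -> None:
    """Vectorized epoch loop for the all-lookup case (no attribute encoders).

    Consumes the RNG in exactly the per-triple order documented in the module
    docstring; only the arithmetic is batched.  Gradients are scattered into
    W_e in the fixed order: positive heads, positive tails, then replacement
    entities, followed by one scatter into W_r.
    """
    lut = registry.lookup
    e_ix = lut.entity_index
    r_ix = lut.relation_index
    n_ent = len(entities)
    h_all = np.array([e_ix[t.head] for t in triples])
    r_all = np.array([r_ix[t.relation] for t in triples])
    t_all = np.array([e_ix[t.tail] for t in triples])
    k = loss.num_negatives
    alpha, lam = state.learning_rate, state.reg_weight

    for epoch in range(epochs):
        order = rng.permutation(len(triples))
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            h_ix, r_ixb, t_ix = h_all[batch], r_all[batch], t_all[batch]
            B = len(batch)
            sides = np.empty((B, k), dtype=np.int64)  # 0 = head, 1 = tail
            reps = np.empty((B, k), dtype=np.int64)
            for i in range(B):
                for j in range(k):
                    side = rng.integers(2)
                    orig = h_ix[i] if side == 0 else t_ix[i]
                    rep = rng.integers(n_ent)
                    while rep == orig:
                        rep = rng.integers(n_ent)
                    sides[i, j], reps[i, j] = side, rep

            H, R, T = lut.W_e[h_ix], lut.W_r[r_ixb], lut.W_e[t_ix]
            REP = lut.W_e[reps]  # (B, k, d)
            head_side = (sides == 0)[..., None]
            NH = np.where(head_side, REP, H[:, None, :])
            NT = np.where(head_side, T[:, None, :], REP)
            f_pos = scorer.score(H, R, T)
            f_neg = scorer.score(NH, R[:, None, :], NT)

            lval, g_pos, g_neg = _loss_and_grads_batch(loss, f_pos, f_neg)
            if not np.all(np.isfinite(lval)):
                bad = batch[int(np.argmax(~np.isfinite(lval)))]
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}, "
                    f"triple {triples[bad]}"
                )
            epoch_loss += float(lval.sum())

            gh, gr, gt = scorer.grad(H, R, T)
            nh, nr, nt = scorer.grad(NH, R[:, None, :], NT)
            Gh = g_pos[:, None] * gh + np.sum(
                np.where(head_side, 0.0, g_neg[..., None] * nh), axis=1)
            Gt = g_pos[:, None] * gt + np.sum(
                np.where(head_side, g_neg[..., None] * nt, 0.0), axis=1)
            Gr = g_pos[:, None] * gr + np.sum(g_neg[..., None] * nr, axis=1)
            Grep = g_neg[..., None] * np.where(head_side, nh, nt)
            if lam:
                Gh = Gh + 2.0 * lam * H
                Gt = Gt + 2.0 * lam * T
                Gr = Gr + 2.0 * lam * R

            registry.zero_grads()
            np.add.at(lut.g_W_e, h_ix, Gh)
            np.add.at(lut.g_W_e, t_ix, Gt)
            np.add.at(lut.g_W_e, reps.ravel(), Grep.reshape(B * k, -1))
            np.add.at(lut.g_W_r, r_ixb, Gr)
            apply_update(state)
            state.step += 1
        state.loss_history.append(epoch_loss / len(triples))
        if on_epoch_end is not None:
            on_epoch_end(epoch, state.loss_history[-1])


def _check_compatibility(scorer: Scorer, loss: LossSpec) -> None:
    preferred = PREFERRED_LOSSES.get(scorer.name, LOSS_KINDS)
    if loss.kind not in preferred:
        logger.warning(
            "loss %s is unusual for scorer %s (typical: %s)",
            loss.kind, scorer.name, "/".join(preferred),
        )


def train(
    kg: AttributedKG,
    registry: EncoderRegistry,
    scorer: Scorer,
    loss: LossSpec,
    state: TrainState,
    epochs: int = 10,
    batch_size: int = 128,
    triples: Sequence[Triple] | None = None,
    on_epoch_end=None,
) -> TrainState:
    """Joint SGD over encoder parameters and lookup tables.

    ``triples`` defaults to ``kg.triples`` (pass the training split when the
    graph has been partitioned).  One batch = embed, corrupt, score, loss,
    accumulate gradients, single SGD update.  The L2 penalty (weight
    ``state.reg_weight``) acts on the embedding vectors of each positive
    triple and is applied inside the gradient only.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    _check_compatibility(scorer, loss)
    triples = list(triples if triples is not None else kg.triples)
    entities = sorted(kg.entities)
    rng = np.random.default_rng(state.seed)
    alpha, lam = state.learning_rate, state.reg_weight

    # fast path: pure-lookup model whose W_e rows are exactly the entity list
    all_lookup = not registry.encoders and all(
        registry.lookup.entity_index.get(v) == i for i, v in enumerate(entities)
    )
    if all_lookup:
        _train_lookup_fast(registry, scorer, loss, state, triples, entities,
                           epochs, batch_size, rng, on_epoch_end)
        return state

    for epoch in range(epochs):
        order = rng.permutation(len(triples))
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            registry.zero_grads()
            for idx in batch:
                trp = triples[idx]
                h_emb, h_cache = registry.forward_entity(trp.head, kg)
                t_emb, t_cache = registry.forward_entity(trp.tail, kg)
                r_emb = registry.embed_relation(trp.relation)

                negs = [
                    corrupt_triple(trp, entities, rng)
                    for _ in range(loss.num_negatives)
                ]
                neg_embs, neg_caches, f_negs = [], [], []
                for c in negs:
                    rep_emb, rep_cache = registry.forward_entity(c.replacement, kg)
                    neg_embs.append(rep_emb)
                    neg_caches.append(rep_cache)
                    if c.side == "head":
                        f_negs.append(scorer.score(rep_emb, r_emb, t_emb))
                    else:
                        f_negs.append(scorer.score(h_emb, r_emb, rep_emb))
                f_pos = float(scorer.score(h_emb, r_emb, t_emb))
                f_negs = np.asarray(f_negs, float)

                lval, g_pos, g_negs = loss_and_score_grads(loss, f_pos, f_negs)
                if not np.isfinite(lval):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch start {start}, "
                        f"triple {trp}"
                    )
                epoch_loss += lval

                gh, gr, gt = scorer.grad(h_emb, r_emb, t_emb)
                acc_h = g_pos * gh
                acc_r = g_pos * gr
                acc_t = g_pos * gt
                for c, rep_emb, rep_cache, gn in zip(negs, neg_embs, neg_caches, g_negs):
                    if c.side == "head":
                        nh, nr, nt = scorer.grad(rep_emb, r_emb, t_emb)
                        registry.backward_entity(rep_cache, gn * nh)
                        acc_r += gn * nr
                        acc_t += gn * nt
                    else:
                        nh, nr, nt = scorer.grad(h_emb, r_emb, rep_emb)
                        acc_h += gn * nh
                        acc_r += gn * nr
                        registry.backward_entity(rep_cache, gn * nt)
                if lam:
                    acc_h = acc_h + 2.0 * lam * h_emb
                    acc_r = acc_r + 2.0 * lam * r_emb
                    acc_t = acc_t + 2.0 * lam * t_emb
                registry.backward_entity(h_cache, acc_h)
                registry.backward_entity(t_cache, acc_t)
                registry.backward_relation(trp.relation, acc_r)

            apply_update(state)
            state.step += 1
        state.loss_history.append(epoch_loss / len(triples))
        if on_epoch_end is not None:
            on_epoch_end(epoch, state.loss_history[-1])
    return state


# ---------------------------------------------------------------------------
# Two-stage pretraining
# ---------------------------------------------------------------------------

def pretrain_transfer(
    pretrained: TrainState,
    kg: AttributedKG,
    registry: EncoderRegistry,
) -> TrainState:
    """Initialize a fresh encoder-equipped model from an all-lookup stage-1 run.

    Relation rows are copied in full; W_e rows are copied for attribute-less
    entities; the stage-1 rows of attribute-covered entities are discarded
    (those entities are now embedded by freshly initialized encoders).
    """
    src = pretrained.registry
    if src.scorer_name != registry.scorer_name or src.space != registry.space:
        raise ValueError("pretrained model uses a different scorer or dimension")
    if src.lookup.relation_index != registry.lookup.relation_index:
        raise ValueError("relation index mismatch between stages")
    missing = set(registry.lookup.entity_index) - set(src.lookup.entity_index)
    if missing:
        raise ValueError(f"stage-1 model lacks rows for entities: {sorted(missing)[:5]}")

    registry.lookup.W_r[...] = src.lookup.W_r
    for ent, row in registry.lookup.entity_index.items():
        registry.lookup.W_e[row] = src.lookup.W_e[src.lookup.entity_index[ent]]
    return TrainState(
        registry=registry,
        learning_rate=pretrained.learning_rate,
        reg_weight=pretrained.reg_weight,
        seed=pretrained.seed,
    )


# ---------------------------------------------------------------------------
# Hyperparameter ranges (random search)
# ---------------------------------------------------------------------------

BATCH_SIZES = (128, 256, 512, 1024)


def sample_hyperparameters(rng: np.random.Generator) -> dict:
    """One random draw from the KGE hyperparameter ranges.

    Learning rate log-uniform on [1e-3, 1], regularization weight log-uniform
    on [1e-6, 1e-3], batch size in {128, 256, 512, 1024}, loss one of the
    three supported kinds.
    """
    return {
        "learning_rate": float(10 ** rng.uniform(-3, 0)),
        "reg_weight": float(10 ** rng.uniform(-6, -3)),
        "batch_size": int(BATCH_SIZES[rng.integers(len(BATCH_SIZES))]),
        "loss": LOSS_KINDS[rng.integers(len(LOSS_KINDS))],
    }
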