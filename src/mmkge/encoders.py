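"""Modality-specific attribute encoders and lookup-table fallbacks.

Every entity resolves to exactly one embedding path:

* entities with a protein sequence -> mean of frozen per-residue features,
  linearly projected into the embedding space;
* entities with a molecule string -> single-head self-attention over frozen
  per-character features (with a BOS marker prepended), first-position output
  projected into the embedding space;
* entities with a text description -> mean of *trainable* token embeddings
  (lowercased whitespace tokens, truncated to ``max_length``), projected;
* everything else -> a row of the trainable lookup matrix ``W_e``.

Relations are always lookup rows of ``W_r`` (phase vectors for the rotation
scorer).  Frozen feature tables stand in for large pretrained sequence and
molecule language models: they are seeded random by default, but per-token
features exported from a real model can be loaded from TSV behind the same
interface.  Only projections, attention weights, text token embeddings and
the lookup matrices receive gradients.

Entities unseen during training but equipped with an attribute record can be
embedded through the same encoders (inductive link prediction); attribute-less
unseen entities cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .kg_data import AttributedKG, AttributeRecord, TYPE_MODALITY
from .scoring import Scorer

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
# character-level SMILES vocabulary; unknown characters map to UNK
MOLECULE_ALPHABET = tuple("BCFHINOPSclnos()[]=#@+-\\/.%0123456789")
UNK = "<unk>"
BOS = "<bos>"


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[-1], shape[0]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


# ---------------------------------------------------------------------------
# Frozen feature tables
# ---------------------------------------------------------------------------

@dataclass
class FrozenFeatureTable:
    """Per-token feature vectors that never receive gradients."""

    tokens: tuple[str, ...]
    features: np.ndarray  # (len(tokens), n_e)
    frozen: bool = True
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.tokens) != self.features.shape[0]:
            raise ValueError("one feature row per token required")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature rows")
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.features.setflags(write=False)

    @property
    def n_e(self) -> int:
        return self.features.shape[1]

    def row(self, token: str) -> int:
        return self.index.get(token, self.index[UNK])

    @classmethod
    def random(
        cls,
        alphabet: Sequence[str],
        n_e: int,
        seed: int,
        with_bos: bool = False,
    ) -> "FrozenFeatureTable":
        """Seeded random stand-in for a pretrained per-token feature export."""
        tokens = tuple(alphabet) + ((BOS,) if with_bos else ()) + (UNK,)
        rng = np.random.default_rng(seed)
        feats = rng.standard_normal((len(tokens), n_e)) / np.sqrt(n_e)
        return cls(tokens, feats)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrozenFeatureTable":
        """Load ``token<TAB>f_1..f_{n_e}`` rows (e.g. real pretrained features)."""
        tokens, rows = [], []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                tokens.append(cols[0])
                rows.append([float(x) for x in cols[1:]])
        if UNK not in tokens:
            raise ValueError(f"{path}: feature table must include an {UNK} row")
        return cls(tuple(tokens), np.asarray(rows, dtype=float))


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

class ModalityEncoder:
    """Base class: forward returns (embedding, cache); backward accumulates grads."""

    modality: str

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)

    def zero_grads(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def forward(self, payload: str):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, g: np.ndarray) -> None:  # pragma: no cover
        raise NotImplementedError

    def encode(self, payload: str) -> np.ndarray:
        return self.forward(payload)[0]


class ProteinEncoder(ModalityEncoder):
    """Mean over frozen per-residue features, then a learned linear projection."""

    modality = "protein_sequence"

    def __init__(self, table: FrozenFeatureTable, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = table
        self._register("P", xavier_uniform(rng, (out_dim, table.n_e)))

    def forward(self, payload: str):
        if not payload:
            raise ValueError("empty attribute payload")
        rows = [self.table.row(a) for a in payload]
        x = self.table.features[rows].mean(axis=0)
        return self.params["P"] @ x, x

    def backward(self, cache, g: np.ndarray) -> None:
        self.grads["P"] += np.outer(g, cache)


class MoleculeEncoder(ModalityEncoder):
    """Single-head self-attention over frozen character features.

    A BOS marker is prepended; softmax(Q K^T / sqrt(d)) V is computed without
    residual connections and the output at the BOS position is projected into
    the embedding space.  Trainable: W_q, W_k, W_v, P.
    """

    modality = "molecule_string"

    def __init__(self, table: FrozenFeatureTable, out_dim: int, rng: np.random.Generator):
        super().__init__()
        if BOS not in table.index:
            raise ValueError("molecule feature table must include a BOS row")
        self.table = table
        n_e = table.n_e
        self._register("Wq", xavier_uniform(rng, (n_e, n_e)))
        self._register("Wk", xavier_uniform(rng, (n_e, n_e)))
        self._register("Wv", xavier_uniform(rng, (n_e, n_e)))
        self._register("P", xavier_uniform(rng, (out_dim, n_e)))

    def forward(self, payload: str):
        if not payload:
            raise ValueError("empty attribute payload")
        rows = [self.table.index[BOS]] + [self.table.row(ch) for ch in payload]
        X = self.table.features[rows]  # (L+1, n_e)
        Wq, Wk, Wv, P = (self.params[k] for k in ("Wq", "Wk", "Wv", "P"))
        q0 = X[0] @ Wq                      # only the BOS query is needed
        K = X @ Wk
        V = X @ Wv
        logits = (K @ q0) / np.sqrt(X.shape[1])
        a = np.exp(logits - logits.max())
        a /= a.sum()
        out0 = a @ V
        cache = {"X": X, "q0": q0, "K": K, "a": a, "V": V, "out0": out0}
        return P @ out0, cache

    def backward(self, cache, g: np.ndarray) -> None:
        X, q0, K, a, V, out0 = (
            cache["X"], cache["q0"], cache["K"], cache["a"], cache["V"], cache["out0"]
        )
        sqrt_d = np.sqrt(X.shape[1])
        self.grads["P"] += np.outer(g, out0)
        g_out0 = self.params["P"].T @ g
        g_a = V @ g_out0
        g_V = np.outer(a, g_out0)
        g_logits = a * (g_a - g_a @ a)  # softmax backward
        g_q0 = (g_logits @ K) / sqrt_d
        g_K = np.outer(g_logits, q0) / sqrt_d
        self.grads["Wq"] += np.outer(X[0], g_q0)
        self.grads["Wk"] += X.T @ g_K
        self.grads["Wv"] += X.T @ g_V


class TextEncoder(ModalityEncoder):
    """Mean of trainable token embeddings, truncated to ``max_length`` tokens.

    Both the token-embedding table and the projection receive gradients,
    mirroring a fully fine-tuned text encoder; a pretrained transformer
    backbone can be substituted behind the same forward/backward contract.
    """

    modality = "text"

    def __init__(
        self,
        vocabulary: Sequence[str],
        n_e: int,
        out_dim: int,
        rng: np.random.Generator,
        max_length: int = 64,
    ):
        super().__init__()
        self.vocab = {t: i for i, t in enumerate(tuple(vocabulary) + (UNK,))}
        self.max_length = max_length
        self._register("E", xavier_uniform(rng, (len(self.vocab), n_e)))
        self._register("P", xavier_uniform(rng, (out_dim, n_e)))

    def tokenize(self, text: str) -> list[int]:
        toks = text.lower().split()
        if not toks:
            raise ValueError("empty attribute payload")
        toks = toks[: self.max_length]
        unk = self.vocab[UNK]
        return [self.vocab.get(t, unk) for t in toks]

    def forward(self, payload: str):
        rows = self.tokenize(payload)
        x = self.params["E"][rows].mean(axis=0)
        return self.params["P"] @ x, (rows, x)

    def backward(self, cache, g: np.ndarray) -> None:
        rows, x = cache
        self.grads["P"] += np.outer(g, x)
        g_tok = (self.params["P"].T @ g) / len(rows)
        np.add.at(self.grads["E"], rows, g_tok)


# ---------------------------------------------------------------------------
# Lookup tables and registry
# ---------------------------------------------------------------------------

class LookupTables:
    """Trainable matrices W_e (attribute-less entities) and W_r (relations)."""

    def __init__(
        self,
        lookup_entities: Sequence[str],
        relations: Sequence[str],
        entity_dim: int,
        relation_dim: int,
        rng: np.random.Generator,
    ):
        self.entity_index = {v: i for i, v in enumerate(sorted(set(lookup_entities)))}
        self.relation_index = {r: i for i, r in enumerate(sorted(set(relations)))}
        self.W_e = xavier_uniform(rng, (max(1, len(self.entity_index)), entity_dim))
        self.W_r = xavier_uniform(rng, (max(1, len(self.relation_index)), relation_dim))
        self.g_W_e = np.zeros_like(self.W_e)
        self.g_W_r = np.zeros_like(self.W_r)

    def zero_grads(self) -> None:
        self.g_W_e[...] = 0.0
        self.g_W_r[...] = 0.0


class EncoderRegistry:
    """Total dispatch from entities and relations to embeddings in X.

    Entities with an attribute record go through their modality encoder;
    attribute-less entities through ``W_e``; relations through ``W_r``.
    """

    def __init__(
        self,
        kg: AttributedKG,
        scorer: Scorer,
        seed: int = 0,
        n_e: int = 32,
        max_text_length: int = 64,
        feature_tables: Mapping[str, FrozenFeatureTable] | None = None,
    ):
        self.space = scorer.space
        self.scorer_name = scorer.name
        self.entity_dim = scorer.entity_dim
        self.relation_dim = scorer.relation_dim
        rng = np.random.default_rng(seed)

        lookup_entities = sorted(kg.entities - kg.covered_entities)
        self.lookup = LookupTables(
            lookup_entities, sorted(kg.relations), self.entity_dim,
            self.relation_dim, rng,
        )

        tables = dict(feature_tables or {})
        modalities = {rec.modality for rec in kg.attributes.values()}
        self.encoders: dict[str, ModalityEncoder] = {}
        if "protein_sequence" in modalities:
            tab = tables.get(
                "protein_sequence",
                FrozenFeatureTable.random(PROTEIN_ALPHABET, n_e, seed=hash_seed(seed, 1)),
            )
            self.encoders["protein_sequence"] = ProteinEncoder(tab, self.entity_dim, rng)
        if "molecule_string" in modalities:
            tab = tables.get(
                "molecule_string",
                FrozenFeatureTable.random(
                    MOLECULE_ALPHABET, n_e, seed=hash_seed(seed, 2), with_bos=True
                ),
            )
            self.encoders["molecule_string"] = MoleculeEncoder(tab, self.entity_dim, rng)
        if "text" in modalities:
            vocab = sorted({
                tok
                for rec in kg.attributes.values()
                if rec.modality == "text"
                for tok in rec.payload.lower().split()
            })
            self.encoders["text"] = TextEncoder(
                vocab, n_e, self.entity_dim, rng, max_length=max_text_length
            )

    # -- embedding paths ---------------------------------------------------

    def forward_entity(self, v: str, kg: AttributedKG | None = None,
                       attribute: AttributeRecord | None = None):
        """Return (embedding, path cache) for one entity.

        ``attribute`` overrides the KG attribute map, enabling inductive
        embedding of entities absent from training.
        """
        rec = attribute
        if rec is None and kg is not None:
            rec = kg.attributes.get(v)
        if rec is not None:
            enc = self.encoders.get(rec.modality)
            if enc is None:
                raise ValueError(f"no encoder for modality {rec.modality!r}")
            emb, cache = enc.forward(rec.payload)
            return emb, ("enc", rec.modality, cache)
        idx = self.lookup.entity_index.get(v)
        if idx is None:
            raise ValueError(f"entity not embeddable: {v!r}")
        return self.lookup.W_e[idx], ("lookup", idx, None)

    def embed_entity(self, v: str, kg: AttributedKG | None = None,
                     attribute: AttributeRecord | None = None) -> np.ndarray:
        return self.forward_entity(v, kg, attribute)[0]

    def backward_entity(self, cache, g: np.ndarray) -> None:
        kind, key, inner = cache
        if kind == "enc":
            self.encoders[key].backward(inner, g)
        else:
            self.lookup.g_W_e[key] += g

    def embed_relation(self, r: str) -> np.ndarray:
        idx = self.lookup.relation_index.get(r)
        if idx is None:
            raise ValueError(f"unknown relation: {r!r}")
        return self.lookup.W_r[idx]

    def backward_relation(self, r: str, g: np.ndarray) -> None:
        self.lookup.g_W_r[self.lookup.relation_index[r]] += g

    def all_entity_embeddings(
        self, kg: AttributedKG, entity_order: Sequence[str]
    ) -> np.ndarray:
        return np.stack([self.embed_entity(v, kg) for v in entity_order])

    # -- parameter plumbing ------------------------------------------------

    def zero_grads(self) -> None:
        self.lookup.zero_grads()
        for enc in self.encoders.values():
            enc.zero_grads()

    def named_parameters(self):
        """Yield (name, parameter array, gradient array) for all trainables."""
        yield "W_e", self.lookup.W_e, self.lookup.g_W_e
        yield "W_r", self.lookup.W_r, self.lookup.g_W_r
        for mod in sorted(self.encoders):
            enc = self.encoders[mod]
            for name in sorted(enc.params):
                yield f"{mod}.{name}", enc.params[name], enc.grads[name]

    def sgd_step(self, lr: float) -> None:
        for _, p, g in self.named_parameters():
            p -= lr * g


def hash_seed(seed: int, salt: int) -> int:
    """Derive a stable sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))
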