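"""Checkpoints: parameter blocks + index maps + config, as .npz archives.

A checkpoint stores every trainable parameter, the frozen feature tables,
the entity/relation index maps and the model config (scorer, dimension,
seeds).  Loading rebuilds the registry against the *same* KG files and
overwrites its parameters, verifying that the index maps agree.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .encoders import EncoderRegistry, FrozenFeatureTable
from .kg_data import AttributedKG
from .scoring import make_scorer
from .training import TrainState


def save_checkpoint(state: TrainState, path: str | Path, norm: int = 2) -> None:
    reg = state.registry
    arrays: dict[str, np.ndarray] = {}
    for name, p, _ in reg.named_parameters():
        arrays[f"param/{name}"] = p
    for mod, enc in reg.encoders.items():
        table = getattr(enc, "table", None)
        if table is not None:
            arrays[f"features/{mod}"] = np.asarray(table.features)
    meta = {
        "scorer": reg.scorer_name,
        "dimension": reg.space.dimension,
        "norm": norm,
        "seed": state.seed,
        "learning_rate": state.learning_rate,
        "reg_weight": state.reg_weight,
        "loss_history": state.loss_history,
        "entity_index": reg.lookup.entity_index,
        "relation_index": reg.lookup.relation_index,
        "feature_tokens": {
            mod: list(enc.table.tokens)
            for mod, enc in reg.encoders.items()
            if getattr(enc, "table", None) is not None
        },
        "text_vocab": {
            mod: sorted(enc.vocab, key=enc.vocab.get)
            for mod, enc in reg.encoders.items()
            if hasattr(enc, "vocab")
        },
    }
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path, kg: AttributedKG) -> tuple[TrainState, object]:
    """Rebuild (state, scorer) from a checkpoint against the same KG."""
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    scorer = make_scorer(meta["scorer"], meta["dimension"], meta.get("norm", 2))

    tables = {}
    for mod, tokens in meta.get("feature_tokens", {}).items():
        tables[mod] = FrozenFeatureTable(tuple(tokens), data[f"features/{mod}"].copy())
    reg = EncoderRegistry(kg, scorer, seed=meta["seed"], feature_tables=tables)
    if reg.lookup.entity_index != meta["entity_index"]:
        raise ValueError("entity index mismatch: checkpoint was trained on a different KG")
    if reg.lookup.relation_index != meta["relation_index"]:
        raise ValueError("relation index mismatch")
    for name, p, _ in reg.named_parameters():
        p[...] = data[f"param/{name}"]
    state = TrainState(
        registry=reg,
        learning_rate=meta["learning_rate"],
        reg_weight=meta["reg_weight"],
        seed=meta["seed"],
        loss_history=list(meta.get("loss_history", [])),
    )
    return state, scorer
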