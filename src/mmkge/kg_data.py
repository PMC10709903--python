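"""Attributed knowledge graphs: domain types, file I/O, splitting, degrees.

A knowledge graph here is a tuple ``G = (V, R, E, D, d)``: typed entities
``V``, relations ``R``, directed triples ``E``, and a *partial* attribute map
``d`` from a subset of entities to modality-tagged payloads (amino-acid
sequences, SMILES-like molecule strings, or free text).  Partiality is a
first-class citizen — large biomedical graphs rarely have attributes for
every entity — and downstream encoders fall back to lookup embeddings for
uncovered entities.

Splitting supports *benchmark decoupling*: before a train/valid/test split is
made, every triple whose endpoint set coincides with a benchmark entity pair
is removed (in either orientation, for any relation), so that classifiers
later trained on the benchmark cannot leak KG edges.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("protein", "drug", "disease", "pathway", "disorder", "other")

#: entity type -> attribute modality carried by that type (others are lookup-only)
TYPE_MODALITY = {
    "protein": "protein_sequence",
    "drug": "molecule_string",
    "disease": "text",
}

MODALITIES = ("protein_sequence", "molecule_string", "text")


class Triple(NamedTuple):
    """A directed edge (head, relation, tail)."""

    head: str
    relation: str
    tail: str


@dataclass(frozen=True)
class AttributeRecord:
    """Attribute payload of one entity, tagged with its modality."""

    modality: str
    payload: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.payload:
            raise ValueError("empty attribute payload")


@dataclass(frozen=True)
class BenchmarkPair:
    """An unordered benchmark entity pair (x, y), e.g. a drug-protein interaction."""

    x: str
    y: str
    label_source: str = ""

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError(f"benchmark pair with identical endpoints: {self.x!r}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.x, self.y))


@dataclass
class AttributedKG:
    """The tuple G = (V, R, E, D, d).

    ``entity_types`` maps every entity id in V to its type label;
    ``attributes`` is the partial map d, defined on V_d ⊆ V.
    """

    entity_types: dict[str, str]
    relations: set[str]
    triples: list[Triple]
    attributes: dict[str, AttributeRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, t in self.entity_types.items():
            if t not in ENTITY_TYPES:
                raise ValueError(f"unknown entity type {t!r} for entity {v!r}")
        ents = self.entities
        for tr in self.triples:
            if not (tr.head and tr.relation and tr.tail):
                raise ValueError(f"triple with empty component: {tr}")
            if tr.head not in ents or tr.tail not in ents:
                raise ValueError(f"triple references unknown entity: {tr}")
            if tr.relation not in self.relations:
                raise ValueError(f"triple references unknown relation: {tr}")
        for v in self.attributes:
            if v not in ents:
                raise ValueError(f"attribute for unknown entity {v!r}")

    @property
    def entities(self) -> set[str]:
        return set(self.entity_types)

    @property
    def covered_entities(self) -> set[str]:
        """V_d: the subset of entities with attribute data."""
        return set(self.attributes)

    def entity_type(self, v: str) -> str:
        return self.entity_types[v]

    def attribute_coverage(self) -> float:
        return len(self.attributes) / max(1, len(self.entity_types))

    def without_attributes(self) -> "AttributedKG":
        """A copy with the attribute map emptied (pure-lookup setting)."""
        return AttributedKG(
            entity_types=dict(self.entity_types),
            relations=set(self.relations),
            triples=list(self.triples),
            attributes={},
        )


@dataclass
class SplitResult:
    """Outcome of benchmark decoupling followed by a train/valid/test split."""

    train: list[Triple]
    valid: list[Triple]
    test: list[Triple]
    removed: list[Triple] = field(default_factory=list)
    dropped_entities: set[str] = field(default_factory=set)

    def stats(self) -> dict:
        return {
            "train": len(self.train),
            "valid": len(self.valid),
            "test": len(self.test),
            "removed": len(self.removed),
            "dropped_entities": len(self.dropped_entities),
        }


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path, min_cols: int) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, columns) for non-comment, non-blank lines.

    Dialect: UTF-8, tab-separated, ``#``-prefixed comment lines skipped,
    no quoting.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, found {len(cols)}"
                )
            yield lineno, cols


def read_triples(path: str | Path) -> list[Triple]:
    triples = [Triple(c[0], c[1], c[2]) for _, c in _read_tsv_rows(path, 3)]
    if not triples:
        raise ValueError(f"{path}: no triples")
    return triples


def write_triples(path: str | Path, triples: Iterable[Triple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def read_entity_types(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, cols in _read_tsv_rows(path, 2):
        if cols[0] in out and out[cols[0]] != cols[1]:
            raise ValueError(f"{path}:{lineno}: conflicting type for entity {cols[0]!r}")
        out[cols[0]] = cols[1]
    return out


def read_benchmark_pairs(path: str | Path, label_source: str = "") -> list[BenchmarkPair]:
    name = label_source or Path(path).stem
    return [BenchmarkPair(c[0], c[1], name) for _, c in _read_tsv_rows(path, 2)]


def _read_attribute_tsv(path: str | Path, modality: str) -> dict[str, AttributeRecord]:
    out: dict[str, AttributeRecord] = {}
    for lineno, cols in _read_tsv_rows(path, 2):
        ent, payload = cols[0], cols[1]
        if ent in out:
            raise ValueError(f"{path}:{lineno}: duplicate attribute for entity {ent!r}")
        out[ent] = AttributeRecord(modality, payload)
    return out


def _read_attribute_fasta(path: str | Path) -> dict[str, AttributeRecord]:
    out: dict[str, AttributeRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate attribute for entity {rec.id!r}")
        out[rec.id] = AttributeRecord("protein_sequence", str(rec.seq))
    return out


def load_kg(
    triples_path: str | Path,
    types_path: str | Path | None = None,
    attribute_paths: Mapping[str, str | Path] | None = None,
) -> AttributedKG:
    """Load an attributed KG from disk.

    Parameters
    ----------
    triples_path:
        TSV of ``head<TAB>relation<TAB>tail``.
    types_path:
        Optional TSV of ``entity<TAB>type``; entities not listed default to
        type ``other``.
    attribute_paths:
        Mapping from modality to file path: ``protein_sequence`` → FASTA
        (record id = entity id), ``molecule_string`` → TSV
        ``entity<TAB>smiles``, ``text`` → TSV ``entity<TAB>description``.
    """
    triples = read_triples(triples_path)
    ents = {e for t in triples for e in (t.head, t.tail)}
    types = read_entity_types(types_path) if types_path else {}
    entity_types = {v: types.get(v, "other") for v in ents}

    attributes: dict[str, AttributeRecord] = {}
    for modality, path in (attribute_paths or {}).items():
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        recs = (
            _read_attribute_fasta(path)
            if modality == "protein_sequence"
            else _read_attribute_tsv(path, modality)
        )
        for ent, rec in recs.items():
            if ent not in ents:
                logger.warning(
                    "attribute file %s: entity %r not in triples; ignored", path, ent
                )
                continue
            if ent in attributes:
                raise ValueError(f"duplicate attribute for entity {ent!r}")
            attributes[ent] = rec

    relations = {t.relation for t in triples}
    return AttributedKG(entity_types, relations, triples, attributes)


# ---------------------------------------------------------------------------
# Benchmark decoupling and splitting
# ---------------------------------------------------------------------------

def decouple_benchmarks(
    kg: AttributedKG, pairs: Sequence[BenchmarkPair]
) -> tuple[list[Triple], list[Triple]]:
    """Remove every triple whose endpoint set equals a benchmark pair.

    Removal is relation-agnostic and orientation-agnostic: a triple is removed
    iff ``{head, tail} == {x, y}`` for some pair.  Self-loops never match,
    because pairs have distinct endpoints.  Returns (kept, removed).
    """
    known = kg.entities
    unknown = sum(1 for p in pairs if p.x not in known or p.y not in known)
    if unknown:
        logger.warning("%d benchmark pairs reference entities absent from the KG", unknown)
    pair_keys = {p.key for p in pairs}
    kept, removed = [], []
    for t in kg.triples:
        if t.head != t.tail and frozenset((t.head, t.tail)) in pair_keys:
            removed.append(t)
        else:
            kept.append(t)
    return kept, removed


def split_triples(
    triples: Sequence[Triple],
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitResult:
    """Split triples into train/valid/test with an entity-coverage pass.

    Every entity must occur in at least one *training* triple (a requirement
    of lookup-table embeddings, which are undefined for unseen entities).  For
    each entity one uniformly-chosen incident triple is pinned to train, the
    remaining triples are shuffled, and valid/test are cut at the proportion
    boundaries; everything left goes to train.  Deterministic given the seed.
    """
    if any(p <= 0 for p in proportions):
        raise ValueError("proportions must be positive")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {sum(proportions)}")
    if not triples:
        raise ValueError("no triples to split")

    rng = np.random.default_rng(seed)
    n = len(triples)
    incident: dict[str, list[int]] = {}
    for i, t in enumerate(triples):
        incident.setdefault(t.head, []).append(i)
        incident.setdefault(t.tail, []).append(i)

    pinned: set[int] = set()
    for ent in sorted(incident):
        idxs = incident[ent]
        if not any(i in pinned for i in idxs):
            pinned.add(idxs[rng.integers(len(idxs))])

    rest = np.array([i for i in range(n) if i not in pinned], dtype=np.int64)
    rng.shuffle(rest)
    n_valid = int(round(proportions[1] * n))
    n_test = int(round(proportions[2] * n))
    if n_valid + n_test > len(rest):
        logger.warning(
            "entity coverage pinned %d triples to train; train oversized "
            "relative to requested proportion", len(pinned)
        )
        n_valid = min(n_valid, len(rest))
        n_test = min(n_test, len(rest) - n_valid)
    valid_idx = rest[:n_valid]
    test_idx = rest[n_valid : n_valid + n_test]
    train_idx = sorted(set(range(n)) - set(valid_idx.tolist()) - set(test_idx.tolist()))

    return SplitResult(
        train=[triples[i] for i in train_idx],
        valid=[triples[i] for i in sorted(valid_idx.tolist())],
        test=[triples[i] for i in sorted(test_idx.tolist())],
    )


def decouple_and_split(
    kg: AttributedKG,
    pairs: Sequence[BenchmarkPair],
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitResult:
    """Benchmark decoupling followed by a coverage-respecting split.

    Entities left with zero incident triples after decoupling are dropped and
    reported in ``dropped_entities``.
    """
    kept, removed = decouple_benchmarks(kg, pairs)
    if not kept:
        raise ValueError("decoupling removed all triples")
    surviving = {e for t in kept for e in (t.head, t.tail)}
    dropped = kg.entities - surviving
    result = split_triples(kept, proportions, seed)
    result.removed = removed
    result.dropped_entities = dropped
    return result


# ---------------------------------------------------------------------------
# Degrees
# ---------------------------------------------------------------------------

def entity_degree(triples: Sequence[Triple], v: str) -> int:
    """Sum of incoming and outgoing edges of ``v``; a self-loop counts 2."""
    return sum((t.head == v) + (t.tail == v) for t in triples)


def degree_map(triples: Sequence[Triple]) -> dict[str, int]:
    """Degrees of all entities appearing in ``triples`` (single pass)."""
    deg: Counter[str] = Counter()
    for t in triples:
        deg[t.head] += 1
        deg[t.tail] += 1
    return dict(deg)


def degree_summary(triples: Sequence[Triple]) -> dict:
    degs = np.array(sorted(degree_map(triples).values()), dtype=float)
    return {
        "mean": float(degs.mean()),
        "std": float(degs.std()),
        "min": float(degs.min()),
        "median": float(np.median(degs)),
        "max": float(degs.max()),
    }


def write_split(split: SplitResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_triples(out / "train.tsv", split.train)
    write_triples(out / "valid.tsv", split.valid)
    write_triples(out / "test.tsv", split.test)
    write_triples(out / "removed.tsv", split.removed)
    stats = split.stats()
    stats["dropped_entity_ids"] = sorted(split.dropped_entities)
    with open(out / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats, fh, indent=2)
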