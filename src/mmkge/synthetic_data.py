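"""Desk-scale synthetic attributed knowledge graphs.

The generator emulates the statistical structure that multimodal KG
embedding assumes in real biomedical graphs:

* a typed schema (proteins, drugs, diseases, pathways, gene disorders) with
  relation types restricted to legal type pairs;
* heavy-tailed node degrees (entity sampling weights follow a rank^(-a)
  law, so the degree histogram is right-skewed: mean > median);
* partial attribute coverage (default 68% of the attribute-eligible
  entities carry a payload);
* attributes that carry *link-relevant* signal: entities belong to latent
  classes with per-relation class-compatibility, plus a latent position on
  the unit sphere; links concentrate on class-compatible, high-affinity
  pairs, and attribute payloads embed class-specific motifs (protein
  subsequences, molecule character n-grams, text keywords) with fidelity
  ``s``.  At ``s = 1`` an attribute reveals its entity's class; at ``s = 0``
  motifs are drawn from a random class and carry no class information.

The latent ground truth is returned alongside the graph so that
parameter-recovery and encoder-benefit experiments can condition on it.
Generation is fully deterministic given the config (including its seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .kg_data import (
    AttributedKG,
    AttributeRecord,
    BenchmarkPair,
    Triple,
    TYPE_MODALITY,
)

PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
MOLECULE_LETTERS = "BCFHINOPSclnos()=#123456"
# backgrounds, class motifs and positional anchors draw on pairwise disjoint
# sub-alphabets, so that under mean pooling the class-motif letter counts and
# the anchor letter counts are separately recoverable, free of background
# noise (the sequences are synthetic; chemical/biological plausibility is a
# non-goal)
PROTEIN_BG = "ACDEFGHIKLM"
PROTEIN_MOTIF_LETTERS = "NPQRST"
PROTEIN_ANCHOR_LETTERS = ["V", "W", "Y"]
MOLECULE_BG = "CHNOPSclnos()="
MOLECULE_MOTIF_LETTERS = "#123456"
MOLECULE_ANCHOR_LETTERS = ["B", "F", "I"]

#: relation name -> (head type, tail type)
DEFAULT_SCHEMA: dict[str, tuple[str, str]] = {
    "protein_protein_interaction": ("protein", "protein"),
    "drug_protein_interaction": ("drug", "protein"),
    "protein_pathway_association": ("protein", "pathway"),
    "protein_disease_association": ("protein", "disease"),
    "drug_disease_treatment": ("drug", "disease"),
    "disorder_disease_association": ("disorder", "disease"),
}

DEFAULT_RELATION_WEIGHTS: dict[str, float] = {
    "protein_protein_interaction": 0.30,
    "drug_protein_interaction": 0.25,
    "protein_pathway_association": 0.10,
    "protein_disease_association": 0.15,
    "drug_disease_treatment": 0.10,
    "disorder_disease_association": 0.10,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic attributed KG.

    Defaults give ~150 entities and ~2,000 triples with 68% attribute
    coverage over the eligible types, a right-skewed degree distribution
    (skew exponent ``degree_skew``), and fully informative attributes
    (``signal = 1``).
    """

    n_protein: int = 80
    n_drug: int = 30
    n_disease: int = 20
    n_pathway: int = 12
    n_disorder: int = 8
    n_triples: int = 2000
    coverage: float = 0.68          # fraction of eligible entities with attributes
    degree_skew: float = 0.8        # entity weight ~ rank^(-degree_skew)
    n_classes: int = 24
    signal: float = 1.0             # motif fidelity s in [0, 1]
    affinity: float = 12.0          # latent-position sharpness beta
    latent_dim: int = 3
    class_noise: float = 0.15       # within-class latent spread
    edge_noise: float = 0.0         # fraction of edges ignoring latent structure
    rare_fraction: float = 0.25     # bottom fraction of entities ("understudied")
    rare_weight: float = 0.02       # extra down-weighting of rare entities
    rare_edge_noise: float = 0.5    # rare-entity edges that are screen-like
                                    # (popularity-driven, affinity-free)
    anchor_scale: float = 4.0       # anchor-letter repeats encode latent position
    protein_length: tuple[int, int] = (30, 60)
    molecule_length: tuple[int, int] = (20, 40)
    text_length: tuple[int, int] = (8, 16)
    protein_motif_len: int = 12
    molecule_motif_len: int = 8
    text_keywords: int = 4
    background_vocab: int = 120
    schema: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEMA)
    )
    relation_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATION_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        counts = (self.n_protein, self.n_drug, self.n_disease,
                  self.n_pathway, self.n_disorder)
        if any(c <= 0 for c in counts):
            raise ValueError("entity counts must be positive")
        types = {"protein", "drug", "disease", "pathway", "disorder"}
        for rel, (ht, tt) in self.schema.items():
            if ht not in types or tt not in types:
                raise ValueError(f"schema relation {rel!r} references unknown type")

    @property
    def type_counts(self) -> dict[str, int]:
        return {
            "protein": self.n_protein, "drug": self.n_drug,
            "disease": self.n_disease, "pathway": self.n_pathway,
            "disorder": self.n_disorder,
        }


@dataclass
class LatentGroundTruth:
    """What the generator planted: classes, positions, compatibilities, motifs."""

    classes: dict[str, int]
    positions: dict[str, list[float]]
    compatibility: dict[str, list[list[float]]]  # relation -> C x C table
    motifs: dict[str, list[str]]                 # modality -> per-class motif
    anchors: dict[str, list[str]]                # modality -> positional anchors
    covered: list[str]
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    def pair_affinity(self, gt_relation: str, x: str, y: str,
                      beta: float) -> float:
        cx, cy = self.classes[x], self.classes[y]
        zx = np.array(self.positions[x])
        zy = np.array(self.positions[y])
        compat = self.compatibility[gt_relation][cx][cy]
        return float(compat * np.exp(beta * zx @ zy))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _entity_ids(cfg: SynthConfig) -> dict[str, list[str]]:
    prefix = {"protein": "prot", "drug": "drug", "disease": "dis",
              "pathway": "path", "disorder": "gdis"}
    return {
        t: [f"{prefix[t]}{i:03d}" for i in range(n)]
        for t, n in cfg.type_counts.items()
    }


def _random_motifs(
    cfg: SynthConfig, rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Per-class motifs plus positional anchor motifs shared by all classes."""
    motifs: dict[str, list[str]] = {"protein_sequence": [], "molecule_string": [],
                                    "text": []}
    for _ in range(cfg.n_classes):
        motifs["protein_sequence"].append(
            "".join(rng.choice(list(PROTEIN_MOTIF_LETTERS), cfg.protein_motif_len))
        )
        motifs["molecule_string"].append(
            "".join(rng.choice(list(MOLECULE_MOTIF_LETTERS), cfg.molecule_motif_len))
        )
    for c in range(cfg.n_classes):
        words = [f"kw{c}x{j}" for j in range(cfg.text_keywords)]
        motifs["text"].append(" ".join(words))
    if cfg.latent_dim > len(PROTEIN_ANCHOR_LETTERS):
        raise ValueError("latent_dim exceeds the available anchor letters")
    anchors = {
        "protein_sequence": PROTEIN_ANCHOR_LETTERS[: cfg.latent_dim],
        "molecule_string": MOLECULE_ANCHOR_LETTERS[: cfg.latent_dim],
        "text": [f"anc{j}" for j in range(cfg.latent_dim)],
    }
    return motifs, anchors


def _anchor_counts(z: np.ndarray, scale: float) -> list[int]:
    """Repeat counts of each anchor motif: a linear encoding of the latent
    position, recoverable by mean pooling over tokens."""
    return [int(round(scale * (float(zj) + 1.0))) for zj in z]


def _make_payload(
    modality: str,
    motif: str,
    anchors: Sequence[str],
    counts: Sequence[int],
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> str:
    """Random background with the class motif and repeated positional anchor
    motifs spliced in at random offsets."""
    if modality == "text":
        lo, hi = cfg.text_length
        background = [f"w{int(i):03d}" for i in
                      rng.integers(0, cfg.background_vocab, rng.integers(lo, hi + 1))]
        pieces = [motif.split()]
    else:
        letters = PROTEIN_BG if modality == "protein_sequence" else MOLECULE_BG
        lo, hi = (cfg.protein_length if modality == "protein_sequence"
                  else cfg.molecule_length)
        background = list(rng.choice(list(letters), rng.integers(lo, hi + 1)))
        pieces = [list(motif)]
    for anchor, count in zip(anchors, counts):
        piece = ([anchor] if modality == "text" else list(anchor)) * count
        if piece:
            pieces.append(piece)
    # each piece is spliced in contiguously at a random background gap, so the
    # class motif always survives as an intact substring
    gaps = [int(rng.integers(0, len(background) + 1)) for _ in pieces]
    tokens: list[str] = []
    for i in range(len(background) + 1):
        for piece, gap in zip(pieces, gaps):
            if gap == i:
                tokens.extend(piece)
        if i < len(background):
            tokens.append(background[i])
    return ("".join(tokens) if modality != "text" else " ".join(tokens))


def generate_attributed_kg(
    cfg: SynthConfig,
) -> tuple[AttributedKG, LatentGroundTruth]:
    """Sample a typed, attributed KG plus the latent ground truth behind it."""
    rng = np.random.default_rng(cfg.seed)
    ids = _entity_ids(cfg)
    entity_types = {v: t for t in sorted(ids) for v in ids[t]}

    # latent classes and positions on the unit sphere
    centers = rng.standard_normal((cfg.n_classes, cfg.latent_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    classes: dict[str, int] = {}
    positions: dict[str, np.ndarray] = {}
    for t in sorted(ids):
        for v in ids[t]:
            c = int(rng.integers(cfg.n_classes))
            z = centers[c] + cfg.class_noise * rng.standard_normal(cfg.latent_dim)
            z /= np.linalg.norm(z)
            classes[v] = c
            positions[v] = z

    # per-relation class compatibility: each class strongly compatible with a
    # few classes, weakly with the rest (so the schema always admits triples)
    compatibility: dict[str, np.ndarray] = {}
    for rel in sorted(cfg.schema):
        table = np.full((cfg.n_classes, cfg.n_classes), 0.05)
        for c in range(cfg.n_classes):
            k = 1 + int(rng.integers(2))
            partners = rng.choice(cfg.n_classes, size=k, replace=False)
            table[c, partners] = 1.0
        compatibility[rel] = table

    # heavy-tailed popularity weights per type: a rank^(-a) law, with the
    # bottom `rare_fraction` of ranks further down-weighted so the graph has
    # genuinely understudied, near-isolated entities (mean degree >> median)
    popularity: dict[str, np.ndarray] = {}
    rare: set[str] = set()
    for t in sorted(ids):
        n = len(ids[t])
        ranks = rng.permutation(n) + 1
        w = ranks.astype(float) ** (-cfg.degree_skew)
        is_rare = ranks > (1.0 - cfg.rare_fraction) * n
        w[is_rare] *= cfg.rare_weight
        rare.update(v for v, r in zip(ids[t], is_rare) if r)
        popularity[t] = w / w.sum()

    rels = sorted(cfg.schema)
    relw = np.array([cfg.relation_weights.get(r, 1.0) for r in rels], float)
    if relw.sum() <= 0:
        raise ValueError("relation weights must have positive mass")
    relw = relw / relw.sum()

    cls_arr = {t: np.array([classes[v] for v in ids[t]]) for t in sorted(ids)}
    pos_arr = {t: np.stack([positions[v] for v in ids[t]]) for t in sorted(ids)}

    triples: list[Triple] = []
    seen: set[Triple] = set()
    attempts = 0
    max_attempts = 200 * cfg.n_triples
    while len(triples) < cfg.n_triples:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "schema admits too few legal triples for the requested count"
            )
        rel = rels[rng.choice(len(rels), p=relw)]
        ht, tt = cfg.schema[rel]
        head = ids[ht][rng.choice(len(ids[ht]), p=popularity[ht])]
        zh = positions[head]
        # understudied entities' recorded links come disproportionately from
        # popularity-driven screens, so a fraction of their edges ignores the
        # latent structure; a global edge-noise floor can be added on top
        p_noise = cfg.rare_edge_noise if head in rare else cfg.edge_noise
        if rng.random() < p_noise:
            # structure-free edge: legal for the schema but ignoring classes
            # and latent affinity (curation noise)
            w = popularity[tt].copy()
        else:
            w = (
                popularity[tt]
                * compatibility[rel][classes[head], cls_arr[tt]]
                * np.exp(cfg.affinity * (pos_arr[tt] @ zh))
            )
        if ht == tt:  # no self-loops
            w = w.copy()
            w[ids[tt].index(head)] = 0.0
        total = w.sum()
        if total <= 0:
            continue
        tail = ids[tt][rng.choice(len(ids[tt]), p=w / total)]
        trp = Triple(head, rel, tail)
        if trp in seen:
            continue
        seen.add(trp)
        triples.append(trp)

    # attributes: per-type coverage, motif fidelity s; with probability s the
    # payload carries the entity's class motif and anchor counts encoding its
    # own latent position, otherwise those of a random class/position
    motifs, anchors = _random_motifs(cfg, rng)
    attributes: dict[str, AttributeRecord] = {}
    covered: list[str] = []
    for t in ("protein", "drug", "disease"):
        modality = TYPE_MODALITY[t]
        ents = ids[t]
        n_cov = int(round(cfg.coverage * len(ents)))
        chosen = sorted(rng.permutation(len(ents))[:n_cov].tolist())
        for i in chosen:
            v = ents[i]
            if rng.random() < cfg.signal:
                motif = motifs[modality][classes[v]]
                z_enc = positions[v]
            else:
                motif = motifs[modality][int(rng.integers(cfg.n_classes))]
                z_enc = rng.standard_normal(cfg.latent_dim)
                z_enc /= np.linalg.norm(z_enc)
            counts = _anchor_counts(z_enc, cfg.anchor_scale)
            attributes[v] = AttributeRecord(modality, _make_payload(
                modality, motif, anchors[modality], counts, cfg, rng))
            covered.append(v)

    kg = AttributedKG(entity_types, set(rels), triples, attributes)
    gt = LatentGroundTruth(
        classes=classes,
        positions={v: z.tolist() for v, z in positions.items()},
        compatibility={r: t.tolist() for r, t in compatibility.items()},
        motifs=motifs,
        anchors=anchors,
        covered=covered,
        config=_config_dict(cfg),
    )
    return kg, gt


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["schema"] = {k: list(v) for k, v in d["schema"].items()}
    return d


def generate_benchmark_pairs(
    kg: AttributedKG,
    gt: LatentGroundTruth,
    n_pairs: int,
    rng: np.random.Generator,
) -> list[BenchmarkPair]:
    """Sample positive-by-construction drug-protein pairs.

    Pairs are drawn (without replacement) from class-compatible drug-protein
    combinations with probability proportional to their latent affinity, so
    the sample includes high-affinity pairs that also occur as KG edges —
    exactly the leakage that benchmark decoupling must remove.
    """
    rel = "drug_protein_interaction"
    if rel not in gt.compatibility:
        raise ValueError("ground truth lacks a drug-protein relation")
    drugs = sorted(v for v, t in kg.entity_types.items() if t == "drug")
    prots = sorted(v for v, t in kg.entity_types.items() if t == "protein")
    compat = np.array(gt.compatibility[rel])

    cand, weights = [], []
    for d in drugs:
        for p in prots:
            if compat[gt.classes[d], gt.classes[p]] >= 1.0:
                cand.append((d, p))
                weights.append(gt.pair_affinity(rel, d, p,
                                                gt.config["affinity"]))
    if len(cand) < n_pairs:
        raise ValueError(
            f"insufficient class-compatible drug-protein pairs: "
            f"need {n_pairs}, have {len(cand)}"
        )
    w = np.asarray(weights)
    chosen = rng.choice(len(cand), size=n_pairs, replace=False, p=w / w.sum())
    return [BenchmarkPair(*cand[i], "synthetic_dpi") for i in sorted(chosen.tolist())]


# ---------------------------------------------------------------------------
# File emission (formats consumed by kg_data.load_kg)
# ---------------------------------------------------------------------------

def write_dataset(
    kg: AttributedKG,
    gt: LatentGroundTruth,
    out_dir: str | Path,
    pairs: Sequence[BenchmarkPair] | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "triples.tsv", "w", encoding="utf-8") as fh:
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")
    with open(out / "types.tsv", "w", encoding="utf-8") as fh:
        for v in sorted(kg.entity_types):
            fh.write(f"{v}\t{kg.entity_types[v]}\n")
    with open(out / "proteins.fasta", "w", encoding="utf-8") as fh:
        for v in sorted(kg.attributes):
            rec = kg.attributes[v]
            if rec.modality == "protein_sequence":
                fh.write(f">{v}\n{rec.payload}\n")
    for fname, modality in (("molecules.tsv", "molecule_string"),
                            ("texts.tsv", "text")):
        with open(out / fname, "w", encoding="utf-8") as fh:
            for v in sorted(kg.attributes):
                rec = kg.attributes[v]
                if rec.modality == modality:
                    fh.write(f"{v}\t{rec.payload}\n")
    if pairs is not None:
        with open(out / "pairs.tsv", "w", encoding="utf-8") as fh:
            for p in pairs:
                fh.write(f"{p.x}\t{p.y}\n")
    gt.to_json(out / "ground_truth.json")
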