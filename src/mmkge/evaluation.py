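"""Rank-based link-prediction evaluation and degree-stratified analysis.

For every test triple (h, r, t) two ranking queries are asked: predict the
tail given (h, r, ?) and the head given (?, r, t), scoring *all* entities as
candidates.  From the collected ranks (p_1 ... p_m; m = number of ranks, two
per triple):

    MRR  = (1/m) sum_i 1 / p_i
    H@k  = (1/m) sum_i 1[p_i <= k]

In the *filtered* setting (default), candidates forming other known-true
triples are removed before ranking — the true entity itself is never
filtered.  Ties use the "realistic" policy: the true entity receives the mean
of its optimistic and pessimistic positions, so constant scorers are not
inflated.

Because micro-averaged metrics are dominated by high-degree entities, a
*macro* MRR is also provided: ranks are grouped by the training-graph degree
of the predicted entity, and each degree value contributes equally.  The
cumulative-cutoff analysis compares an encoder model against a lookup
baseline over nodes of degree <= d for growing d, and reports the largest
degree up to which the encoder model is ahead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .encoders import EncoderRegistry
from .kg_data import AttributedKG, Triple, degree_map
from .scoring import Scorer


@dataclass(frozen=True)
class RankRecord:
    """One ranking query: the rank of the true entity and its metadata."""

    rank: float
    side: str  # "head" | "tail" (which position was predicted)
    predicted_entity: str
    n_candidates: int
    degree: int | None = None
    entity_type: str | None = None


@dataclass
class EvalReport:
    ranks: list[RankRecord]
    mode: str = "filtered"
    per_degree: dict[int, float] = field(default_factory=dict)

    @property
    def mrr(self) -> float:
        return float(np.mean([1.0 / r.rank for r in self.ranks]))

    def hits_at(self, k: int) -> float:
        return float(np.mean([r.rank <= k for r in self.ranks]))

    @property
    def hits(self) -> dict[int, float]:
        return {k: self.hits_at(k) for k in (1, 3, 10)}

    def to_dict(self) -> dict:
        return {
            "mrr": self.mrr,
            "hits": {str(k): v for k, v in self.hits.items()},
            "n_ranks": len(self.ranks),
            "mode": self.mode,
            "per_degree": [
                {"degree": d, "n": sum(1 for r in self.ranks if r.degree == d), "mrr": v}
                for d, v in sorted(self.per_degree.items())
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_of_true_entity(
    scores: np.ndarray,
    true_index: int,
    filter_indices: Sequence[int] | None = None,
) -> tuple[float, int]:
    """Realistic-tie rank of the true candidate after filtering competitors.

    Returns (rank, number of candidates after filtering).  ``filter_indices``
    are candidate positions known to form true triples; the true entity is
    never filtered even if listed.
    """
    scores = np.asarray(scores, float)
    keep = np.ones(scores.shape[0], dtype=bool)
    if filter_indices is not None:
        keep[np.asarray(list(filter_indices), dtype=int)] = False
    keep[true_index] = True
    s_true = scores[true_index]
    kept = scores[keep]
    greater = int(np.sum(kept > s_true))
    ties = int(np.sum(kept == s_true)) - 1  # exclude the true entity itself
    return 1.0 + greater + 0.5 * ties, int(kept.size)


def _known_triple_index(
    triples: Sequence[Triple], ent_index: Mapping[str, int]
) -> tuple[dict, dict]:
    tails_of: dict[tuple[str, str], list[int]] = {}
    heads_of: dict[tuple[str, str], list[int]] = {}
    for t in triples:
        tails_of.setdefault((t.head, t.relation), []).append(ent_index[t.tail])
        heads_of.setdefault((t.relation, t.tail), []).append(ent_index[t.head])
    return tails_of, heads_of


def evaluate_link_prediction(
    registry: EncoderRegistry,
    scorer: Scorer,
    test_triples: Sequence[Triple],
    kg: AttributedKG,
    mode: str = "filtered",
    filter_triples: Sequence[Triple] | None = None,
    degrees: Mapping[str, int] | None = None,
) -> EvalReport:
    """Rank head and tail predictions for every test triple.

    ``filter_triples`` is the set of known-true triples excluded from the
    candidate lists in filtered mode (typically train + valid + test);
    ``degrees`` are training-graph degrees used to annotate each rank with
    the predicted entity's degree (enables the macro analysis).
    """
    if not test_triples:
        raise ValueError("empty test set")
    if mode not in ("raw", "filtered"):
        raise ValueError(f"unknown mode {mode!r}")

    entity_order = sorted(kg.entities)
    ent_index = {v: i for i, v in enumerate(entity_order)}
    E = registry.all_entity_embeddings(kg, entity_order)
    tails_of, heads_of = (
        _known_triple_index(filter_triples, ent_index)
        if (mode == "filtered" and filter_triples is not None)
        else ({}, {})
    )

    records: list[RankRecord] = []
    for trp in test_triples:
        r_emb = registry.embed_relation(trp.relation)
        h_emb, t_emb = E[ent_index[trp.head]], E[ent_index[trp.tail]]

        # tail prediction: the predicted entity is the tail
        scores = scorer.score(h_emb, r_emb, E)
        filt = tails_of.get((trp.head, trp.relation))
        rank, n_cand = rank_of_true_entity(scores, ent_index[trp.tail], filt)
        records.append(RankRecord(
            rank, "tail", trp.tail, n_cand,
            degree=None if degrees is None else degrees.get(trp.tail, 0),
            entity_type=kg.entity_types.get(trp.tail),
        ))

        # head prediction
        scores = scorer.score(E, r_emb, t_emb)
        filt = heads_of.get((trp.relation, trp.tail))
        rank, n_cand = rank_of_true_entity(scores, ent_index[trp.head], filt)
        records.append(RankRecord(
            rank, "head", trp.head, n_cand,
            degree=None if degrees is None else degrees.get(trp.head, 0),
            entity_type=kg.entity_types.get(trp.head),
        ))

    report = EvalReport(records, mode=mode)
    if degrees is not None:
        report.per_degree = macro_mrr_by_degree(records)
    return report


# ---------------------------------------------------------------------------
# Degree-stratified analysis
# ---------------------------------------------------------------------------

def macro_mrr_by_degree(ranks: Sequence[RankRecord]) -> dict[int, float]:
    """Micro MRR within each exact degree value of the predicted entity."""
    groups: dict[int, list[float]] = {}
    for r in ranks:
        if r.degree is None:
            raise ValueError("rank record missing its degree annotation")
        groups.setdefault(r.degree, []).append(1.0 / r.rank)
    return {d: float(np.mean(v)) for d, v in groups.items()}


def macro_mrr(per_degree: Mapping[int, float]) -> float:
    """Unweighted mean of per-degree MRRs: each degree value weighs equally."""
    if not per_degree:
        raise ValueError("empty per-degree table")
    return float(np.mean(list(per_degree.values())))


@dataclass
class CumulativeDelta:
    degrees: list[int]
    curve: list[float]  # cumulative macro-MRR difference (baseline - encoder)
    cutoff: int | None  # largest degree with nonpositive difference

    def to_dict(self) -> dict:
        return {"degrees": self.degrees, "curve": self.curve, "cutoff": self.cutoff}


def cumulative_delta_cutoff(
    per_degree_encoder: Mapping[int, float],
    per_degree_baseline: Mapping[int, float],
) -> CumulativeDelta:
    """Largest degree up to which the encoder model beats the lookup baseline.

    For each degree d (ascending over the shared support) the difference in
    cumulative macro MRR over nodes of degree <= d is computed, oriented as
    baseline minus encoder so that *negative values mean the encoder model
    outperforms the baseline*.  The cutoff is the largest d at which the
    cumulative difference is still <= 0, or ``None`` if the encoder model is
    already behind at the smallest degree.
    """
    support = sorted(set(per_degree_encoder) & set(per_degree_baseline))
    if not support:
        raise ValueError("empty shared degree support")
    deltas = [per_degree_baseline[d] - per_degree_encoder[d] for d in support]
    curve = list(np.cumsum(deltas) / np.arange(1, len(deltas) + 1))
    nonpos = [d for d, c in zip(support, curve) if c <= 0]
    return CumulativeDelta(support, [float(c) for c in curve],
                           max(nonpos) if nonpos else None)


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def random_ranking_expectation(candidate_counts: Sequence[int]) -> float:
    """Expected MRR of a uniformly random ranker.

    For a query with k candidates the rank of the true entity is uniform on
    1..k, so E[1/rank] = H_k / k with H_k the k-th harmonic number; the
    expectation is averaged over queries.
    """
    vals = []
    for k in candidate_counts:
        harmonics = np.sum(1.0 / np.arange(1, k + 1))
        vals.append(harmonics / k)
    return float(np.mean(vals))


def expected_random_mrr(report: EvalReport) -> float:
    """Analytic random-ranking MRR for the candidate sets of a report."""
    return random_ranking_expectation([r.n_candidates for r in report.ranks])


def reciprocal_rank_ttest(ranks_a: Sequence[float], ranks_b: Sequence[float]):
    """Welch's t-test on paired reciprocal ranks of two models (utility only)."""
    a = 1.0 / np.asarray(ranks_a, float)
    b = 1.0 / np.asarray(ranks_b, float)
    return stats.ttest_ind(a, b, equal_var=False)
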