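import numpy as np
import pytest

from mmkge.encoders import EncoderRegistry
from mmkge.evaluation import (
    EvalReport,
    RankRecord,
    cumulative_delta_cutoff,
    evaluate_link_prediction,
    expected_random_mrr,
    macro_mrr,
    macro_mrr_by_degree,
    random_ranking_expectation,
    rank_of_true_entity,
)
from mmkge.kg_data import AttributedKG, Triple
from mmkge.scoring import make_scorer


class TestRankOfTrueEntity:
    def test_strict_maximum_ranks_first(self):
        rank, n = rank_of_true_entity(np.array([0.9, 0.5, 0.1]), 0)
        assert rank == 1.0 and n == 3

    def test_realistic_tie_gives_half_integer(self):
        scores = np.array([0.8, 0.8, 0.1, 0.2])
        rank, _ = rank_of_true_entity(scores, 0)
        assert rank == 1.5

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            scores = np.round(rng.standard_normal(30), 1)  # rounding makes ties
            true = int(rng.integers(30))
            filt = [int(i) for i in rng.choice(30, size=5, replace=False)
                    if i != true]
            rank, _ = rank_of_true_entity(scores, true, filt)
            kept = [i for i in range(30) if i == true or i not in filt]
            s_true = scores[true]
            greater = sum(scores[i] > s_true for i in kept)
            equal = sum(scores[i] == s_true for i in kept) - 1
            assert rank == 1 + greater + equal / 2

    def test_true_entity_never_filtered(self):
        scores = np.array([0.9, 0.5, 0.1])
        rank, n = rank_of_true_entity(scores, 0, [0, 1])
        assert rank == 1.0 and n == 2

    def test_filtered_rank_never_exceeds_raw(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            scores = rng.standard_normal(20)
            true = int(rng.integers(20))
            filt = [int(i) for i in rng.choice(20, 6, replace=False) if i != true]
            raw, _ = rank_of_true_entity(scores, true)
            filtered, _ = rank_of_true_entity(scores, true, filt)
            assert filtered <= raw


def _report(ranks):
    return EvalReport([RankRecord(r, "tail", "e", 10) for r in ranks])


class TestMetrics:
    def test_mrr_direct_formula(self):
        assert _report([1, 2, 4]).mrr == pytest.approx(7 / 12)

    def test_hits_at_k_direct(self):
        rep = _report([1, 5, 2, 10])
        assert rep.hits_at(3) == pytest.approx(0.5)
        assert rep.hits_at(1) == pytest.approx(0.25)
        assert rep.hits_at(10) == pytest.approx(1.0)

    def test_hits_monotone_and_bounded(self):
        rep = _report([1, 1.5, 3, 7, 20])
        assert 0 < rep.mrr <= 1
        assert rep.hits_at(1) <= rep.hits_at(3) <= rep.hits_at(10)


class TestEvaluateLinkPrediction:
    @pytest.fixture
    def lookup_model(self):
        triples = [Triple("a", "r", "b"), Triple("b", "r", "c"),
                   Triple("c", "r", "d"), Triple("d", "r", "e"),
                   Triple("e", "r", "a")]
        kg = AttributedKG({v: "other" for v in "abcde"}, {"r"}, triples)
        scorer = make_scorer("transe", 6)
        reg = EncoderRegistry(kg, scorer, seed=3)
        return kg, scorer, reg, triples

    def test_matches_exhaustive_scoring_oracle(self, lookup_model):
        kg, scorer, reg, triples = lookup_model
        test = triples[:3]
        report = evaluate_link_prediction(reg, scorer, test, kg, mode="raw")
        ents = sorted(kg.entities)
        recips = []
        for trp in test:
            r_emb = reg.embed_relation(trp.relation)
            for side in ("tail", "head"):
                scores = []
                for cand in ents:
                    if side == "tail":
                        s = scorer.score(reg.embed_entity(trp.head, kg), r_emb,
                                         reg.embed_entity(cand, kg))
                    else:
                        s = scorer.score(reg.embed_entity(cand, kg), r_emb,
                                         reg.embed_entity(trp.tail, kg))
                    scores.append(float(s))
                true = ents.index(trp.tail if side == "tail" else trp.head)
                s_true = scores[true]
                rank = 1 + sum(s > s_true for s in scores) \
                    + (sum(s == s_true for s in scores) - 1) / 2
                recips.append(1 / rank)
        assert report.mrr == pytest.approx(np.mean(recips))

    def test_two_ranks_per_triple(self, lookup_model):
        kg, scorer, reg, triples = lookup_model
        report = evaluate_link_prediction(reg, scorer, triples, kg, mode="raw")
        assert len(report.ranks) == 2 * len(triples)

    def test_perfect_model_reaches_mrr_one(self):
        # a translational model whose embeddings realize the graph exactly
        triples = [Triple("a", "r", "b"), Triple("b", "r", "c")]
        kg = AttributedKG({v: "other" for v in "abc"}, {"r"}, triples)
        scorer = make_scorer("transe", 2)
        reg = EncoderRegistry(kg, scorer, seed=0)
        coords = {"a": [0.0, 0.0], "b": [1.0, 0.0], "c": [2.0, 0.0]}
        for v, xy in coords.items():
            reg.lookup.W_e[reg.lookup.entity_index[v]] = xy
        reg.lookup.W_r[0] = [1.0, 0.0]
        report = evaluate_link_prediction(reg, scorer, triples, kg,
                                          mode="filtered", filter_triples=triples)
        assert report.mrr == 1.0
        assert report.hits_at(1) == 1.0

    def test_filtered_mode_removes_known_competitors(self):
        # b and c are both tails of (a, r, .); filtering the train edge (a,r,b)
        # must improve the rank of c for the test query
        triples = [Triple("a", "r", "b"), Triple("a", "r", "c")]
        kg = AttributedKG({v: "other" for v in "abc"}, {"r"}, triples)
        scorer = make_scorer("transe", 2)
        reg = EncoderRegistry(kg, scorer, seed=0)
        reg.lookup.W_e[reg.lookup.entity_index["a"]] = [0, 0]
        reg.lookup.W_e[reg.lookup.entity_index["b"]] = [1, 0]
        reg.lookup.W_e[reg.lookup.entity_index["c"]] = [1.1, 0]
        reg.lookup.W_r[0] = [1, 0]
        test = [Triple("a", "r", "c")]
        raw = evaluate_link_prediction(reg, scorer, test, kg, mode="raw")
        filt = evaluate_link_prediction(reg, scorer, test, kg, mode="filtered",
                                        filter_triples=triples)
        tail_raw = [r for r in raw.ranks if r.side == "tail"][0]
        tail_filt = [r for r in filt.ranks if r.side == "tail"][0]
        assert tail_raw.rank == 2.0
        assert tail_filt.rank == 1.0

    def test_empty_test_set_rejected(self, lookup_model):
        kg, scorer, reg, _ = lookup_model
        with pytest.raises(ValueError, match="empty test set"):
            evaluate_link_prediction(reg, scorer, [], kg)


class TestMacroMRR:
    def test_weighting_contrast(self):
        ranks = [RankRecord(1, "tail", "x", 5, degree=1),
                 RankRecord(10, "tail", "y", 5, degree=100),
                 RankRecord(10, "head", "y", 5, degree=100)]
        per_degree = macro_mrr_by_degree(ranks)
        assert per_degree == {1: 1.0, 100: pytest.approx(0.1)}
        assert macro_mrr(per_degree) == pytest.approx(0.55)
        micro = np.mean([1 / r.rank for r in ranks])
        assert micro == pytest.approx(0.4)

    def test_single_degree_macro_equals_micro(self):
        ranks = [RankRecord(r, "tail", "x", 9, degree=7) for r in (1, 2, 4)]
        assert macro_mrr(macro_mrr_by_degree(ranks)) == pytest.approx(7 / 12)

    def test_missing_degree_annotation_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            macro_mrr_by_degree([RankRecord(1, "tail", "x", 5)])

    def test_grouping_matches_tally_oracle(self):
        rng = np.random.default_rng(2)
        ranks = [RankRecord(float(rng.integers(1, 20)), "tail", "x", 30,
                            degree=int(rng.integers(1, 5))) for _ in range(200)]
        per_degree = macro_mrr_by_degree(ranks)
        for d in set(r.degree for r in ranks):
            vals = [1 / r.rank for r in ranks if r.degree == d]
            assert per_degree[d] == pytest.approx(np.mean(vals))

    def test_micro_is_count_weighted_mean_of_per_degree(self):
        rng = np.random.default_rng(3)
        ranks = [RankRecord(float(rng.integers(1, 20)), "tail", "x", 30,
                            degree=int(rng.integers(1, 6))) for _ in range(300)]
        per_degree = macro_mrr_by_degree(ranks)
        counts = {d: sum(r.degree == d for r in ranks) for d in per_degree}
        weighted = sum(per_degree[d] * counts[d] for d in per_degree) / len(ranks)
        micro = np.mean([1 / r.rank for r in ranks])
        assert micro == pytest.approx(weighted)


class TestCumulativeDelta:
    def test_direct_arithmetic_example(self):
        # per-degree differences (baseline - encoder) of
        # [-0.1, -0.05, -0.02, +0.01, +0.5] at degrees 1..5 give cumulative
        # means crossing zero after degree 4
        base = {d: 0.5 for d in range(1, 6)}
        deltas = [-0.1, -0.05, -0.02, 0.01, 0.5]
        enc = {d: base[d] - deltas[d - 1] for d in base}
        result = cumulative_delta_cutoff(enc, base)
        np.testing.assert_allclose(
            result.curve, [-0.1, -0.075, -0.056667, -0.04, 0.068], atol=1e-5)
        assert result.cutoff == 4

    def test_encoder_ahead_everywhere_gives_max_degree(self):
        enc = {d: 0.6 for d in (1, 3, 9)}
        base = {d: 0.4 for d in (1, 3, 9)}
        assert cumulative_delta_cutoff(enc, base).cutoff == 9

    def test_encoder_behind_at_smallest_degree_gives_none(self):
        enc = {1: 0.1, 2: 0.9}
        base = {1: 0.5, 2: 0.2}
        res = cumulative_delta_cutoff(enc, base)
        assert res.curve[0] > 0
        assert res.cutoff in (None, 2)  # depends on the cumulative mean
        assert cumulative_delta_cutoff({1: 0.1}, {1: 0.5}).cutoff is None

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            degrees = sorted(rng.choice(50, size=10, replace=False) + 1)
            enc = {int(d): float(rng.random()) for d in degrees}
            base = {int(d): float(rng.random()) for d in degrees}
            res = cumulative_delta_cutoff(enc, base)
            best = None
            for i, d in enumerate(degrees):
                cum = np.mean([base[dd] - enc[dd] for dd in degrees[: i + 1]])
                if cum <= 0:
                    best = int(d)
            assert res.cutoff == best

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            cumulative_delta_cutoff({1: 0.5}, {2: 0.5})


class TestRandomExpectation:
    def test_harmonic_formula(self):
        # k candidates: E[1/rank] = H_k / k
        assert random_ranking_expectation([1]) == 1.0
        assert random_ranking_expectation([4]) == pytest.approx((1 + 1/2 + 1/3 + 1/4) / 4)

    def test_matches_simulation(self):
        rng = np.random.default_rng(5)
        k = 12
        sim = np.mean([1 / (rng.integers(k) + 1) for _ in range(200_000)])
        assert random_ranking_expectation([k]) == pytest.approx(sim, rel=0.01)

    def test_report_helper_uses_candidate_counts(self):
        rep = EvalReport([RankRecord(3, "tail", "x", 5),
                          RankRecord(2, "head", "y", 10)])
        expected = (random_ranking_expectation([5])
                    + random_ranking_expectation([10])) / 2
        assert expected_random_mrr(rep) == pytest.approx(expected)
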