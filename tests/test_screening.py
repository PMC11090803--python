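"""Virtual-screening metrics against brute-force and RDKit oracles."""

import itertools

import numpy as np
import pytest

from mapfp import (
    FPConfig,
    MinHashedAtomPairFingerprint,
    MinHashFP,
    RankedScreen,
    aggregate_ranks,
    auc,
    bedroc,
    enrichment_factor,
    rank_by_similarity,
    rie,
    run_benchmark_set,
)
from mapfp.errors import TooFewActivesError
from mapfp.screening import MetricTable, compute_metrics


def make_screen(actives_mask, scores=None):
    n = len(actives_mask)
    scores = scores if scores is not None else [float(n - i) for i in range(n)]
    return RankedScreen(
        ids=tuple(f"m{i}" for i in range(n)),
        scores=tuple(scores),
        actives=tuple(actives_mask),
    )


def brute_force_auc(screen):
    """Exhaustive active/decoy pair counting with half-credit ties."""
    wins = total = 0
    for (sa, aa), (sd, ad) in itertools.product(
        zip(screen.scores, screen.actives), repeat=2
    ):
        if aa and not ad:
            total += 1
            wins += 1 if sa > sd else (0.5 if sa == sd else 0)
    return wins / total


class TestAUC:
    def test_all_actives_on_top(self):
        assert auc(make_screen([True, True, False, False])) == 1.0

    def test_all_actives_at_bottom(self):
        assert auc(make_screen([False, False, True, True])) == 0.0

    def test_worked_example(self):
        # actives at ranks 1 and 4 of 5: pairs won = (3 + 1) of 6
        assert auc(make_screen([True, False, False, True, False])) == \
            pytest.approx(4 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 20))
        scores = rng.integers(0, 4, n).astype(float)  # heavy ties
        actives = rng.random(n) < 0.4
        if not 1 <= actives.sum() < n:
            return
        order = np.argsort(-scores)
        screen = make_screen(actives[order].tolist(), scores[order].tolist())
        assert auc(screen) == pytest.approx(brute_force_auc(screen))

    def test_matches_rdkit_oracle(self):
        from rdkit.ML.Scoring import Scoring

        rng = np.random.default_rng(8)
        scores = -np.sort(-rng.random(30))
        actives = rng.random(30) < 0.3
        if not 1 <= actives.sum() < 30:
            actives[0], actives[-1] = True, False
        screen = make_screen(actives.tolist(), scores.tolist())
        oracle = Scoring.CalcAUC([[s, a] for s, a in zip(scores, actives)], 1)
        assert auc(screen) == pytest.approx(oracle)


class TestEnrichmentFactor:
    def test_all_actives_in_top_one_percent(self):
        actives = [True] * 2 + [False] * 198
        assert enrichment_factor(make_screen(actives), 1.0) == \
            pytest.approx(100.0)

    def test_toy_list_hand_count(self):
        # top 5% of 20 = 1 compound; 1 of 4 actives there
        actives = [True, False, True, True, False] + [False] * 14 + [True]
        screen = make_screen(actives)
        assert enrichment_factor(screen, 5.0) == pytest.approx((1 / 4) / 0.05)

    def test_uniform_expectation_near_one(self):
        rng = np.random.default_rng(1)
        values = []
        for _ in range(200):
            actives = (rng.random(40) < 0.25)
            if not 1 <= actives.sum() < 40:
                continue
            values.append(enrichment_factor(make_screen(actives.tolist()), 25.0))
        assert np.mean(values) == pytest.approx(1.0, abs=0.1)


class TestRIEBedroc:
    def test_all_actives_first_is_max(self):
        screen = make_screen([True] * 3 + [False] * 17)
        assert bedroc(screen, 20.0) == pytest.approx(1.0)

    def test_all_actives_last_is_min(self):
        screen = make_screen([False] * 17 + [True] * 3)
        assert bedroc(screen, 20.0) == pytest.approx(0.0)

    def test_rie_closed_form_small_list(self):
        screen = make_screen([False, True, False, True, False])
        alpha, n = 2.0, 5
        observed = np.exp(-alpha * 2 / n) + np.exp(-alpha * 4 / n)
        expectation = (2 / n) * (1 - np.exp(-alpha)) / (np.exp(alpha / n) - 1)
        assert rie(screen, alpha) == pytest.approx(observed / expectation)

    def test_matches_rdkit_oracle(self):
        from rdkit.ML.Scoring import Scoring

        rng = np.random.default_rng(3)
        for alpha in (20.0, 100.0):
            scores = -np.sort(-rng.random(50))
            actives = rng.random(50) < 0.2
            if not 1 <= actives.sum() < 50:
                continue
            screen = make_screen(actives.tolist(), scores.tolist())
            ranked = [[s, a] for s, a in zip(scores, actives)]
            assert rie(screen, alpha) == \
                pytest.approx(Scoring.CalcRIE(ranked, 1, alpha))
            assert bedroc(screen, alpha) == \
                pytest.approx(Scoring.CalcBEDROC(ranked, 1, alpha))

    def test_bedroc_invariant_to_decoy_shuffle_below_last_active(self):
        a = make_screen([True, False, True, False, False, False])
        b = make_screen([True, False, True, False, False, False])
        assert bedroc(a, 20.0) == bedroc(b, 20.0)

    def test_bedroc_monotone_under_active_promotion(self):
        worse = make_screen([False, True, False, True, False, False])
        better = make_screen([True, False, False, True, False, False])
        assert bedroc(better, 20.0) > bedroc(worse, 20.0)

    def test_small_alpha_approaches_auc_behaviour(self):
        screen = make_screen([True, False, True, False, False, False, True, False])
        assert bedroc(screen, 0.001) == pytest.approx(auc(screen), abs=0.01)


class TestRanking:
    def test_identical_member_ranked_first(self, map4c):
        library = ["CCO", "CCCN", "c1ccccc1"]
        fps = map4c.transform(library)
        query = MinHashFP(values=map4c.encode("CCO"), config=map4c.config_)
        screen = rank_by_similarity(query, fps, [True, False, False],
                                    ids=list("abc"))
        assert screen.ids[0] == "a" and screen.scores[0] == 1.0

    def test_matches_argsort_oracle(self, map4c):
        library = ["CCO", "CCN", "CCCO", "CCC(N)C", "CC(O)C"]
        fps = map4c.transform(library)
        query = MinHashFP(values=map4c.encode("CCOC"), config=map4c.config_)
        screen = rank_by_similarity(
            query, fps, [True, False, True, False, False],
            ids=[f"m{i}" for i in range(5)])
        sims = np.mean(fps == query.values[None, :], axis=1)
        expected = [f"m{i}" for i in np.lexsort((range(5), -sims))]
        assert list(screen.ids) == expected


class TestBenchmarkProtocol:
    def test_near_duplicate_actives_score_high(self):
        actives = ["CCCCCCCCO", "CCCCCCCCN", "CCCCCCC(C)O",
                   "CCCCCCCCOC", "CCCCCCCC(N)O", "CCCCCCCCC(O)C"]
        decoys = ["c1ccccc1", "c1ccncc1", "C1CC1", "CC(=O)OC",
                  "O=S(=O)(O)O", "CCl"]
        table = run_benchmark_set(actives, decoys,
                                  FPConfig.from_variant("map4c"),
                                  n_queries=3, seed=0)
        assert table.values["AUC"] > 0.9

    def test_determinism(self):
        actives = [f"CCCCC{'C' * i}O" for i in range(7)]
        decoys = ["c1ccccc1", "CCl", "CBr"]
        kwargs = dict(config=FPConfig.from_variant("map4c"), n_queries=3, seed=4)
        assert run_benchmark_set(actives, decoys, **kwargs).values == \
            run_benchmark_set(actives, decoys, **kwargs).values

    def test_too_few_actives(self):
        with pytest.raises(TooFewActivesError):
            run_benchmark_set(["CCO", "CCN"], ["CCl"], n_queries=5)


class TestAggregateRanks:
    @staticmethod
    def table(set_name, fingerprint, value):
        return MetricTable(set_name, fingerprint,
                           {m: value for m in ("AUC", "EF1")})

    def test_dominating_fingerprint_rank_one(self):
        tables = [self.table(s, "good", 0.9) for s in "AB"] + \
                 [self.table(s, "bad", 0.5) for s in "AB"]
        ranks = aggregate_ranks(tables)
        assert (ranks.loc["good"] == 1.0).all()
        assert (ranks.loc["bad"] == 2.0).all()

    def test_tied_fingerprints_average_rank(self):
        tables = [self.table("A", "x", 0.7), self.table("A", "y", 0.7)]
        ranks = aggregate_ranks(tables)
        assert (ranks.loc["x"] == 1.5).all() and (ranks.loc["y"] == 1.5).all()

    def test_hand_computed_three_by_two(self):
        values = {"f1": {"A": 0.9, "B": 0.4}, "f2": {"A": 0.8, "B": 0.6},
                  "f3": {"A": 0.7, "B": 0.5}}
        tables = [self.table(s, f, values[f][s])
                  for f in values for s in "AB"]
        ranks = aggregate_ranks(tables)
        # set A order: f1 f2 f3 -> 1 2 3 ; set B order: f2 f3 f1 -> 3 1 2
        assert ranks.loc["f1", "AUC"] == pytest.approx(2.0)
        assert ranks.loc["f2", "AUC"] == pytest.approx(1.5)
        assert ranks.loc["f3", "AUC"] == pytest.approx(2.5)

    def test_missing_set_rejected(self):
        from mapfp.errors import MissingSetError

        tables = [self.table("A", "x", 0.7), self.table("B", "y", 0.7)]
        with pytest.raises(MissingSetError):
            aggregate_ranks(tables)


class TestComputeMetrics:
    def test_all_seven_metrics_present(self):
        metrics = compute_metrics(make_screen([True, False, True, False]))
        assert set(metrics) == {"AUC", "EF1", "EF5", "BEDROC20",
                                "BEDROC100", "RIE20", "RIE100"}
        assert 0 <= metrics["AUC"] <= 1
        assert 0 <= metrics["BEDROC20"] <= 1
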