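import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwtcardio import metrics as m


def brute_force_max_matching(truth, detected, tol):
    """Maximum bipartite matching oracle (exhaustive via networkx)."""
    import networkx as nx

    g = nx.Graph()
    t_nodes = [("t", i) for i in range(len(truth))]
    d_nodes = [("d", j) for j in range(len(detected))]
    g.add_nodes_from(t_nodes, bipartite=0)
    g.add_nodes_from(d_nodes, bipartite=1)
    for i, tv in enumerate(truth):
        for j, dv in enumerate(detected):
            if abs(tv - dv) <= tol:
                g.add_edge(("t", i), ("d", j))
    match = nx.bipartite.maximum_matching(g, top_nodes=t_nodes)
    return len(match) // 2


class TestMatchEvents:
    def test_identical_lists_perfect(self):
        t = [1.0, 2.0, 3.0]
        cm = m.match_events(t, t, 0.05, 1000)
        assert (cm.TP, cm.FN, cm.FP) == (3, 0, 0)
        assert cm.TN == 997

    def test_miss_and_false_alarm(self):
        cm = m.match_events([1.0], [1.3], 0.1, 100)
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (0, 1, 1, 98)

    def test_n_samples_too_small_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            m.match_events([1.0, 2.0], [5.0], 0.1, 2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_greedy_matching_attains_optimal_cardinality(self, seed):
        rng = np.random.default_rng(seed)
        n_t, n_d = rng.integers(0, 20, 2)
        truth = np.sort(rng.uniform(0, 10, n_t))
        detected = np.sort(truth[: min(n_t, n_d)] + rng.normal(0, 0.08, min(n_t, n_d)))
        detected = np.sort(np.concatenate(
            [detected, rng.uniform(0, 10, max(n_d - n_t, 0))]
        ))
        tol = 0.1
        cm = m.match_events(truth, detected, tol, 10_000)
        assert cm.TP == brute_force_max_matching(truth, detected, tol)


class TestStatistics:
    def test_r_wave_user1_values(self):
        cm = m.ConfusionMatrix(TP=117, FN=6, FP=0, TN=32901)
        assert m.round_half_up(m.sensitivity(cm), 4) == 0.9512
        assert m.specificity(cm) == 1.0
        assert m.round_half_up(m.accuracy(cm), 4) == 0.9998

    def test_r_wave_user5_values(self):
        cm = m.ConfusionMatrix(TP=229, FN=2, FP=10, TN=101903)
        assert m.round_half_up(m.sensitivity(cm), 4) == 0.9913
        assert m.round_half_up(m.specificity(cm), 4) == 0.9999

    def test_degenerate_perfect_matrix(self):
        cm = m.ConfusionMatrix(TP=1, FN=0, FP=0, TN=1)
        for stat in (m.sensitivity, m.specificity, m.accuracy, m.ppv):
            assert stat(cm) == 1.0
        assert m.correct_rate(cm) == 100.0

    def test_accuracy_is_not_ppv(self):
        # the published tables' "Precision" equals overall accuracy
        cm = m.ConfusionMatrix(TP=117, FN=6, FP=0, TN=32901)
        assert m.ppv(cm) == 1.0
        assert m.accuracy(cm) != m.ppv(cm)

    def test_zero_denominator_names_statistic(self):
        cm = m.ConfusionMatrix(TP=0, FN=0, FP=1, TN=1)
        with pytest.raises(m.UndefinedStatisticError, match="sensitivity"):
            m.sensitivity(cm)

    def test_sensitivity_monotone_in_tp(self):
        prev = -1.0
        for tp in range(0, 50, 5):
            s = m.sensitivity(m.ConfusionMatrix(TP=tp, FN=10, FP=3, TN=100))
            assert s >= prev
            prev = s


class TestPooling:
    def test_pool_singleton_identity(self):
        cm = m.ConfusionMatrix(TP=1, FN=2, FP=3, TN=4)
        assert m.pool([cm]) == cm

    def test_pool_order_invariant_and_associative(self, rng):
        cms = [
            m.ConfusionMatrix(*map(int, rng.integers(0, 100, 4)))
            for _ in range(5)
        ]
        a = m.pool(cms)
        b = m.pool(cms[::-1])
        c = m.pool([m.pool(cms[:2]), m.pool(cms[2:])])
        assert a == b == c

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            m.pool([])


@pytest.fixture(scope="module")
def tables():
    return m.load_reference_tables()


class TestReferenceTables:
    """The bundled count tables must reproduce every printed statistic."""

    def test_r_wave_stats_reproduced_at_printed_precision(self, tables):
        for user, printed in tables["r_wave_stats"].items():
            cm = m.cm_from_dict(tables["r_wave"][user])
            for stat, fn in (("sensitivity", m.sensitivity),
                             ("specificity", m.specificity),
                             ("precision", m.accuracy)):
                want = printed[stat]
                decimals = max(len(str(want).split(".")[-1]), 1)
                got = m.round_half_up(fn(cm), decimals)
                assert got == pytest.approx(want, abs=10 ** -decimals / 2), (
                    f"{user} {stat}"
                )

    def test_extrasystole_per_test_and_pooled(self, tables):
        for test, counts in tables["extrasystole"].items():
            cm = m.cm_from_dict(counts)
            want = tables["extrasystole_stats_pct"][test]
            assert m.round_half_up(100 * m.sensitivity(cm), 2) == want["sensitivity"]
            assert 100 * m.specificity(cm) == want["specificity"]
        pooled = m.pool([m.cm_from_dict(c) for c in tables["extrasystole"].values()])
        assert m.round_half_up(100 * m.sensitivity(pooled), 2) == 99.29
        assert 100 * m.specificity(pooled) == 100.0

    def test_arrhythmia_per_test_and_pooled(self, tables):
        for test, counts in tables["arrhythmia"].items():
            cm = m.cm_from_dict(counts)
            want = tables["arrhythmia_stats_pct"][test]
            assert m.round_half_up(100 * m.sensitivity(cm), 2) == want["sensitivity"]
        pooled = m.pool([m.cm_from_dict(c) for c in tables["arrhythmia"].values()])
        assert m.round_half_up(100 * m.sensitivity(pooled), 2) == 93.48
        assert 100 * m.specificity(pooled) == 100.0

    def test_headline_mean_sensitivity(self, tables):
        cms = [m.cm_from_dict(c) for c in tables["r_wave"].values()]
        mean_pct = 100 * m.mean_stat(cms, m.sensitivity)
        assert m.round_half_up(mean_pct, 2) == tables["headline_mean_r_sensitivity_pct"]

    def test_scr_correct_rows_reproduced(self, tables):
        # the printed rows mix round-half-up and truncation; 0.02 points
        # covers every cell of both protocols
        for key_cm, key_stats in (("scr_stroop", "scr_stroop_stats_pct"),
                                  ("scr_sounds", "scr_sounds_stats_pct")):
            for user, counts in tables[key_cm].items():
                cm = m.cm_from_dict(counts)
                want = tables[key_stats][user]["correct"]
                assert m.correct_rate(cm) == pytest.approx(want, abs=0.02), user

    def test_sounds_success_average(self, tables):
        successes = [v["success"] for v in tables["scr_sounds_stats_pct"].values()]
        assert m.round_half_up(float(np.mean(successes)), 2) == (
            tables["stress_test_averages_pct"]["sounds"]
        )


class TestRoc:
    def test_separable_scores_reach_perfect_corner(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["relax", "relax", "stress", "stress"])
        fpr, tpr = m.roc_points(scores, labels)
        assert np.any((fpr == 0.0) & (tpr == 1.0))

    def test_single_class_rejected(self):
        with pytest.raises(m.UndefinedStatisticError):
            m.roc_points([0.1, 0.2], ["stress", "stress"])
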