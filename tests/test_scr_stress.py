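import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwtcardio import SCRRecord, SCRSimSpec, gen_scr, metrics
from cwtcardio import scr_stress as ss


class TestVoltageDivider:
    def test_zero_resistance_gives_vcc(self):
        cfg = ss.DividerConfig()
        assert ss.divider_voltage(0.0, cfg) == pytest.approx(cfg.Vcc)

    def test_matched_resistance_halves_vcc(self):
        cfg = ss.DividerConfig()
        assert ss.divider_voltage(cfg.R2, cfg) == pytest.approx(cfg.Vcc / 2)

    def test_printed_anchor_10k(self):
        cfg = ss.DividerConfig()
        vo = ss.divider_voltage(10e3, cfg)
        assert vo / cfg.Vcc == pytest.approx(890.0 / 900.0)  # ~0.98889 Vcc

    def test_strictly_decreasing_in_rs(self):
        rs = np.logspace(3, 7, 50)
        vo = ss.divider_voltage(rs)
        assert np.all(np.diff(vo) < 0)

    def test_inverse_degenerate_points(self):
        cfg = ss.DividerConfig()
        assert ss.resistance_from_voltage(cfg.Vcc, cfg) == pytest.approx(0.0)
        assert ss.resistance_from_voltage(cfg.Vcc / 2, cfg) == pytest.approx(cfg.R2)

    def test_round_trip_identity_over_physiological_range(self, rng):
        cfg = ss.DividerConfig()
        rs = rng.uniform(10e3, 10e6, 1000)
        back = ss.resistance_from_voltage(ss.divider_voltage(rs, cfg), cfg)
        np.testing.assert_allclose(back, rs, rtol=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ss.divider_voltage(-1.0)
        with pytest.raises(ValueError):
            ss.resistance_from_voltage(0.0)
        with pytest.raises(ValueError):
            ss.resistance_from_voltage(2.0, ss.DividerConfig(Vcc=1.775))


class TestLabelSamples:
    def test_stroop_beginning_window(self):
        scr = gen_scr(SCRSimSpec(duration_s=300.0, seed=0))
        labeled = ss.label_samples(
            scr, ss.ProtocolSchedule.stroop(60.0, 240.0, "beginning")
        )
        t = labeled.time
        assert np.all(labeled.labels[t < 55.0] == "relax")
        assert np.all(labeled.labels[(t >= 60.0) & (t < 240.0)] == "stress")
        assert np.all(labeled.labels[(t >= 55.0) & (t < 60.0)] == "unlabeled")

    def test_stroop_end_window(self):
        scr = gen_scr(SCRSimSpec(duration_s=300.0, seed=0))
        labeled = ss.label_samples(
            scr, ss.ProtocolSchedule.stroop(60.0, 230.0, "end")
        )
        t = labeled.time
        assert np.all(labeled.labels[t >= t[-1] - 60.0] == "relax")

    def test_stroop_custom_window(self):
        scr = gen_scr(SCRSimSpec(duration_s=300.0, seed=0))
        labeled = ss.label_samples(
            scr, ss.ProtocolSchedule.stroop(60.0, 240.0, ("custom", 15.0, 55.0))
        )
        t = labeled.time
        assert np.all(labeled.labels[(t >= 15.0) & (t < 55.0)] == "relax")
        assert np.all(labeled.labels[t < 15.0] == "unlabeled")

    def test_empty_schedule_all_unlabeled(self):
        scr = gen_scr(SCRSimSpec(duration_s=60.0, seed=0))
        labeled = ss.label_samples(scr, ss.ProtocolSchedule(kind="sounds"))
        assert set(labeled.labels) == {"unlabeled"}

    def test_sounds_only_reactive_spans_labeled(self):
        scr = gen_scr(SCRSimSpec(duration_s=200.0, seed=0))
        onsets = [60.0, 75.0, 90.0, 105.0, 120.0]
        sched = ss.ProtocolSchedule.sounds(
            onsets, reactive=[False, True, False, True, False]
        )
        labeled = ss.label_samples(scr, sched)
        n_stress = int(np.sum(labeled.labels == "stress"))
        assert n_stress == 2 * int(15.0 * scr.fs)  # two 15 s spans at 4 Hz

    def test_contradictory_events_rejected(self):
        with pytest.raises(ss.ScheduleError, match="contradictory"):
            ss.ProtocolSchedule(
                kind="sounds",
                events=[(10.0, "stress"), (10.0, "relax")],
            )


class TestStressTree:
    @staticmethod
    def _record(voltages, labels):
        return SCRRecord(np.asarray(voltages, dtype=float),
                         labels=np.asarray(labels, dtype=object))

    def test_separable_classes_depth_one(self):
        rec = self._record([1.0] * 10 + [1.2] * 10,
                           ["relax"] * 10 + ["stress"] * 10)
        tree = ss.train_stress_tree(rec)
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert 1.0 < tree.root_threshold < 1.2
        cm = ss.evaluate_tree(tree, rec)
        assert cm.FN == cm.FP == 0

    def test_no_signal_majority_stump(self, rng):
        v = np.tile([0.5, 0.7], 30)
        labels = np.array(["stress"] * 40 + ["relax"] * 20, dtype=object)
        rec = self._record(v[:60], labels)
        # features and labels are independent: any gain is zero
        tree = ss.train_stress_tree(rec)
        assert tree.root.is_leaf
        assert tree.root.klass == "stress"

    def test_majority_stump_on_balanced_data_scores_half(self):
        rec = self._record([0.5, 0.7] * 20,
                           ["stress", "relax"] * 20)
        stump = ss.StressTree(root=ss.TreeNode(klass="stress"))
        cm = ss.evaluate_tree(stump, rec)
        assert metrics.accuracy(cm) == pytest.approx(0.5)

    def test_gaussian_threshold_recovery(self):
        """Root threshold lands within 15 mV of the analytic Bayes boundary."""
        rng = np.random.default_rng(7)
        n = 400
        relax = rng.normal(0.68, 0.015, n // 2)
        stress = rng.normal(0.73, 0.015, n // 2)
        bayes = 0.705  # equal priors, equal variances: midpoint of the means
        v = np.clip(np.concatenate([relax, stress]), 0.0, 2.35)
        labels = np.array(["relax"] * (n // 2) + ["stress"] * (n // 2),
                          dtype=object)
        perm = rng.permutation(n)
        rec = self._record(v[perm], labels[perm])
        tree = ss.train_stress_tree(rec)
        assert abs(tree.root_threshold - bayes) <= 0.015
        cm = ss.evaluate_tree(tree, rec)
        assert metrics.accuracy(cm) >= 0.90

    def test_training_determinism_given_order(self, rng):
        v = np.clip(rng.normal(0.7, 0.03, 200), 0, 2.35)
        labels = np.where(v > 0.71, "stress", "relax").astype(object)
        rec = self._record(v, labels)
        t1 = ss.train_stress_tree(rec).to_json()
        t2 = ss.train_stress_tree(rec).to_json()
        assert t1 == t2

    def test_single_class_input_rejected(self):
        rec = self._record([0.5] * 10, ["relax"] * 10)
        with pytest.raises(ss.TrainingError):
            ss.train_stress_tree(rec)

    def test_unlabeled_only_evaluation_rejected(self):
        rec = self._record([0.5] * 10, ["unlabeled"] * 10)
        stump = ss.StressTree(root=ss.TreeNode(klass="stress"))
        with pytest.raises(ss.EvaluationError):
            ss.evaluate_tree(stump, rec)

    def test_json_round_trip(self):
        rec = self._record([1.0] * 10 + [1.2] * 10,
                           ["relax"] * 10 + ["stress"] * 10)
        tree = ss.train_stress_tree(rec)
        clone = ss.StressTree.from_json(tree.to_json())
        v = np.array([[0.9], [1.1], [1.3]])
        assert list(tree.predict(v)) == list(clone.predict(v))

    def test_reduced_error_pruning_collapses_overfit_split(self, rng):
        v = np.clip(rng.normal(0.7, 0.02, 300), 0, 2.35)
        labels = rng.choice(["stress", "relax"], 300).astype(object)
        rec = self._record(v, labels)
        tree = ss.train_stress_tree(rec, min_leaf=2)
        pruned = ss.reduced_error_prune(tree, rec)

        def depth(node):
            return 0 if node.is_leaf else 1 + max(depth(node.left),
                                                  depth(node.right))
        assert depth(pruned.root) <= depth(tree.root)

    def test_paper_scale_separation_classifies_well(self):
        """Millivolt-scale stress/relax separation (0.70 vs 0.68 V) is
        learnable per user when the noise floor is small."""
        spec = SCRSimSpec(
            duration_s=400.0, baseline_v=0.68, noise_sd_v=0.005,
            responses=[(60.0 + 80.0 * k, 0.02, 5.0, 55.0) for k in range(4)],
            seed=21,
        )
        rec = gen_scr(spec)
        tree = ss.train_stress_tree(rec)
        cm = ss.evaluate_tree(tree, rec)
        assert metrics.correct_rate(cm) >= 90.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_single_changepoint_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        split = rng.uniform(0.5, 1.5)
        lo = np.sort(rng.uniform(0.1, split - 0.01, 20))
        hi = np.sort(rng.uniform(split + 0.01, 2.0, 20))
        rec = self._record(
            np.concatenate([lo, hi]),
            np.array(["relax"] * 20 + ["stress"] * 20, dtype=object),
        )
        tree = ss.train_stress_tree(rec)
        assert lo[-1] < tree.root_threshold <= hi[0]
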