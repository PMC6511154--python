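import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import svhotspot as sv
from svhotspot.metrics import TOP_FRACTIONS, recall_curve
from svhotspot.model import ModelDataset

from helpers import brute_auc
from test_model import make_dataset


class TestAUC:
    def test_perfect_and_all_ties(self):
        assert sv.auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert sv.auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_hand_counted_pairs(self):
        assert sv.auc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sv.auc([1, 1], [0.1, 0.2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 200))
    def test_matches_all_pairs_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, max(1, n // 4), replace=False)] = 1
        if labels.sum() == n:
            return
        scores = np.round(rng.uniform(size=n), 2)  # ties likely
        assert sv.auc(labels, scores) == pytest.approx(
            brute_auc(labels, scores), abs=1e-12)


class TestRecallAtTopFraction:
    def test_single_top_positive(self):
        labels = [1] + [0] * 9
        scores = np.linspace(1, 0.1, 10)
        assert sv.recall_at_top_fraction(labels, scores, 0.1) == 1.0

    def test_bottom_half_positives_miss(self):
        labels = [0] * 5 + [1] * 5
        scores = np.linspace(1, 0.1, 10)
        assert sv.recall_at_top_fraction(labels, scores, 0.1) == 0.0

    def test_counting_above_the_cut(self):
        # positives at ranks 1, 2, 5, 20 of 20; top 25% = 5 observations
        scores = np.linspace(1.0, 0.05, 20)
        labels = np.zeros(20)
        labels[[0, 1, 4, 19]] = 1
        assert sv.recall_at_top_fraction(labels, scores, 0.25) == 0.75

    def test_exact_count_marked_positive(self):
        """The top-10% threshold marks exactly 10% of a 1000-point set."""
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=1000)
        m = int(np.floor(0.1 * 1000 + 0.5))
        assert m == 100
        order = np.argsort(-scores, kind="stable")[:m]
        assert len(order) == 100

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            sv.recall_at_top_fraction([0, 0], [0.1, 0.2], 0.5)


class TestLift:
    def test_basic_ratios(self):
        assert sv.lift_of_recall(0.2, 0.1) == pytest.approx(2.0)
        assert sv.lift_of_recall(0.1, 0.1) == pytest.approx(1.0)
        assert sv.lift_of_recall(0.0, 0.3) == 0.0


class TestTInterval:
    def test_constant_values_zero_width(self):
        lo, hi = sv.t_interval([0.7] * 10)
        assert lo == hi == pytest.approx(0.7)

    def test_two_point_hand_formula(self):
        lo, hi = sv.t_interval([0.4, 0.6], alpha=0.05)
        s = np.std([0.4, 0.6], ddof=1)
        half = stats.t.ppf(0.975, 1) * s / np.sqrt(2)
        assert (lo, hi) == pytest.approx((0.5 - half, 0.5 + half))

    def test_widens_as_alpha_decreases(self):
        vals = [0.4, 0.5, 0.6, 0.7]
        w5 = np.diff(sv.t_interval(vals, 0.05))[0]
        w1 = np.diff(sv.t_interval(vals, 0.01))[0]
        assert w1 > w5

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            sv.t_interval([0.5])


class TestHanleyMcNeilSE:
    def test_perfect_auc_has_zero_se(self):
        assert sv.hanley_mcneil_se(1.0, 10, 10) == 0.0

    def test_hand_evaluated_small_case(self):
        # Q=0.5: Q1=1/3, Q2=1/3; var=(0.25 + (1/3-0.25) + (1/3-0.25))/4
        expected = np.sqrt((0.25 + (1 / 3 - 0.25) * 2) / 4)
        assert sv.hanley_mcneil_se(0.5, 2, 2) == pytest.approx(expected)

    def test_vanishes_with_sample_size(self):
        ses = [sv.hanley_mcneil_se(0.8, n, n) for n in (10, 100, 10_000)]
        assert ses[0] > ses[1] > ses[2]
        assert ses[2] < 0.01

    def test_matches_bootstrap_se(self):
        """Analytic SE within 25% of a bootstrap SE at Q=0.8, n0=500, n1=50."""
        rng = np.random.default_rng(42)
        # score distributions tuned so that true AUC ~ 0.8
        mu = stats.norm.ppf(0.8) * np.sqrt(2)
        aucs = []
        for _ in range(400):
            neg = rng.normal(0, 1, 500)
            pos = rng.normal(mu, 1, 50)
            labels = np.r_[np.zeros(500), np.ones(50)]
            aucs.append(sv.auc(labels, np.r_[neg, pos]))
        empirical_se = np.std(aucs, ddof=1)
        analytic = sv.hanley_mcneil_se(0.8, 500, 50)
        assert abs(analytic - empirical_se) / empirical_se < 0.25

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            sv.hanley_mcneil_se(1.2, 10, 10)
        with pytest.raises(ValueError):
            sv.hanley_mcneil_se(0.5, 0, 10)


class TestSummarize:
    def test_constant_aucs(self):
        # test folds large enough that SE(W) at AUC 0.7 excludes 0.5
        ds = make_dataset(n=2000, n_pos=200, seed=3)
        cv = sv.run_repeated_cv(ds, repeats=2, seed=3)
        for f in cv.fold_results:  # force constant fold AUCs
            f.train_auc = f.test_auc = 0.7
        summ = sv.summarize(cv)
        assert summ.median_test_auc == 0.7
        c = summ.confidence
        assert c.t_lower == pytest.approx(0.7)
        assert c.t_upper == pytest.approx(0.7)
        assert c.has_power  # both intervals exclude 0.5

    def test_best_lift_is_max_of_lift_vector(self):
        ds = make_dataset(n=400, n_pos=40, seed=5)
        summ = sv.summarize(sv.run_repeated_cv(ds, repeats=2, seed=5))
        assert summ.best_lift == max(summ.recall.lift)
        assert summ.recall.top_fractions == TOP_FRACTIONS

    def test_has_power_monotone_in_auc(self):
        ds = make_dataset(n=300, n_pos=30, seed=6)
        cv = sv.run_repeated_cv(ds, repeats=2, seed=6)
        summ0 = sv.summarize(cv)
        for f in cv.fold_results:
            f.test_auc = min(f.test_auc + 0.3, 1.0)
        summ1 = sv.summarize(cv)
        assert not (summ0.has_power and not summ1.has_power)

    def test_null_run_rarely_has_power(self):
        """Models fitted to unrelated targets must not be declared powerful."""
        flags = []
        for seed in range(8):
            ds = make_dataset(n=2000, n_pos=30, seed=100 + seed)
            summ = sv.summarize(sv.run_repeated_cv(ds, repeats=5, seed=seed))
            flags.append(summ.has_power)
        assert sum(flags) <= 1

    def test_json_round_trip(self, tmp_path):
        import json
        ds = make_dataset(n=200, n_pos=20, seed=7)
        summ = sv.summarize(sv.run_repeated_cv(ds, repeats=2, seed=7))
        path = tmp_path / "summary.json"
        summ.to_json(path)
        d = json.loads(path.read_text())
        assert d["best_lift"] == summ.best_lift
        assert len(d["lift"]) == len(TOP_FRACTIONS)


class TestSelectionAndComparison:
    def _summary(self, cancer, lift, auc_value, level=10_000, pset=("G4",)):
        ds = make_dataset(n=200, n_pos=20, seed=1)
        summ = sv.summarize(sv.run_repeated_cv(ds, repeats=2, seed=1))
        object.__setattr__(summ, "cancer_type", cancer)
        object.__setattr__(summ, "aggregation_level", level)
        object.__setattr__(summ, "predictor_set", pset)
        object.__setattr__(summ, "median_test_auc", auc_value)
        object.__setattr__(summ.recall, "lift",
                           np.full(len(TOP_FRACTIONS), lift))
        return summ

    def test_argmax_lift_per_cancer(self):
        s = [self._summary("A", 1.2, 0.6), self._summary("A", 3.0, 0.6),
             self._summary("A", 2.1, 0.6)]
        best = sv.select_best_models(s)
        assert best["A"].best_lift == 3.0

    def test_lift_tie_broken_by_auc(self):
        s = [self._summary("A", 2.0, 0.6), self._summary("A", 2.0, 0.7)]
        assert sv.select_best_models(s)["A"].median_test_auc == 0.7

    def test_single_dataset_selected(self):
        s = [self._summary("B", 1.5, 0.55)]
        assert sv.select_best_models(s)["B"] is s[0]

    def test_compare_flags_winner_and_tie(self):
        s = [self._summary("A", 1.5, 0.6, pset=("G4",)),
             self._summary("A", 2.0, 0.6, pset=("SL_short", "SL_long"))]
        table = sv.compare_predictor_sets(s)
        w = table[table["winner"]]
        assert w.iloc[0]["predictor_set"] == "SL_short+SL_long"
        tied = sv.compare_predictor_sets(
            [self._summary("A", 2.0, 0.6, pset=("G4",)),
             self._summary("A", 2.0, 0.6, pset=("SL_short",))])
        assert tied["tie"].all()

    def test_median_over_datasets_matches_direct_sort(self):
        lifts = [1.0, 3.0, 2.0]
        s = [self._summary("A", l, 0.6, pset=("G4",)) for l in lifts]
        table = sv.compare_predictor_sets(s)
        assert table.iloc[0]["median_best_lift"] == sorted(lifts)[1]


class TestTransfer:
    def test_self_transfer_beats_shuffled_target(self):
        better = 0
        for seed in range(10):
            ds = make_dataset(n=1500, n_pos=75, seed=seed, signal=3.0)
            cv = sv.run_repeated_cv(ds, repeats=2, seed=seed)
            model = sv.freeze_median_model(cv)
            own = sv.transfer_evaluate(model, ds)
            shuffled = make_dataset(n=1500, n_pos=75, seed=500 + seed)
            null = sv.transfer_evaluate(model, shuffled)
            better += own.best_lift >= null.best_lift
        assert better >= 8

    def test_zero_coefficient_model_is_random_equivalent(self):
        ds = make_dataset(n=2000, n_pos=200, seed=9)
        model = sv.FrozenModel(("P0", "P1"), np.zeros(2), 0.0,
                               np.zeros(2), np.ones(2))
        curve = sv.transfer_evaluate(model, ds)
        # all scores tie at 0.5; stable-order cut = random selection
        assert 0.5 <= max(curve.lift) <= 1.6

    def test_independent_hotspots_give_null_lift(self):
        lifts = []
        for seed in range(10):
            src = make_dataset(n=1200, n_pos=60, seed=seed, signal=2.0)
            cv = sv.run_repeated_cv(src, repeats=2, seed=seed)
            model = sv.freeze_median_model(cv)
            tgt = make_dataset(n=1200, n_pos=60, seed=900 + seed)
            lifts.append(np.mean(sv.transfer_evaluate(model, tgt).lift))
        assert 0.6 <= np.mean(lifts) <= 1.4

    def test_predictor_mismatch_rejected(self):
        ds = make_dataset(n=100, n_pos=10, seed=1)
        model = sv.FrozenModel(("other",), np.zeros(1), 0.0,
                               np.zeros(1), np.ones(1))
        with pytest.raises(ValueError, match="mismatch"):
            sv.transfer_evaluate(model, ds)
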