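import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import svhotspot as sv
from svhotspot.density import DensityProfile

from helpers import brute_spearman, brute_top_k


def make_profile(densities, windows, cancer="X"):
    return DensityProfile(cancer_type=cancer, windows=windows,
                          densities=np.asarray(densities, dtype=float))


class TestMakeWindows:
    def test_tiling_with_truncated_last_window(self):
        w = sv.make_windows({"1": 25_000}, 10_000)
        assert w.frame[["start", "end"]].to_numpy().tolist() == \
            [[0, 10_000], [10_000, 20_000], [20_000, 25_000]]

    def test_exact_fit_single_window(self):
        assert sv.make_windows({"1": 10_000}, 10_000).n == 1

    def test_global_indices_across_chromosomes(self):
        w = sv.make_windows({"2": 5_000, "1": 15_000}, 10_000)
        assert w.n == 3
        # genome order: chromosome 1 before 2, regardless of input order
        assert w.frame["chrom"].tolist() == ["1", "1", "2"]
        assert w.frame["index"].tolist() == [0, 1, 2]

    def test_bad_size_rejected(self):
        with pytest.raises(ValueError):
            sv.make_windows({"1": 100}, 0)


class TestBreakpointDensity:
    def test_fraction_of_total(self, small_windows):
        ends = pd.DataFrame({
            "chrom": ["1"] * 5 + ["2"] * 95,
            "start": [100] * 5 + [50] * 95,
            "end": [101] * 5 + [51] * 95})
        prof = sv.breakpoint_density(ends, small_windows)
        assert prof.densities[0] == 0.05

    def test_boundary_spanning_end_counted_in_both_windows(self, small_windows):
        ends = pd.DataFrame({"chrom": ["1"], "start": [9_995], "end": [10_005]})
        prof = sv.breakpoint_density(ends, small_windows)
        assert prof.densities[0] == 1.0 and prof.densities[1] == 1.0
        assert prof.densities.sum() == 2.0  # 2/1 for a single spanning end

    def test_interior_ends_sum_to_one(self, small_windows):
        rng = np.random.default_rng(0)
        n = 200
        chrom = rng.choice(["1", "2"], size=n)
        start = np.where(chrom == "1", rng.integers(10, 24_000, n),
                         rng.integers(10, 9_000, n))
        ends = pd.DataFrame({"chrom": chrom, "start": start, "end": start + 1})
        prof = sv.breakpoint_density(ends, small_windows)
        assert prof.densities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_one_per_window(self, small_windows):
        frame = small_windows.frame
        ends = pd.DataFrame({"chrom": frame["chrom"],
                             "start": frame["start"] + 1,
                             "end": frame["start"] + 2})
        prof = sv.breakpoint_density(ends, small_windows)
        assert np.allclose(prof.densities, 1 / small_windows.n)

    def test_no_ends_is_an_error(self, small_windows):
        with pytest.raises(ValueError):
            sv.breakpoint_density(pd.DataFrame(columns=["chrom", "start", "end"]),
                                  small_windows)


class TestGeneralProfile:
    def test_weighted_sum(self, small_windows):
        p1 = make_profile([0.1] * 4, small_windows, "A")
        p2 = make_profile([0.2] * 4, small_windows, "B")
        g = sv.general_profile([p1, p2], {"A": 0.7, "B": 0.3})
        assert np.allclose(g.densities, 0.13)
        assert g.cancer_type == "general"

    def test_single_cancer_identity(self, small_windows):
        p = make_profile([0.5, 0.2, 0.2, 0.1], small_windows)
        g = sv.general_profile([p], {"X": 1.0})
        assert np.allclose(g.densities, p.densities)

    def test_equal_weights_give_mean(self, small_windows):
        p1 = make_profile([0.4, 0.3, 0.2, 0.1], small_windows, "A")
        p2 = make_profile([0.1, 0.2, 0.3, 0.4], small_windows, "B")
        g = sv.general_profile([p1, p2], {"A": 0.5, "B": 0.5})
        assert np.allclose(g.densities, 0.25)

    def test_identical_profiles_invariant_to_weights(self, small_windows):
        d = np.array([0.4, 0.3, 0.2, 0.1])
        ps = [make_profile(d, small_windows, c) for c in "ABC"]
        for w in ({"A": 0.8, "B": 0.1, "C": 0.1}, {"A": 1 / 3, "B": 1 / 3, "C": 1 / 3}):
            g = sv.general_profile(ps, w)
            assert np.allclose(g.densities, d)

    def test_missing_weight_is_an_error(self, small_windows):
        p = make_profile([0.25] * 4, small_windows, "A")
        with pytest.raises(ValueError, match="A"):
            sv.general_profile([p], {"B": 1.0})


class TestIncidenceWeights:
    def test_imputation_and_normalization(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("A\t80\nB\t20\n")
        w = sv.load_incidence_weights(path, ["A", "B", "C"])
        assert w == pytest.approx({"A": 80 / 120, "B": 20 / 120, "C": 20 / 120})
        assert sum(w.values()) == pytest.approx(1.0)

    def test_single_cancer_gets_weight_one(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("A\t7\n")
        assert sv.load_incidence_weights(path, ["A"]) == {"A": 1.0}

    def test_equal_counts_give_uniform_weights(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("A\t5\nB\t5\nC\t5\n")
        w = sv.load_incidence_weights(path, ["A", "B", "C"])
        assert all(v == pytest.approx(1 / 3) for v in w.values())

    def test_empty_table_is_an_error(self, tmp_path):
        path = tmp_path / "w.tsv"
        path.write_text("")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            sv.load_incidence_weights(path, ["A"])


class TestProfileCorrelation:
    def test_monotone_transform_gives_one(self, small_windows):
        p1 = make_profile([0.1, 0.2, 0.3, 0.4], small_windows)
        p2 = make_profile([0.2, 0.4, 0.6, 0.8], small_windows)
        assert sv.profile_correlation(p1, p2) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, small_windows):
        p1 = make_profile([0.1, 0.2, 0.3, 0.4], small_windows)
        p2 = make_profile([0.4, 0.3, 0.2, 0.1], small_windows)
        assert sv.profile_correlation(p1, p2) == pytest.approx(-1.0)

    def test_hand_ranked_value(self, small_windows):
        # d = (-1, 1, 0, 0): rho = 1 - 6*2/(4*(16-1)) = 0.8
        p1 = make_profile([1, 2, 3, 4], small_windows)
        p2 = make_profile([2, 1, 3, 4], small_windows)
        assert sv.profile_correlation(p1, p2) == pytest.approx(0.8)

    def test_per_chromosome_mode(self, small_windows):
        p1 = make_profile([1, 2, 3, 4], small_windows)
        p2 = make_profile([1, 3, 2, 9], small_windows)
        rho = sv.profile_correlation(p1, p2, per_chromosome=True)
        assert set(rho) == {"1", "2"}
        assert np.isnan(rho["2"])  # single window: undefined, reported missing

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=60),
           st.integers(0, 2**31 - 1))
    def test_matches_rank_then_pearson_oracle(self, xs, seed):
        rng = np.random.default_rng(seed)
        ys = rng.uniform(size=len(xs))
        if len(set(xs)) < 2:
            return  # constant input: correlation undefined
        w = sv.make_windows({"1": len(xs)}, 1)
        got = sv.profile_correlation(make_profile(xs, w), make_profile(ys, w))
        assert got == pytest.approx(brute_spearman(xs, ys), abs=1e-12)


class TestLabelHotspots:
    def test_top_k_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        n = 1000
        w = sv.make_windows({"1": n}, 1)
        dens = rng.uniform(size=n)
        lab = sv.label_hotspots(make_profile(dens, w), 1.0)
        assert lab.n_positives == 10
        assert set(lab.positive_indices()) == brute_top_k(dens, 10)

    def test_ties_resolved_in_genome_order(self):
        n = 1000
        w = sv.make_windows({"1": n}, 1)
        lab = sv.label_hotspots(make_profile(np.ones(n), w), 1.0)
        assert lab.positive_indices().tolist() == list(range(10))

    def test_floor_can_give_zero_hotspots(self):
        w = sv.make_windows({"1": 50}, 1)
        lab = sv.label_hotspots(make_profile(np.arange(50.0), w), 0.01)
        assert lab.n_positives == 0

    def test_positive_densities_dominate_negatives(self):
        rng = np.random.default_rng(5)
        w = sv.make_windows({"1": 500}, 1)
        dens = rng.uniform(size=500)
        lab = sv.label_hotspots(make_profile(dens, w), 5.0)
        assert dens[lab.labels].min() >= dens[~lab.labels].max()

    def test_bad_percent_rejected(self, small_windows):
        with pytest.raises(ValueError):
            sv.label_hotspots(make_profile([1, 2, 3, 4], small_windows), 0)


class TestPruneAndDedupe:
    def _labeling(self, windows, percent, positives, cancer="A"):
        labels = np.zeros(windows.n, dtype=bool)
        labels[list(positives)] = True
        return sv.HotspotLabeling(cancer_type=cancer, windows=windows,
                                  labeling_percent=percent, labels=labels)

    def test_few_positive_labelings_removed(self):
        w = sv.make_windows({"1": 100}, 1)
        l9 = self._labeling(w, 0.1, range(9))
        l10 = self._labeling(w, 0.5, range(10))
        kept, report = sv.prune_and_dedupe([l9, l10], min_positives=10)
        assert kept == [l10]
        assert report[0][3].startswith("fewer")

    def test_duplicates_keep_largest_percent(self):
        w = sv.make_windows({"1": 100}, 1)
        a = self._labeling(w, 0.5, range(12))
        b = self._labeling(w, 1.0, range(12))
        kept, report = sv.prune_and_dedupe([a, b])
        assert kept == [b]
        assert "duplicate" in report[0][3]

    def test_boundary_exactly_min_positives_kept(self):
        w = sv.make_windows({"1": 100}, 1)
        l10 = self._labeling(w, 1.0, range(10))
        kept, report = sv.prune_and_dedupe([l10])
        assert kept == [l10] and not report

    def test_same_labels_different_cancers_both_kept(self):
        w = sv.make_windows({"1": 100}, 1)
        a = self._labeling(w, 1.0, range(10), cancer="A")
        b = self._labeling(w, 1.0, range(10), cancer="B")
        kept, _ = sv.prune_and_dedupe([a, b])
        assert len(kept) == 2


class TestJaccard:
    def _labeling(self, windows, positives):
        labels = np.zeros(windows.n, dtype=bool)
        labels[list(positives)] = True
        return sv.HotspotLabeling("A", windows, 1.0, labels)

    def test_identity_symmetry_disjoint(self):
        w = sv.make_windows({"1": 10}, 1)
        a = self._labeling(w, {1, 2})
        b = self._labeling(w, {2, 3})
        c = self._labeling(w, {5, 6})
        assert sv.jaccard(a, a) == 1.0
        assert sv.jaccard(a, c) == 0.0
        assert sv.jaccard(a, b) == pytest.approx(1 / 3)
        assert sv.jaccard(a, b) == sv.jaccard(b, a)

    def test_both_empty_defined_as_zero(self):
        w = sv.make_windows({"1": 10}, 1)
        empty = self._labeling(w, set())
        assert sv.jaccard(empty, empty) == 0.0

    def test_mismatched_grids_rejected(self):
        a = self._labeling(sv.make_windows({"1": 10}, 1), {1})
        b = self._labeling(sv.make_windows({"1": 20}, 1), {1})
        with pytest.raises(ValueError):
            sv.jaccard(a, b)
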