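import numpy as np
import pandas as pd
import pytest

from refselect.bootstrap import (
    BootstrapSummary,
    bootstrap_selection,
    select_criterion_A,
    select_criterion_B,
    select_criterion_C,
    top_subsets_by_rank,
    top_subsets_by_size,
    ucl_vs_rank_plotdata,
)
from refselect.covariance import DesignSpec
from refselect.simulation import (
    SCENARIOS,
    build_scenario_covariance,
    simulate_dataset,
    true_optimal_subset,
)
from refselect.subsets import GeneSubset, enumerate_subsets

from conftest import make_matrix


def make_summary(ucl_sd=None, mean_rank=None, j=3):
    """Hand-built summary for criterion tests (fixture values, not bootstrapped)."""
    subsets = enumerate_subsets(j)
    n = len(subsets)
    ucl_sd = np.asarray(ucl_sd if ucl_sd is not None else np.linspace(0.5, 1.0, n))
    mean_rank = np.asarray(
        mean_rank if mean_rank is not None else np.arange(1.0, n + 1)
    )
    gene_ids = [f"g{i+1}" for i in range(j)]
    table = pd.DataFrame(
        {
            "subset": [s.indicator_string() for s in subsets],
            "genes": [",".join(s.gene_labels(gene_ids)) for s in subsets],
            "size": [s.size for s in subsets],
            "point_variance": ucl_sd**2,
            "ucl95_variance": ucl_sd**2,
            "ucl95_sd": ucl_sd,
            "mean_rank": mean_rank,
        }
    )
    return BootstrapSummary(
        table=table, subsets=subsets, gene_ids=gene_ids, B=1, seed=0
    )


class TestBootstrapSelection:
    def test_reproducible_given_seed(self, random_log_matrix):
        s1 = bootstrap_selection(random_log_matrix, B=50, seed=42)
        s2 = bootstrap_selection(random_log_matrix, B=50, seed=42)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_different_seeds_differ(self, random_log_matrix):
        s1 = bootstrap_selection(random_log_matrix, B=50, seed=1)
        s2 = bootstrap_selection(random_log_matrix, B=50, seed=2)
        assert not np.allclose(
            s1.table["ucl95_variance"], s2.table["ucl95_variance"]
        )

    def test_degenerate_identical_samples(self):
        m = make_matrix([[1.0, 2.0, 3.0]] * 6)
        summary = bootstrap_selection(m, B=20, seed=0)
        np.testing.assert_allclose(summary.table["ucl95_variance"], 0.0, atol=1e-14)
        # all variances tie at 0 -> every mean rank is the average rank
        np.testing.assert_allclose(summary.table["mean_rank"], (7 + 1) / 2)

    def test_B1_ucl_equals_single_replicate(self, random_log_matrix):
        summary = bootstrap_selection(
            random_log_matrix, B=1, seed=7, keep_replicates=True
        )
        np.testing.assert_allclose(
            summary.table["ucl95_variance"], summary.replicate_variances[0]
        )

    def test_ucl_above_5th_percentile_sort_oracle(self, random_log_matrix):
        summary = bootstrap_selection(
            random_log_matrix, B=200, seed=3, keep_replicates=True
        )
        reps = summary.replicate_variances
        assert reps.shape == (200, 31)
        # sort-based oracle for the interpolated 95th percentile
        srt = np.sort(reps, axis=0)
        pos = 0.95 * (200 - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        oracle = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
        np.testing.assert_allclose(summary.table["ucl95_variance"], oracle, rtol=1e-12)
        p5 = np.percentile(reps, 5, axis=0)
        assert np.all(summary.table["ucl95_variance"] >= p5)

    def test_point_variance_is_full_data_estimate(self, random_log_matrix):
        from refselect.covariance import estimate_covariance
        from refselect.subsets import subset_indicator_matrix, all_subset_variances

        summary = bootstrap_selection(random_log_matrix, B=5, seed=0)
        est = estimate_covariance(random_log_matrix)
        expected = all_subset_variances(est.V_hat, subset_indicator_matrix(5))
        np.testing.assert_allclose(summary.table["point_variance"], expected)

    def test_design_path_matches_intercept_when_trivial_groups(self, rng):
        # one-level category -> same model as intercept-only, different code path
        y = rng.normal(size=(15, 3))
        m = make_matrix(y)
        design = DesignSpec(np.ones((15, 1)), ["intercept"])
        s1 = bootstrap_selection(m, B=30, seed=9, design=design)
        s2 = bootstrap_selection(m, B=30, seed=9)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_design_bootstrap_runs(self, rng):
        y = rng.normal(size=(16, 3))
        design = DesignSpec.from_categories(["a", "b"] * 8)
        summary = bootstrap_selection(make_matrix(y), B=25, seed=11, design=design)
        assert len(summary.table) == 7
        assert (summary.table["ucl95_variance"] >= 0).all()

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="N >= 3"):
            bootstrap_selection(make_matrix([[1.0, 2.0], [3.0, 4.0]]), B=5, seed=0)

    def test_scenario1_recovers_true_optimum_in_majority_of_runs(self):
        # Monte-Carlo: at N=80 the bootstrap-UCL choice should usually be
        # the pair that truly minimizes the log-NF variance
        spec = SCENARIOS["s1_uncorrelated"]
        truth, _ = true_optimal_subset(build_scenario_covariance(spec))
        hits = 0
        for i in range(20):
            data = simulate_dataset(spec, seed=1000 + i)
            summary = bootstrap_selection(data, B=200, seed=i)
            if select_criterion_A(summary).subset == truth:
                hits += 1
        assert hits > 10


class TestCriterionA:
    def test_picks_smallest_ucl(self):
        ucl = np.array([0.8, 0.5, 0.9, 0.349, 0.356, 0.7, 0.6])
        res = select_criterion_A(make_summary(ucl_sd=ucl))
        assert res.subset == enumerate_subsets(3)[3]
        assert res.metrics["ucl95_sd"] == pytest.approx(0.349)

    def test_single_subset(self):
        subsets = enumerate_subsets(1)
        summary = make_summary(ucl_sd=[0.4], mean_rank=[1.0], j=1)
        assert select_criterion_A(summary).subset == subsets[0]

    def test_tie_prefers_smaller_size(self):
        # sizes are 1,1,1,2,2,2,3 for J=3; tie between index 1 (size 1)
        # and index 4 (size 2)
        ucl = np.array([0.9, 0.5, 0.9, 0.9, 0.5, 0.9, 0.9])
        res = select_criterion_A(make_summary(ucl_sd=ucl))
        assert res.subset.size == 1


class TestCriterionB:
    def test_threshold_selects_smallest_qualifying_size(self):
        ucl = np.array([0.60, 0.70, 0.80, 0.54, 0.52, 0.58, 0.50])
        res = select_criterion_B(make_summary(ucl_sd=ucl), sd_threshold=0.55)
        assert res.subset.size == 2
        assert res.metrics["ucl95_sd"] == pytest.approx(0.52)
        assert res.status == "ok"

    def test_no_qualifying_subset(self):
        res = select_criterion_B(make_summary(ucl_sd=np.full(7, 0.9)), 0.55)
        assert res.subsets == []
        assert "no subset" in res.status

    def test_threshold_above_all_gives_best_single_gene(self):
        ucl = np.array([0.3, 0.2, 0.4, 0.1, 0.1, 0.1, 0.05])
        res = select_criterion_B(make_summary(ucl_sd=ucl), sd_threshold=10.0)
        assert res.subset.size == 1
        assert res.subset.genes == (1,)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="positive"):
            select_criterion_B(make_summary(), 0.0)


class TestCriterionC:
    def test_picks_smallest_mean_rank(self):
        mr = np.array([6.4, 9.0, 8.8, 3.2, 1.2, 4.7, 2.0])
        res = select_criterion_C(make_summary(mean_rank=mr))
        assert res.subset == enumerate_subsets(3)[4]
        assert res.metrics["mean_rank"] == pytest.approx(1.2)

    def test_matches_argmin_oracle(self, rng):
        mr = rng.uniform(1, 7, size=7)
        res = select_criterion_C(make_summary(mean_rank=mr))
        assert res.subset == enumerate_subsets(3)[int(np.argmin(mr))]

    def test_all_equal_picks_first_canonical(self):
        res = select_criterion_C(make_summary(mean_rank=np.full(7, 4.0)))
        assert res.subset == enumerate_subsets(3)[0]


class TestPlotData:
    def test_double_argmin_has_distance_zero(self):
        ucl = np.array([0.9, 0.8, 0.7, 0.3, 0.6, 0.5, 0.4])
        mr = np.array([7.0, 6.0, 5.0, 1.0, 4.0, 3.0, 2.0])
        tab = ucl_vs_rank_plotdata(make_summary(ucl_sd=ucl, mean_rank=mr))
        assert tab.loc[0, "normalized_distance"] == pytest.approx(0.0)
        assert tab.loc[0, "subset"] == "110"  # canonical index 3 = genes {1,2}
        assert len(tab) == 7

    def test_two_subsets_hand_distance(self):
        summary = make_summary(ucl_sd=[0.4], mean_rank=[1.0], j=1)
        tab = ucl_vs_rank_plotdata(summary)
        assert tab.loc[0, "normalized_distance"] == pytest.approx(0.0)

    def test_hand_minmax_euclid(self):
        # three subsets of J=3 used; distances checked by hand after
        # min-max scaling: point (mid, mid) -> hypot(0.5, 0.5)
        ucl = np.array([0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        mr = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        tab = ucl_vs_rank_plotdata(make_summary(ucl_sd=ucl, mean_rank=mr))
        mid = tab[tab["subset"] == "110"]["normalized_distance"].iloc[0]
        assert mid == pytest.approx(np.hypot(0.5, 0.5))

    def test_rank_cutoff_filters(self):
        tab = ucl_vs_rank_plotdata(make_summary(), rank_cutoff=4.0)
        assert (tab["mean_rank"] < 4.0).all()
        assert len(tab) == 3


class TestReports:
    def test_top_by_size_contains_criterion_A_choice(self, random_log_matrix):
        summary = bootstrap_selection(random_log_matrix, B=100, seed=5)
        res = select_criterion_A(summary)
        best = top_subsets_by_size(summary)
        row = best[best["size"] == res.subset.size]
        indicator = "".join(
            str(int(row[g].iloc[0])) for g in random_log_matrix.gene_ids
        )
        assert indicator == res.subset.indicator_string()

    def test_top_by_rank_shape(self, random_log_matrix):
        summary = bootstrap_selection(random_log_matrix, B=50, seed=5)
        top = top_subsets_by_rank(summary, n=10)
        assert len(top) == 10
        assert top["mean_rank"].is_monotonic_increasing
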