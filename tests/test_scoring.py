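import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnchain import (
    ActivityScoreSet,
    ExpressionDataset,
    FitReport,
    IncidenceMatrixSet,
    activity_matrix,
    activity_score,
    dissimilarity_table,
    drop_poor_targets,
    filter_regulons,
    minmax_tv,
    normalize_weights,
    score_distribution,
    total_variation,
)


class TestNormalizeWeights:
    def test_column_halved_by_norm_two(self):
        W = np.array([[1.0, 4.0], [3.0, 0.0]])
        Y = np.array([[2.0, 3.0], [0.0, 4.0]])  # norms [2, 5]
        nw = normalize_weights(W, Y)
        np.testing.assert_allclose(nw.W_hat, [[0.5, 0.8], [1.5, 0.0]])

    def test_homogeneity_in_target_scale(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 4))
        Y = rng.gamma(2, 2, size=(10, 4))
        a = normalize_weights(W, Y).W_hat
        b = normalize_weights(W, 10.0 * Y).W_hat
        np.testing.assert_allclose(b, a / 10.0)

    def test_zero_norm_target_zeroed_with_warning(self):
        W = np.ones((2, 2))
        Y = np.zeros((3, 2))
        Y[:, 0] = 1.0
        with pytest.warns(UserWarning, match="zero-norm"):
            nw = normalize_weights(W, Y)
        np.testing.assert_allclose(nw.W_hat[:, 1], 0.0)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            normalize_weights(np.ones((2, 3)), np.ones((5, 2)))


class TestActivityScore:
    def test_single_target_scores_one(self):
        assert activity_score([7.0], [0.4]) == pytest.approx(1.0)

    def test_equal_weights_closed_form(self):
        # any ordering; T=3 -> (T+1)/(2T) = 2/3
        assert activity_score([3.0, 1.0, 2.0], [0.5, 0.5, 0.5]) == pytest.approx(2 / 3)

    def test_one_hot_best_and_worst_rank(self):
        # weight-1 target most expressed -> 1.0; least expressed -> 1/3
        assert activity_score([10.0, 1.0, 2.0], [1.0, 0.0, 0.0]) == pytest.approx(1.0)
        assert activity_score([0.5, 1.0, 2.0], [1.0, 0.0, 0.0]) == pytest.approx(1 / 3)

    def test_empty_regulon_returns_nan(self):
        assert np.isnan(activity_score([1.0, 2.0], [0.0, 0.0]))

    def test_ascending_flag_reverses_extremes(self):
        assert activity_score([10.0, 1.0, 2.0], [1.0, 0.0, 0.0], ascending=True) == pytest.approx(
            1 / 3
        )

    @given(
        st.lists(st.floats(0.1, 100.0), min_size=2, max_size=8, unique=True),
        st.floats(0.5, 20.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_invariant_to_rank_preserving_rescaling(self, expr, scale):
        rng = np.random.default_rng(len(expr))
        w = rng.uniform(0.1, 2.0, size=len(expr))
        a = activity_score(np.array(expr), w)
        b = activity_score(scale * np.array(expr), w)
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0


def _two_state_dataset_with_flip():
    """1-hot regulon; state B reverses the target-expression ranking of state A."""
    drivers = ["TF0"]
    targets = ["G0", "G1", "G2"]
    # state A cells express G0 most; state B cells express G0 least
    Y_A = np.array([[10.0, 2.0, 1.0], [9.0, 2.0, 1.0]])
    Y_B = np.array([[0.5, 2.0, 9.0], [0.4, 2.0, 10.0]])
    X = np.ones((2, 1))
    matrix = np.vstack(
        [np.vstack([X, X]).T, np.vstack([Y_A, Y_B]).T]
    )
    cells = ["a1", "a2", "b1", "b2"]
    ds = ExpressionDataset(
        matrix=matrix,
        gene_ids=drivers + targets,
        cell_ids=cells,
        phenotype_of_cell={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        phenotype_order=["A", "B"],
        driver_ids=drivers,
        target_ids=targets,
    )
    W = np.zeros((2, 3))
    W[0, 0] = 1.0  # TF0 -> G0 only
    W_set = IncidenceMatrixSet([W, W.copy()], drivers, targets, ["A", "B"], 0.0, 0.0)
    return ds, W_set


class TestActivityMatrix:
    def test_scores_flip_between_states(self):
        ds, W_set = _two_state_dataset_with_flip()
        act = activity_matrix(ds, W_set)
        a = act.scores["A"]["TF0"].to_numpy()
        b = act.scores["B"]["TF0"].to_numpy()
        np.testing.assert_allclose(a, 1.0)
        np.testing.assert_allclose(b, 1 / 3)

    def test_all_entries_in_unit_interval(self):
        from conftest import make_dataset
        from grnchain import SolverConfig, fit_joint_grns

        ds, _ = make_dataset(m=4, n=5, cells_per_state=30, K=2, seed=20)
        W_set, _ = fit_joint_grns(ds, 0.01, 0.01, SolverConfig())
        act = activity_matrix(ds, W_set)
        for ph in ds.phenotype_order:
            vals = act.scores[ph].to_numpy()
            ok = vals[~np.isnan(vals)]
            assert np.all((ok >= 0.0) & (ok <= 1.0))

    def test_duplicated_cell_gets_identical_scores(self):
        ds, W_set = _two_state_dataset_with_flip()
        act = activity_matrix(ds, W_set)
        # a1 and a2 have identical ranking -> identical 1-hot regulon scores
        assert act.scores["A"].loc["a1", "TF0"] == act.scores["A"].loc["a2", "TF0"]


class TestFilterRegulons:
    def _wset(self, col):
        W = np.zeros((len(col) + 1, 1))
        W[:-1, 0] = col
        return IncidenceMatrixSet(
            [W], [f"d{i}" for i in range(len(col))], ["t0"], ["A"], 0.0, 0.0
        )

    def test_hand_cumulative_case(self):
        # squared [9,1,1,1]: shares 0.75, 0.833, 0.917 -> keep 3 drivers
        filt = filter_regulons(self._wset([3.0, 1.0, 1.0, 1.0]), 0.9)
        assert filt.driver_mask["A"][:, 0].sum() == 3

    def test_single_nonzero_driver_kept_exactly(self):
        filt = filter_regulons(self._wset([0.0, 2.0, 0.0]), 0.9)
        np.testing.assert_array_equal(filt.driver_mask["A"][:, 0], [False, True, False])

    def test_ten_equal_weights_keep_nine(self):
        filt = filter_regulons(self._wset([1.0] * 10), 0.9)
        assert filt.driver_mask["A"][:, 0].sum() == 9

    def test_kept_set_grows_with_variance_fraction(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=8)
        small = filter_regulons(self._wset(col), 0.5).driver_mask["A"]
        large = filter_regulons(self._wset(col), 0.95).driver_mask["A"]
        assert np.all(large[small])  # superset

    def test_all_zero_column_gives_empty_set(self):
        filt = filter_regulons(self._wset([0.0, 0.0]), 0.9)
        assert filt.driver_mask["A"][:, 0].sum() == 0


class TestDropPoorTargets:
    def _report(self, r2):
        rep = FitReport(objective_trace=[], converged=True, n_epochs=0)
        rep.adjusted_r2_pooled = pd.Series(r2, index=[f"t{i}" for i in range(len(r2))])
        return rep

    def test_threshold_at_0_7_keeps_boundary(self):
        mask = drop_poor_targets(self._report([0.9, 0.69, 0.7]))
        np.testing.assert_array_equal(mask, [True, False, True])

    def test_threshold_zero_keeps_non_negative(self):
        mask = drop_poor_targets(self._report([0.5, -0.1, 0.0]), threshold=0.0)
        np.testing.assert_array_equal(mask, [True, False, True])

    def test_all_poor_warns_and_empties(self):
        with pytest.warns(UserWarning, match="threshold"):
            mask = drop_poor_targets(self._report([0.1, 0.2]))
        assert not mask.any()


class TestDistributions:
    def test_point_mass_two_bins(self):
        d = score_distribution([0.5, 0.5, 0.5], n_bins=2)
        np.testing.assert_allclose(d.probabilities, [0.0, 1.0])

    def test_uniform_grid_fills_bins_evenly(self):
        scores = (np.arange(100) + 0.5) / 100.0
        d = score_distribution(scores, n_bins=10)
        np.testing.assert_allclose(d.probabilities, 0.1)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = score_distribution(rng.random(137), n_bins=100)
        assert d.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            score_distribution([])

    def test_tv_identical_zero_and_disjoint_one(self):
        p = score_distribution([0.1] * 5, n_bins=4)
        q = score_distribution([0.9] * 5, n_bins=4)
        assert total_variation(p, p) == 0.0
        assert total_variation(p, q) == pytest.approx(1.0)

    def test_tv_hand_value(self):
        from grnchain import ScoreDistribution

        P = ScoreDistribution(np.array([0.0, 0.5, 1.0]), np.array([0.5, 0.5]))
        Q = ScoreDistribution(np.array([0.0, 0.5, 1.0]), np.array([0.75, 0.25]))
        assert total_variation(P, Q) == pytest.approx(0.25)

    def test_mismatched_bins_is_error(self):
        p = score_distribution([0.5], n_bins=4)
        q = score_distribution([0.5], n_bins=5)
        with pytest.raises(ValueError):
            total_variation(p, q)

    def test_minmax_tv_degenerates_to_tv_for_two(self):
        """Over 1000 random distribution pairs the two metrics agree to 1e-12."""
        from grnchain import ScoreDistribution

        rng = np.random.default_rng(42)
        edges = np.linspace(0, 1, 21)
        for _ in range(1000):
            a = rng.dirichlet(np.ones(20))
            b = rng.dirichlet(np.ones(20))
            P, Q = ScoreDistribution(edges, a), ScoreDistribution(edges, b)
            assert abs(minmax_tv([P, Q]) - total_variation(P, Q)) < 1e-12

    def test_minmax_tv_identical_and_disjoint(self):
        from grnchain import ScoreDistribution

        edges = np.linspace(0, 1, 4)
        same = ScoreDistribution(edges, np.array([0.2, 0.3, 0.5]))
        assert minmax_tv([same, same, same]) == 0.0
        hots = [
            ScoreDistribution(edges, np.eye(3)[i]) for i in range(3)
        ]
        assert minmax_tv(hots) == pytest.approx(1.0)

    def test_minmax_tv_needs_two(self):
        p = score_distribution([0.5], n_bins=4)
        with pytest.raises(ValueError):
            minmax_tv([p])


class TestDissimilarityTable:
    def _act(self, a_scores, b_scores, cells_a=None, cells_b=None):
        cells_a = cells_a or [f"a{i}" for i in range(len(a_scores))]
        cells_b = cells_b or [f"b{i}" for i in range(len(b_scores))]
        return ActivityScoreSet(
            scores={
                "A": pd.DataFrame({"TF0": a_scores}, index=cells_a),
                "B": pd.DataFrame({"TF0": b_scores}, index=cells_b),
            },
            phenotype_order=["A", "B"],
        )

    def test_identical_distributions_give_zero(self):
        act = self._act([0.2, 0.8], [0.2, 0.8])
        table = dissimilarity_table(act).table
        assert table.shape == (1, 1)
        assert table.loc["TF0", "all"] == pytest.approx(0.0)

    def test_flipped_regulon_near_one(self):
        ds, W_set = _two_state_dataset_with_flip()
        act = activity_matrix(ds, W_set)
        table = dissimilarity_table(act).table
        assert table.loc["TF0", "all"] == pytest.approx(1.0)

    def test_empty_cluster_in_one_phenotype_is_missing(self):
        act = self._act([0.2, 0.8], [0.3, 0.7])
        clusters = {"a0": "c1", "a1": "c1", "b0": "c1", "b1": "c2"}  # c2 absent in A
        with pytest.warns(UserWarning, match="no cells"):
            table = dissimilarity_table(act, clusters).table
        assert np.isnan(table.loc["TF0", "c2"])
        assert not np.isnan(table.loc["TF0", "c1"])

    def test_values_bounded_and_shape(self):
        rng = np.random.default_rng(1)
        act = ActivityScoreSet(
            scores={
                "A": pd.DataFrame(
                    rng.random((30, 3)), columns=["TF0", "TF1", "TF2"],
                    index=[f"a{i}" for i in range(30)],
                ),
                "B": pd.DataFrame(
                    rng.random((30, 3)), columns=["TF0", "TF1", "TF2"],
                    index=[f"b{i}" for i in range(30)],
                ),
            },
            phenotype_order=["A", "B"],
        )
        table = dissimilarity_table(act).table
        assert table.shape == (3, 1)
        assert ((table >= 0) & (table <= 1)).all().all()
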