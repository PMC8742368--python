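"""ANOVA filter and rMLTFL: proximal operator, objective, optimizer, pruning."""

import numpy as np
import pytest
from scipy import optimize, stats

from mcistrat.io import TaskName, make_binary_task
from mcistrat.select import (
    MultiBitLabelMatrix,
    MultiTaskFeatureSelector,
    anova_pvalues,
    anova_select,
    build_multibit_labels,
    default_lambda_grid,
    filter_and_refit,
    fit_auxiliary_models,
    grid_search_rmltfl,
    prox_group_l21,
    rmltfl_fit,
    rmltfl_objective,
)

from conftest import jaccard


class TestAnova:
    def test_strong_contrast_is_selected(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(10, 0.1, 50)])[:, None]
        y = np.repeat([-1, 1], 50)
        # textbook between/within decomposition as oracle
        grand = X.mean()
        ssb = sum(50 * (X[y == g].mean() - grand) ** 2 for g in (-1, 1))
        ssw = sum(((X[y == g] - X[y == g].mean()) ** 2).sum() for g in (-1, 1))
        F = (ssb / 1) / (ssw / 98)
        p_oracle = stats.f.sf(F, 1, 98)
        np.testing.assert_allclose(anova_pvalues(X, y)[0], p_oracle, rtol=1e-10)
        assert p_oracle < 0.05

    def test_constant_feature_gets_p_one(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = np.repeat([-1, 1], 10)
        p = anova_pvalues(X, y)
        assert p[0] == 1.0

    def test_two_group_f_equals_squared_t(self, target_task):
        """With two groups the ANOVA p equals the pooled two-sample t-test p."""
        p_anova = anova_pvalues(target_task.X, target_task.y)
        g1 = target_task.X[target_task.y == 1]
        g2 = target_task.X[target_task.y == -1]
        _, p_t = stats.ttest_ind(g1, g2, axis=0, equal_var=True)
        np.testing.assert_allclose(p_anova, p_t, atol=1e-10)

    def test_selection_invariant_to_subject_permutation(self, small_table, rng):
        perm = rng.permutation(small_table.n_subjects)
        a = anova_select(make_binary_task(small_table, TaskName.LMCI_vs_EMCI))
        b = anova_select(make_binary_task(small_table.subset(perm), TaskName.LMCI_vs_EMCI))
        assert a.feature_indices == b.feature_indices

    def test_tiny_group_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            anova_pvalues(X, np.array([1, -1, -1]))


@pytest.fixture(scope="module")
def aux_and_target(small_table):
    target = make_binary_task(small_table, TaskName.LMCI_vs_EMCI)
    aux = [
        make_binary_task(small_table, t)
        for t in (TaskName.AD_vs_NC, TaskName.AD_vs_MCI, TaskName.MCI_vs_NC)
    ]
    return target, fit_auxiliary_models(aux)


class TestMultiBitLabels:
    def test_shape_and_first_column_is_truth(self, aux_and_target):
        target, models = aux_and_target
        Y = build_multibit_labels(target, models)
        assert Y.Y.shape == (target.n_subjects, 4)
        np.testing.assert_array_equal(Y.Y[:, 0], target.y)
        assert np.all(np.isin(Y.Y, (-1, 1)))

    def test_deterministic_refit(self, small_table):
        aux = [make_binary_task(small_table, TaskName.AD_vs_NC)]
        m1, m2 = fit_auxiliary_models(aux)[0], fit_auxiliary_models(aux)[0]
        np.testing.assert_array_equal(m1.coef_, m2.coef_)

    def test_separable_aux_task_fits_perfectly(self, gaussian_domains):
        src, _ = gaussian_domains
        model = fit_auxiliary_models([src])[0]
        assert model.score(src.X, src.y) == 1.0

    def test_permuted_labels_give_chance_training_accuracy(self, rng):
        # wide-n narrow-d table so overfitting cannot inflate training accuracy
        from mcistrat.synthetic import AdniLikeSpec, make_adni_like

        table = make_adni_like(
            AdniLikeSpec(n_per_class=(20, 160, 130, 20), dim=8, n_informative=3, seed=4)
        )
        task = make_binary_task(table, TaskName.LMCI_vs_EMCI)
        y_perm = rng.permutation(task.y)
        from sklearn.linear_model import LogisticRegression

        acc = LogisticRegression(max_iter=2000).fit(task.X, y_perm).score(
            task.X, y_perm
        )
        majority = max((y_perm == 1).mean(), (y_perm == -1).mean())
        assert abs(acc - majority) <= 0.10

    def test_dimension_mismatch_rejected(self, aux_and_target, small_table):
        target, models = aux_and_target
        narrow = make_binary_task(small_table.select_features(range(5)), TaskName.LMCI_vs_EMCI)
        with pytest.raises(ValueError, match="features"):
            build_multibit_labels(narrow, models)


class TestProx:
    @pytest.mark.parametrize(
        "row,thr,expected",
        [
            ([0.3, 0.4], 1.0, [0.0, 0.0]),  # inside the ball: shrink to zero
            ([3.0, 4.0], 1.0, [2.4, 3.2]),  # closed-form scaling by 4/5
            ([3.0, 4.0], 0.0, [3.0, 4.0]),  # no penalty: identity
        ],
    )
    def test_closed_form_rows(self, row, thr, expected):
        out = prox_group_l21(np.array([row]), thr, axis="rows")
        np.testing.assert_allclose(out[0], expected)

    def test_matches_numeric_minimizer_on_3x3(self, rng):
        """prox is the exact minimizer of (1/2)||Z - M||^2 + t * sum ||row||."""
        M = rng.normal(size=(3, 3))
        t = 0.7
        out = prox_group_l21(M, t, axis="rows")

        def objective(z):
            Z = z.reshape(3, 3)
            return 0.5 * np.sum((Z - M) ** 2) + t * np.linalg.norm(Z, axis=1).sum()

        res = optimize.minimize(objective, M.ravel(), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert objective(out.ravel()) <= res.fun + 1e-9

    def test_column_axis_transposes_grouping(self, rng):
        M = rng.normal(size=(4, 3))
        np.testing.assert_allclose(
            prox_group_l21(M, 0.5, axis="columns"),
            prox_group_l21(M.T, 0.5, axis="rows").T,
        )


class TestProxProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        M=arrays(np.float64, (4, 3),
                 elements=st.floats(-10, 10, allow_nan=False)),
        thr=st.floats(0, 5, allow_nan=False),
    )
    def test_prox_shrinks_row_norms_by_exactly_threshold(self, M, thr):
        """Nonzero output rows keep direction and lose exactly thr of norm."""
        out = prox_group_l21(M, thr, axis="rows")
        for m_row, o_row in zip(M, out):
            norm_in = np.linalg.norm(m_row)
            norm_out = np.linalg.norm(o_row)
            if norm_in <= thr:
                assert norm_out == 0.0
            else:
                assert abs(norm_out - (norm_in - thr)) < 1e-9
                # direction preserved
                assert np.dot(m_row, o_row) >= 0


class TestObjective:
    def test_zero_weights_zero_penalties_give_label_norm(self, rng):
        X = rng.normal(size=(10, 4))
        Y = np.where(rng.normal(size=(10, 4)) > 0, 1.0, -1.0)
        from mcistrat.select import WeightDecomposition

        dec = WeightDecomposition(P=np.zeros((4, 4)), Q=np.zeros((4, 4)),
                                  lambda1=0, lambda2=0, lambda3=0)
        np.testing.assert_allclose(rmltfl_objective(X, Y, dec), np.sum(Y**2))

    def test_matches_term_by_term_recomputation(self, rng):
        """Independent re-implementation of the four-term sum as oracle."""
        n, d, T = 12, 5, 4
        X = rng.normal(size=(n, d))
        Y = np.where(rng.normal(size=(n, T)) > 0, 1.0, -1.0)
        P, Q = rng.normal(size=(d, T)), rng.normal(size=(d, T))
        l1, l2, l3 = 0.3, 0.7, 1.3
        from mcistrat.select import WeightDecomposition

        dec = WeightDecomposition(P=P, Q=Q, lambda1=l1, lambda2=l2, lambda3=l3)
        W = P + Q
        expected = np.linalg.norm(Y - X @ W, "fro") ** 2
        expected += l1 * sum(np.linalg.norm(P[j]) for j in range(d))
        expected += l2 * sum(np.linalg.norm(Q[:, t]) for t in range(T))
        for i in range(1, T):
            expected += l3 * np.sum(
                ((X @ W[:, 0] - X @ W[:, i]) - (Y[:, 0] - Y[:, i])) ** 2
            )
        np.testing.assert_allclose(rmltfl_objective(X, Y, dec), expected, rtol=1e-12)


class TestFit:
    def test_zero_penalty_matches_least_squares(self, rng):
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 4))
        dec = rmltfl_fit(X, Y, (0, 0, 0), max_iter=5000, tol=1e-14)
        W_ls, *_ = np.linalg.lstsq(X, Y, rcond=None)
        obj_ls = np.sum((Y - X @ W_ls) ** 2)
        assert dec.objective <= obj_ls * (1 + 1e-6)

    def test_huge_lambda1_kills_all_features(self, rng):
        X = rng.uniform(size=(40, 10))
        Y = np.where(rng.normal(size=(40, 4)) > 0, 1.0, -1.0)
        dec = rmltfl_fit(X, Y, (1e8, 0.0, 0.0), max_iter=300)
        assert np.allclose(dec.P, 0)
        assert not dec.selected_features.any()

    def test_best_iterate_objective_non_increasing(self, rng):
        X = rng.uniform(size=(60, 20))
        Y = np.where(rng.normal(size=(60, 4)) > 0, 1.0, -1.0)
        dec = rmltfl_fit(X, Y, (0.5, 0.5, 0.5), max_iter=400)
        trace = np.array(dec.objective_trace)
        assert np.all(np.diff(trace) <= 1e-10)
        assert dec.objective <= trace[0]

    def test_recovers_planted_row_sparse_support(self):
        """Group-sparse recovery of a planted 10-row support (fixed seed)."""
        rng = np.random.default_rng(42)
        n, d = 200, 116
        X = rng.normal(size=(n, d))
        X -= X.mean(0)
        P_true = np.zeros((d, 4))
        P_true[:10] = rng.normal(scale=1.0, size=(10, 4))
        Y = X @ P_true + 0.5 * rng.normal(size=(n, 4))
        best_j = 0.0
        for lam1 in (50.0, 100.0, 200.0):  # calibrated grid; lambda2 parks Q at 0
            dec = rmltfl_fit(X, Y, (lam1, 1e4, 0.0), max_iter=2000, tol=1e-10)
            sel = np.flatnonzero(dec.selected_features)
            best_j = max(best_j, jaccard(sel, range(10)))
        assert best_j >= 0.8

    def test_nonconvergence_flagged_not_raised(self, rng):
        X = rng.uniform(size=(30, 10))
        Y = np.where(rng.normal(size=(30, 4)) > 0, 1.0, -1.0)
        dec = rmltfl_fit(X, Y, (0.1, 0.1, 0.1), max_iter=2, tol=1e-16)
        assert dec.converged is False

    def test_negative_lambda_rejected(self, rng):
        with pytest.raises(ValueError):
            rmltfl_fit(rng.normal(size=(5, 2)), rng.normal(size=(5, 2)), (-1, 0, 0))


def _pruning_instance(seed):
    """Shared + private signal aux domains, one coin-flip domain."""
    rng = np.random.default_rng(seed)
    n, d = 300, 30
    X = rng.normal(size=(n, d))
    X -= X.mean(0)
    shared = X[:, :8] @ rng.normal(size=8)
    priv1 = X[:, 8:12] @ (rng.normal(size=4) + 1.0)
    priv2 = X[:, 12:16] @ (rng.normal(size=4) + 1.0)
    yt = np.where(shared + 0.5 * rng.normal(size=n) > 0, 1.0, -1.0)
    y1 = np.where(0.5 * shared + priv1 + 0.3 * rng.normal(size=n) > 0, 1.0, -1.0)
    y2 = np.where(0.5 * shared + priv2 + 0.3 * rng.normal(size=n) > 0, 1.0, -1.0)
    y3 = rng.choice([-1.0, 1.0], size=n)
    return X, np.column_stack([yt, y1, y2, y3])


PRUNING_LAMBDAS = (150.0, 250.0, 0.1)  # calibrated for the instance above


class TestDomainPruning:
    def test_coin_flip_domain_is_pruned_in_most_seeds(self):
        pruned = kept = 0
        for seed in range(25):
            X, Y = _pruning_instance(seed)
            res = MultiTaskFeatureSelector(X, Y, PRUNING_LAMBDAS).fit(
                max_iter=1500, tol=1e-9
            )
            pruned += not res.retained_domains[2]
            kept += res.retained_domains[0] and res.retained_domains[1]
        assert pruned >= 20  # >= 80% of seeds
        assert kept >= 20

    def test_no_zero_columns_means_refit_is_first_fit(self):
        X, Y = _pruning_instance(0)
        res = MultiTaskFeatureSelector(X, Y[:, :3], (10.0, 1.0, 0.1)).fit(
            max_iter=800, tol=1e-9
        )
        if res.retained_domains.all():
            np.testing.assert_array_equal(res.first_fit.P, res.final_fit.P)

    def test_pruned_domain_shrinks_refit_width(self):
        X, Y = _pruning_instance(3)
        res = MultiTaskFeatureSelector(X, Y, PRUNING_LAMBDAS).fit(max_iter=1500, tol=1e-9)
        expected_cols = 1 + int(res.retained_domains.sum())
        assert res.final_fit.Q.shape[1] == expected_cols


class TestGridSearch:
    def test_degenerate_grid_reduces_to_filter_and_refit(self, rng):
        X, Y = _pruning_instance(1)
        Ym = MultiBitLabelMatrix(
            Y=Y, column_tasks=("target", "aux1", "aux2", "aux3")
        )
        res = grid_search_rmltfl(X, Ym, [PRUNING_LAMBDAS], k_folds=3, seed=0)
        assert res.hyperparameters["lambda1"] == PRUNING_LAMBDAS[0]
        assert res.feature_indices == sorted(
            {i for fold in res.per_fold_indices for i in fold}
        )

    def test_default_grid_has_1000_combinations(self):
        assert len(default_lambda_grid()) == 1000

    def test_empty_grid_rejected(self, rng):
        X, Y = _pruning_instance(2)
        Ym = MultiBitLabelMatrix(Y=Y, column_tasks=("t", "a", "b", "c"))
        with pytest.raises(ValueError, match="empty"):
            grid_search_rmltfl(X, Ym, [], k_folds=3)
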