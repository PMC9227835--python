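"""Method contracts and oracle identities for the six procedures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metabobench import (
    MethodOutput,
    bh_select,
    bonferroni_select,
    lasso_fit,
    pcr_importance,
    rf_importance,
    run_method,
    spls_fit,
    splsda_fit,
    top_k,
    tune_sparse,
    univariate_scan,
)
from metabobench.methods import (
    _lasso_alpha_grid,
    _spls_core,
    batched_permutation_importance,
)


def _centered_orthonormal(n, m, seed=0):
    a = np.random.default_rng(seed).standard_normal((n, m))
    a -= a.mean(axis=0)
    q, _ = np.linalg.qr(a)
    return q


class TestUnivariateScan:
    def test_perfect_linear_fit_gives_zero_pvalue(self, rng):
        x = rng.standard_normal((60, 4))
        p, coef = univariate_scan(x, x[:, 2].copy())
        assert p[2] < 1e-12
        assert abs(coef[2] - 1.0) < 1e-10

    def test_null_pvalues_uniform(self, rng):
        # independent null columns: each p-value is one draw from the null
        x = rng.standard_normal((100, 1000))
        p, _ = univariate_scan(x, rng.standard_normal(100))
        d, _ = stats.kstest(p, "uniform")
        assert d < 0.06

    def test_orthogonal_covariate_leaves_pvalues_stable(self, rng):
        n = 800
        x = rng.standard_normal((n, 10))
        y = x[:, 0] * 0.5 + rng.standard_normal(n)
        # covariate orthogonalized against X and y
        c = rng.standard_normal(n)
        basis = np.column_stack([x, y, np.ones(n)])
        c -= basis @ np.linalg.lstsq(basis, c, rcond=None)[0]
        p0, _ = univariate_scan(x, y)
        p1, _ = univariate_scan(x, y, adjust_covariates=c)
        # relative comparison is meaningless below numerical zero
        np.testing.assert_allclose(
            np.maximum(p1, 1e-12), np.maximum(p0, 1e-12), rtol=0.1
        )

    def test_constant_column_gets_unit_pvalue(self, rng):
        x = rng.standard_normal((50, 3))
        x[:, 1] = 2.0
        p, coef = univariate_scan(x, rng.standard_normal(50))
        assert p[1] == 1.0 and coef[1] == 0.0

    def test_logistic_scan_flags_separation_conservatively(self, rng):
        x = rng.standard_normal((40, 2))
        y = (x[:, 0] > 0).astype(float)  # perfectly separated by column 0
        p, _ = univariate_scan(x, y, outcome_type="binary")
        assert p[0] == 1.0

    def test_logistic_scan_detects_real_effect(self, rng):
        x = rng.standard_normal((300, 5))
        lp = 1.0 * x[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-lp))).astype(float)
        p, coef = univariate_scan(x, y, outcome_type="binary")
        assert p[1] < 1e-4 and coef[1] > 0

    def test_linear_probability_variant(self, rng):
        x = rng.standard_normal((200, 4))
        y = (x[:, 0] + rng.standard_normal(200) > 0).astype(float)
        p, _ = univariate_scan(x, y, outcome_type="binary", binary_model="linear")
        assert p[0] < 1e-6


class TestMultiplicityCorrections:
    def test_bonferroni_hand_example(self):
        p = np.array([1e-4, 0.01] + [1.0] * 198)
        assert list(bonferroni_select(p, 0.05)) == [0]

    def test_bh_step_up_hand_example(self):
        assert list(bh_select(np.array([0.001, 0.010, 0.020, 0.900]), 0.1)) == [0, 1, 2]
        assert list(bh_select(np.array([0.05]), 0.1)) == [0]
        assert len(bh_select(np.ones(20), 0.1)) == 0

    def test_bh_matches_naive_step_up(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            q = 0.1
            # independent oracle: literal step-up rule
            order = np.argsort(p)
            ks = [k for k in range(1, len(p) + 1) if p[order[k - 1]] <= q * k / len(p)]
            expected = sorted(order[: max(ks)]) if ks else []
            assert list(bh_select(p, q)) == expected

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_bonferroni_subset_of_bh(self, pvals):
        p = np.array(pvals)
        assert set(bonferroni_select(p, 0.05)) <= set(bh_select(p, 0.05))


class TestPCR:
    def test_full_components_recover_ols_importance(self, rng):
        x = rng.standard_normal((100, 8))
        y = x @ rng.normal(size=8) + rng.normal(size=100)
        out = pcr_importance(x, y, n_components=8)
        xc = np.column_stack([np.ones(100), x])
        ols = np.linalg.lstsq(xc, y, rcond=None)[0][1:]
        np.testing.assert_allclose(out.scores, np.abs(ols), atol=1e-8)
        assert out.selected is None

    def test_single_component_tracks_dominant_direction(self, rng):
        x = rng.standard_normal((200, 5))
        x[:, 3] *= 10.0  # dominant variance direction
        y = x[:, 3] + 0.1 * rng.standard_normal(200)
        out = pcr_importance(x, y, n_components=1)
        assert top_k(out.scores, 1)[0] == 3

    def test_component_range_validated(self, rng):
        x = rng.standard_normal((20, 5))
        with pytest.raises(ValueError):
            pcr_importance(x, x[:, 0], n_components=25)


class TestLasso:
    def test_orthonormal_soft_threshold_closed_form(self):
        q = _centered_orthonormal(50, 10, seed=3)
        rng = np.random.default_rng(4)
        y = q @ rng.normal(size=10) + 0.05 * rng.standard_normal(50)
        lam = 0.003
        out = lasso_fit(q, y, lam=lam)
        ols = q.T @ (y - y.mean())
        expected = np.abs(np.maximum(np.abs(ols) - lam * 50, 0.0))
        np.testing.assert_allclose(out.scores, expected, atol=1e-6)

    def test_zero_penalty_equals_ols(self, rng):
        x = rng.standard_normal((60, 5))
        y = x @ np.arange(1.0, 6.0) + rng.standard_normal(60)
        out = lasso_fit(x, y, lam=0.0)
        ols = np.linalg.lstsq(np.column_stack([np.ones(60), x]), y, rcond=None)[0][1:]
        np.testing.assert_allclose(out.scores, np.abs(ols), atol=1e-6)

    def test_dominating_penalty_empties_selection(self, rng):
        x = rng.standard_normal((40, 6))
        y = x[:, 0] + rng.standard_normal(40)
        out = lasso_fit(x, y, lam=100.0)
        assert len(out.selected) == 0 and np.all(out.scores == 0)

    def test_selection_monotone_along_decreasing_path(self, rng):
        x = rng.standard_normal((80, 12))
        y = x[:, :3] @ np.array([1.0, 0.7, 0.5]) + rng.standard_normal(80)
        sizes = [
            len(lasso_fit(x, y, lam=a).selected)
            for a in sorted(_lasso_alpha_grid(x, y, 15))[::-1]
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_negative_penalty_rejected(self, rng):
        x = rng.standard_normal((20, 3))
        with pytest.raises(ValueError):
            lasso_fit(x, x[:, 0], lam=-1.0)

    def test_logistic_lasso_selects_discriminating_feature(self, rng):
        x = rng.standard_normal((200, 10))
        y = (x[:, 4] + 0.3 * rng.standard_normal(200) > 0).astype(float)
        out = lasso_fit(x, y, outcome_type="binary", lam=0.01)
        assert 4 in out.selected

    def test_unpenalized_covariate_absorbs_its_signal(self, rng):
        x = rng.standard_normal((150, 8))
        batch = rng.standard_normal(150)
        y = x[:, 0] + 2.0 * batch + 0.3 * rng.standard_normal(150)
        out = lasso_fit(x, y, lam=0.05, adjust_covariates=batch)
        assert 0 in out.selected


class TestSPLS:
    def test_eta_zero_single_component_is_dense_pls_direction(self, rng):
        x = rng.standard_normal((80, 12))
        y = x @ rng.normal(size=12) + rng.standard_normal(80)
        out = spls_fit(x, y, eta=0.0, n_components=1)
        assert len(out.selected) == 12
        xc = x - x.mean(axis=0)
        z = xc.T @ (y - y.mean())  # dense first PLS direction ∝ X'y
        coef = np.where(out.scores > 0, out.scores, 0.0) * np.sign(z)
        cos = coef @ z / (np.linalg.norm(coef) * np.linalg.norm(z))
        assert cos > 1 - 1e-8

    def test_extreme_eta_keeps_only_max_covariance_feature(self, rng):
        x = rng.standard_normal((60, 9))
        y = x @ rng.normal(size=9) + rng.standard_normal(60)
        out = spls_fit(x, y, eta=0.99, n_components=1)
        z = (x - x.mean(0)).T @ (y - y.mean())
        assert list(out.selected) == [int(np.argmax(np.abs(z)))]

    def test_exact_dependence_recovered(self, rng):
        x = rng.standard_normal((70, 10))
        out = spls_fit(x, x[:, 1].copy(), eta=0.9, n_components=1)
        assert list(out.selected) == [1]
        assert abs(out.scores[1] - 1.0) < 1e-8

    def test_support_monotone_nonincreasing_in_eta(self, rng):
        x = rng.standard_normal((80, 15))
        y = x[:, :4] @ np.array([1.0, 0.8, 0.6, 0.4]) + rng.standard_normal(80)
        sizes = [
            len(spls_fit(x, y, eta=e, n_components=1).selected)
            for e in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_orthogonal_response_warns_and_selects_nothing(self):
        x = _centered_orthonormal(30, 4, seed=8)
        y = np.zeros(30)
        with pytest.warns(UserWarning, match="orthogonal"):
            sel, coef = _spls_core(x, y, eta=0.5, n_components=1)
        assert len(sel) == 0

    def test_invalid_eta_rejected(self, rng):
        x = rng.standard_normal((30, 4))
        with pytest.raises(ValueError):
            spls_fit(x, x[:, 0], eta=1.0, n_components=1)


class TestSPLSDA:
    def test_dominant_discriminator_selected(self, rng):
        x = rng.standard_normal((100, 8))
        y = (x[:, 0] > 0).astype(float)
        out = splsda_fit(x, y, eta=0.9, n_components=1)
        assert list(out.selected) == [0]

    def test_eta_zero_is_dense(self, rng):
        x = rng.standard_normal((60, 7))
        y = (x[:, 0] + rng.standard_normal(60) > 0).astype(float)
        out = splsda_fit(x, y, eta=0.0, n_components=1)
        assert len(out.selected) == 7

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((30, 4))
        with pytest.raises(ValueError):
            splsda_fit(x, np.ones(30), eta=0.5, n_components=1)

    def test_label_permutation_kills_enrichment(self, rng):
        x = rng.standard_normal((80, 20))
        y = (x[:, 0] + 0.5 * rng.standard_normal(80) > 0).astype(float)
        hits = 0
        n_perm = 40
        for i in range(n_perm):
            yp = rng.permutation(y)
            out = splsda_fit(x, yp, eta=0.8, n_components=1)
            hits += int(0 in set(out.selected))
        # under permutation the true feature is no better than 1-in-20 baseline
        assert hits / n_perm < 0.3


class TestTuning:
    def test_flat_cv_curve_chooses_sparsest(self, rng):
        # pure-noise outcome: all penalties predict equally badly
        x = rng.standard_normal((80, 10))
        y = rng.standard_normal(80)
        grid = _lasso_alpha_grid(x, y, 10)
        chosen = tune_sparse(x, y, "lasso", lambda_grid=grid, seed=0)
        coef_sizes = {
            a: len(lasso_fit(x, y, lam=a).selected) for a in grid
        }
        assert coef_sizes[chosen["lambda"]] == min(coef_sizes.values())

    def test_dominant_grid_point_wins(self, rng):
        x = rng.standard_normal((120, 6))
        y = x[:, 0] * 2.0 + 0.2 * rng.standard_normal(120)
        # tiny penalty predicts far better than a penalty that kills the signal
        chosen = tune_sparse(x, y, "lasso", lambda_grid=[1e-4, 10.0], seed=0)
        assert chosen["lambda"] == pytest.approx(1e-4)

    def test_singleton_grid_short_circuits(self, rng):
        x = rng.standard_normal((30, 4))
        chosen = tune_sparse(x, x[:, 0], "spls", eta_grid=[0.5], k_grid=[2], seed=0)
        assert chosen == {"eta": 0.5, "n_components": 2}

    def test_empty_grid_rejected(self, rng):
        x = rng.standard_normal((30, 4))
        with pytest.raises(ValueError):
            tune_sparse(x, x[:, 0], "spls", eta_grid=[], k_grid=[], seed=0)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((60, 8))
        y = x[:, 0] + rng.standard_normal(60)
        grid = _lasso_alpha_grid(x, y, 8)
        a = tune_sparse(x, y, "lasso", lambda_grid=grid, seed=3)
        b = tune_sparse(x, y, "lasso", lambda_grid=grid, seed=3)
        assert a == b


class TestRandomForest:
    def test_identical_seed_identical_scores(self, rng):
        x = rng.standard_normal((80, 6))
        y = x[:, 0] + rng.standard_normal(80)
        a = rf_importance(x, y, n_trees=30, seed=5)
        b = rf_importance(x, y, n_trees=30, seed=5)
        assert np.array_equal(a.scores, b.scores)
        assert a.selected is None and np.all(a.scores >= 0)

    def test_strong_signal_tops_importance(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal((150, 10))
            y = x[:, 1] + 0.3 * r.standard_normal(150)
            out = rf_importance(x, y, n_trees=60, seed=seed)
            hits += int(top_k(out.scores, 1)[0] == 1)
        assert hits >= 9

    def test_batched_importance_agrees_with_sklearn(self, rng):
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.inspection import permutation_importance

        x = rng.standard_normal((100, 6))
        y = x[:, 0] + 0.5 * x[:, 3] + 0.3 * rng.standard_normal(100)
        model = RandomForestRegressor(n_estimators=60, random_state=0, n_jobs=1).fit(x, y)
        mine = batched_permutation_importance(model, x, y, "continuous",
                                              n_repeats=20, seed=1)
        ref = permutation_importance(model, x, y, n_repeats=20,
                                     random_state=1, n_jobs=1).importances_mean
        np.testing.assert_allclose(mine, ref, atol=0.05)
        assert np.corrcoef(mine, ref)[0, 1] > 0.99

    def test_binary_forest_runs(self, rng):
        x = rng.standard_normal((80, 5))
        y = (x[:, 0] > 0).astype(float)
        out = rf_importance(x, y, outcome_type="binary", n_trees=30, seed=2)
        assert top_k(out.scores, 1)[0] == 0


class TestRankingAndDispatch:
    def test_top_k_ordering_and_ties(self):
        assert list(top_k(np.array([3.0, 1.0, 2.0]), 2)) == [0, 2]
        assert list(top_k(np.ones(4), 2)) == [0, 1]
        assert sorted(top_k(np.array([3.0, 1.0, 2.0]), 3)) == [0, 1, 2]
        with pytest.raises(ValueError):
            top_k(np.ones(3), 4)

    def test_method_output_selection_contract(self):
        with pytest.raises(ValueError):
            MethodOutput("pcr", np.ones(3), selected=np.array([0]))
        with pytest.raises(ValueError):
            MethodOutput("lasso", np.ones(3))

    def test_dispatcher_covers_all_methods(self, rng):
        x = rng.standard_normal((60, 8))
        y = x[:, 0] + rng.standard_normal(60)
        yb = (y > 0).astype(float)
        for name in ("bonferroni", "fdr", "pcr", "lasso", "spls", "random_forest"):
            opts = {"n_trees": 20} if name == "random_forest" else {
                "eta": 0.8, "n_components": 1} if name == "spls" else {
                "lambda": 0.05} if name == "lasso" else {}
            out = run_method(name, x, y, "continuous", opts)
            assert out.method == name and len(out.scores) == 8
        out = run_method("splsda", x, yb, "binary", {"eta": 0.8, "n_components": 1})
        assert out.method == "splsda"
        with pytest.raises(ValueError):
            run_method("elastic_net", x, y)

    def test_method_output_json_serializable(self, rng):
        import json

        x = rng.standard_normal((40, 5))
        out = run_method("fdr", x, x[:, 0] + rng.standard_normal(40))
        parsed = json.loads(json.dumps(out.to_json_dict()))
        assert parsed["method"] == "fdr" and len(parsed["scores"]) == 5
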