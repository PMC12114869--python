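"""Preprocessing, Kennard-Stone, venetian blinds, PLS, metrics, permutations."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from amberscan import chemometrics as chem


def rank3_spectra(rng, n=30, p=20):
    """Spectra confined to a 3-dimensional subspace (3 pure components)."""
    T = rng.normal(size=(n, 3))
    P = rng.normal(size=(3, p))
    return T @ P


class TestDetrend:
    def test_linear_spectrum_annihilated(self):
        t = np.linspace(0, 1, 50)
        X = np.vstack([3.0 + 2.0 * t, -1.0 + 0.5 * t])
        assert np.allclose(chem.Detrend(order=1).transform(X), 0.0, atol=1e-12)

    def test_constant_spectrum_order_zero(self):
        X = np.full((2, 30), 7.0)
        assert np.allclose(chem.Detrend(order=0).transform(X), 0.0)

    def test_residual_orthogonal_to_polynomial_basis(self, rng):
        X = rng.normal(size=(4, 40))
        out = chem.Detrend(order=2).transform(X)
        t = np.linspace(-1, 1, 40)
        basis = np.vander(t, 3, increasing=True)
        assert np.all(np.abs(out @ basis) < 1e-8)

    def test_order_must_be_below_channel_count(self):
        with pytest.raises(ValueError):
            chem.Detrend(order=5).transform(np.zeros((2, 5)))


class TestSNV:
    def test_rows_standardized(self, rng):
        out = chem.SNV().transform(rng.normal(size=(5, 30)) * 3 + 2)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(3, 25))
        assert np.allclose(chem.SNV().transform(X), chem.SNV().transform(2.5 * X - 7.0))

    def test_matches_rowwise_brute_force(self, rng):
        X = rng.normal(size=(5, 10))
        out = chem.SNV().transform(X)
        for i in range(5):
            row = X[i]
            assert np.allclose(out[i], (row - row.mean()) / row.std(ddof=1))

    def test_zero_variance_row_flagged_with_index(self):
        X = np.vstack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(ValueError, match="rows \\[1\\]"):
            chem.SNV().transform(X)


class TestSavGolDerivative:
    def test_second_derivative_of_quadratic_is_two(self):
        x = np.arange(20.0) ** 2
        out = chem.SavGolDerivative(poly=2, deriv=2, window=5).transform(x[None, :])
        assert np.allclose(out[0, 2:-2], 2.0)

    def test_second_derivative_of_line_is_zero(self):
        x = 3.0 * np.arange(20.0) + 1.0
        out = chem.SavGolDerivative(poly=2, deriv=2, window=5).transform(x[None, :])
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_matches_pointwise_local_polynomial_fit(self, rng):
        x = rng.normal(size=30)
        out = chem.SavGolDerivative(poly=2, deriv=2, window=5).transform(x[None, :])[0]
        t = np.arange(-2.0, 3.0)
        for i in range(30):
            if 2 <= i < 28:  # interior: fit the centered window
                coef = np.polyfit(t, x[i - 2 : i + 3], 2)
                assert out[i] == pytest.approx(2.0 * coef[0], abs=1e-9)
        # ends: fit the terminal window once and evaluate its curvature there
        head = np.polyfit(np.arange(5.0), x[:5], 2)
        tail = np.polyfit(np.arange(5.0), x[-5:], 2)
        for i in (0, 1):
            assert out[i] == pytest.approx(2.0 * head[0], abs=1e-9)
            assert out[29 - i] == pytest.approx(2.0 * tail[0], abs=1e-9)

    def test_derivative_above_poly_rejected(self):
        with pytest.raises(ValueError):
            chem.SavGolDerivative(poly=1, deriv=2).transform(np.zeros((1, 10)))

    def test_even_window_widened_with_warning(self):
        with pytest.warns(UserWarning, match="widened"):
            chem.SavGolDerivative(poly=2, deriv=1, window=4).transform(np.zeros((1, 10)))


class TestMeanCenter:
    def test_calibration_columns_centered(self, rng):
        X = rng.normal(size=(10, 6)) + 5
        mc = chem.MeanCenter().fit(X)
        assert np.all(np.abs(mc.transform(X).mean(axis=0)) <= 1e-12)

    def test_mean_spectrum_maps_to_zero(self, rng):
        X = rng.normal(size=(10, 6))
        mc = chem.MeanCenter().fit(X)
        assert np.allclose(mc.transform(X.mean(axis=0)[None, :]), 0.0)

    def test_validation_block_not_recentered(self, rng):
        Xcal = rng.normal(size=(10, 6))
        Xval = rng.normal(size=(5, 6)) + 3.0  # shifted population
        mc = chem.MeanCenter().fit(Xcal)
        assert np.abs(mc.transform(Xval).mean(axis=0)).max() > 0.5


class TestParsePreprocess:
    def test_default_chain_order(self):
        names = [n for n, _ in chem.parse_preprocess(chem.DEFAULT_PREPROCESS)]
        assert names == ["detrend", "savgol", "snv", "mc"]

    def test_mc_must_be_last(self):
        with pytest.raises(ValueError, match="final"):
            chem.parse_preprocess("mc,snv")

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            chem.parse_preprocess("msc")


def brute_kennard_stone(X, n_cal):
    """Independent greedy max-min loop (no vectorized shortcuts)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    d = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)] for i in range(n)])
    best, pair = -1.0, (0, 0)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best:
                best, pair = d[i, j], (i, j)
    sel = list(pair)
    while len(sel) < n_cal:
        cand_best, cand = -1.0, None
        for k in range(n):
            if k in sel:
                continue
            mind = min(d[k, s] for s in sel)
            if mind > cand_best:
                cand_best, cand = mind, k
        sel.append(cand)
    return sorted(sel)


class TestKennardStone:
    def test_collinear_points_pick_extremes(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        cal, val = chem.kennard_stone(X, 2)
        assert list(cal) == [0, 3] and list(val) == [1, 2]

    def test_third_point_maximizes_min_distance(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        cal, _ = chem.kennard_stone(X, 3)
        assert list(cal) == brute_kennard_stone(X, 3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(9, 4))
        for n_cal in (2, 4, 6):
            cal, val = chem.kennard_stone(X, n_cal)
            assert list(cal) == brute_kennard_stone(X, n_cal)
            assert sorted(set(cal) | set(val)) == list(range(9))

    def test_hundred_sample_split_is_75_25(self, rng):
        X = rng.normal(size=(100, 16))
        plan = chem.make_split(X)
        assert len(plan.calibration) == 75 and len(plan.validation) == 25
        assert len(set(plan.calibration) & set(plan.validation)) == 0
        assert sorted(set(plan.calibration) | set(plan.validation)) == list(range(100))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            chem.kennard_stone(np.zeros((5, 2)), 5)


class TestVenetianBlinds:
    def test_ten_of_ten_is_leave_one_out(self):
        plan = chem.venetian_blinds(10, splits=10, thickness=1)
        for f, (train, test) in enumerate(plan):
            assert list(test) == [f] and len(train) == 9

    def test_partition_contract_n75(self):
        plan = chem.venetian_blinds(75, splits=10, thickness=1)
        sizes = sorted(len(test) for _, test in plan)
        assert set(sizes) <= {7, 8}
        all_test = np.concatenate([test for _, test in plan])
        assert sorted(all_test) == list(range(75))

    def test_hand_traced_thickness_two(self):
        plan = chem.venetian_blinds(12, splits=3, thickness=2)
        expected = [[0, 1, 6, 7], [2, 3, 8, 9], [4, 5, 10, 11]]
        assert [list(test) for _, test in plan] == expected

    def test_too_few_splits_rejected(self):
        with pytest.raises(ValueError):
            chem.venetian_blinds(10, splits=1)


class TestPLSFit:
    def test_exact_recovery_when_y_in_three_component_span(self, rng):
        X = rank3_spectra(rng)
        y = 2.0 * X[:, 3] - 0.5 * X[:, 7] + X[:, 12]
        m = chem.NIRPLSRegressor(n_lv=3, preprocess="mc").fit(X, y)
        assert np.max(np.abs(m.predict(X) - y)) <= 1e-8

    def test_fit_quality_monotone_in_latent_variables(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        r2 = []
        for n_lv in (1, 3, 5, 9):
            m = chem.NIRPLSRegressor(n_lv=n_lv, preprocess="mc").fit(X, y)
            pred = m.predict(X)
            r2.append(1 - ((pred - y) ** 2).sum() / ((y - y.mean()) ** 2).sum())
        assert all(b >= a - 1e-10 for a, b in zip(r2, r2[1:]))

    def test_full_rank_pls_equals_ordinary_least_squares(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        m = chem.NIRPLSRegressor(n_lv=5, preprocess="mc").fit(X, y)
        A = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.allclose(m.predict(X), A @ beta, atol=1e-8)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="no variance"):
            chem.NIRPLSRegressor(n_lv=2).fit(rng.normal(size=(10, 8)), np.ones(10))

    def test_estimator_clones_with_sklearn(self):
        from sklearn.base import clone

        m = chem.NIRPLSRegressor(n_lv=4, preprocess="snv,mc")
        assert clone(m).get_params() == m.get_params()


class TestCrossValidate:
    def test_noise_free_linear_system_has_tiny_rmsecv(self, rng):
        X = rank3_spectra(rng, n=40)
        y = X[:, 2] - 0.3 * X[:, 9]
        m = chem.NIRPLSRegressor(n_lv=3, preprocess="mc")
        rmsecv, r2cv = chem.cross_validate(m, X, y)
        assert rmsecv <= 1e-6 and r2cv >= 1 - 1e-10

    def test_shuffled_response_shows_no_skill(self):
        bad = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 30))
            y = rng.permutation(rng.normal(size=100))
            m = chem.NIRPLSRegressor(n_lv=6, preprocess="mc")
            _, r2cv = chem.cross_validate(m, X, y)
            bad += r2cv > 0.2
        assert bad == 0

    def test_matches_independent_fold_loop(self, rng):
        X = rng.normal(size=(40, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=40) * 0.1
        m = chem.NIRPLSRegressor(n_lv=4, preprocess="mc")
        rmsecv, _ = chem.cross_validate(m, X, y)
        # independent bookkeeping: manual centering + direct PLSRegression
        pred = np.empty(40)
        for train, test in chem.venetian_blinds(40):
            xm, ym = X[train].mean(axis=0), y[train].mean()
            pls = PLSRegression(n_components=4, scale=False).fit(X[train] - xm, y[train] - ym)
            pred[test] = (X[test] - xm) @ pls.coef_.reshape(-1) + ym
        assert rmsecv == pytest.approx(float(np.sqrt(np.mean((pred - y) ** 2))), rel=1e-10)


class TestEvaluate:
    def test_biased_predictions_have_unit_bias_and_rmsep(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8)
        m = chem.NIRPLSRegressor(n_lv=8, preprocess="mc").fit(X, y)
        metrics = chem.evaluate(m, X, y + (-1.0))  # observations shifted down by 1
        assert metrics.pred_bias == pytest.approx(1.0, abs=1e-8)
        assert metrics.rmsep == pytest.approx(1.0, abs=1e-8)

    def test_rpd_identity_to_1e10(self, rng):
        X = rng.normal(size=(40, 10))
        y = X @ rng.normal(size=10) + rng.normal(size=40)
        cal, val = chem.kennard_stone(X, 30)
        m = chem.NIRPLSRegressor(n_lv=5, preprocess="mc").fit(X[cal], y[cal])
        metrics = chem.evaluate(m, X[val], y[val])
        sd = np.std(y[val], ddof=1)
        assert abs(metrics.rpd - sd / metrics.rmsep) < 1e-10

    def test_constant_validation_y_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        y = X @ rng.normal(size=5)
        m = chem.NIRPLSRegressor(n_lv=3, preprocess="mc").fit(X, y)
        with pytest.raises(ValueError, match="RPD undefined"):
            chem.evaluate(m, X[:3], np.full(3, 1.5))


class TestPermutationTest:
    def make_strong(self, rng, n=40, p=24):
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) * 0.5 + rng.normal(size=n) * 0.05
        return X, y

    def test_strong_signal_reaches_minimum_p(self, rng):
        X, y = self.make_strong(rng)
        res = chem.permutation_test(X, y, n_lv=4, preprocess="mc", n_perm=30, seed=5)
        assert res.p_empirical == pytest.approx(1 / 31)
        assert res.p_wilcoxon < 0.01 and res.p_sign < 0.01 and res.p_rand_t < 0.01

    def test_minimum_p_formula_at_200_permutations(self):
        # 200 permutations with zero wins -> 1/201
        assert (1 + 0) / (200 + 1) == pytest.approx(0.004975, abs=1e-6)

    def test_null_response_rarely_significant(self):
        low = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(40, 24))
            y = rng.normal(size=40)
            res = chem.permutation_test(X, y, n_lv=4, preprocess="mc", n_perm=30, seed=seed)
            low += res.p_empirical <= 0.05
        assert low <= 1

    def test_seed_is_mandatory_and_reproducible(self, rng):
        X, y = self.make_strong(rng)
        with pytest.raises(ValueError, match="seed"):
            chem.permutation_test(X, y, n_perm=30)
        a = chem.permutation_test(X, y, n_lv=4, preprocess="mc", n_perm=20, seed=9)
        b = chem.permutation_test(X, y, n_lv=4, preprocess="mc", n_perm=20, seed=9)
        assert np.array_equal(a.permuted_rmsecv, b.permuted_rmsecv)
        assert a.p_empirical == b.p_empirical


class TestSpectraMatrix:
    def test_wavelengths_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            chem.SpectraMatrix(np.zeros((2, 3)), np.array([1.0, 3.0, 2.0]))

    def test_channel_count_must_match(self):
        with pytest.raises(ValueError, match="wavelength"):
            chem.SpectraMatrix(np.zeros((2, 4)), np.array([1.0, 2.0, 3.0]))
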