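"""Item QC, imputation, and exploratory factor analysis."""

import numpy as np
import pandas as pd
import pytest

from ctrlcascade.factors import (
    PrincipalAxisFactorAnalysis,
    crossval_scores,
    factor_scores,
    flag_outliers_mad,
    impute_and_average,
    kmo_bartlett,
    map_criterion,
    match_factors,
    paf_oblimin,
    qc_items,
    retain_loadings,
    tucker_congruence,
    vss_criterion,
)
from ctrlcascade.synthgen import default_ground_truth, simulate_ela_items


class TestQC:
    def test_missingness_rule(self):
        df = pd.DataFrame({
            "bad": [np.nan] * 6 + [1.0, 2.0, 3.0, 4.0],
            "good": np.arange(10, dtype=float),
        })
        kept, report = qc_items(df)
        assert report.removed == {"bad": "missing_gt_50pct"}
        assert list(kept.columns) == ["good"]

    def test_constant_item_removed(self):
        df = pd.DataFrame({"const": np.ones(20), "ok": np.arange(20, dtype=float)})
        _, report = qc_items(df)
        assert report.removed["const"] == "near_zero_variance"

    def test_frequency_ratio_boundary_is_strict(self):
        # 95 zeros / 5 ones: ratio exactly 19 -> retained at the default cut
        x = np.array([0.0] * 95 + [1.0] * 5)
        df = pd.DataFrame({"boundary": x, "ok": np.arange(100, dtype=float)})
        kept, report = qc_items(df, nzv_freq_ratio=19, nzv_unique_cut=0.1)
        assert "boundary" in kept.columns
        # 96/4: ratio 24 > 19 and unique fraction 0.02 < 0.1 -> removed
        df2 = pd.DataFrame({"nzv": np.array([0.0] * 96 + [1.0] * 4),
                            "ok": np.arange(100, dtype=float)})
        _, report2 = qc_items(df2, nzv_freq_ratio=19, nzv_unique_cut=0.1)
        assert report2.removed["nzv"] == "near_zero_variance"

    def test_manual_excludes(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
        _, report = qc_items(df, manual_excludes=["b"])
        assert report.removed == {"b": "manual"}

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        df.loc[:30, "a"] = np.nan
        once, _ = qc_items(df)
        twice, report = qc_items(once)
        assert list(once.columns) == list(twice.columns)
        assert not report.removed

    def test_all_removed_errors(self):
        df = pd.DataFrame({"c": np.ones(10)})
        with pytest.raises(ValueError, match="every item"):
            qc_items(df)


class TestMAD:
    def test_hand_computed_cutoff(self):
        # median 2, raw MAD 1, scaled 1.4826, cutoff 4*1.4826 = 5.93
        mask = flag_outliers_mad(np.array([0.0, 1.0, 2.0, 3.0, 100.0]))
        assert mask.tolist() == [False, False, False, False, True]

    def test_zero_mad_warns_no_flags(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            mask = flag_outliers_mad(np.array([1.0, 1.0, 1.0, 1.0, 100.0]))
        assert not mask.any()

    def test_all_within_cutoff(self):
        assert not flag_outliers_mad(np.array([1.0, 2.0, 3.0, 4.0])).any()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            flag_outliers_mad(np.array([1.0, np.nan, np.nan]))


class TestImputation:
    def test_complete_matrix_passthrough(self):
        df = pd.DataFrame(np.arange(20, dtype=float).reshape(10, 2), columns=["a", "b"])
        out = impute_and_average(df)
        pd.testing.assert_frame_equal(out, df)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        df.iloc[::7, 0] = np.nan
        a = impute_and_average(df, n_imputations=2, n_iter=2, seed=3)
        b = impute_and_average(df, n_imputations=2, n_iter=2, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_imputed_value_tracks_regression_prediction(self):
        """One missing cell in a rho=0.9 column lands near the OLS prediction."""
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.normal(size=n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        df.loc[0, "y"] = np.nan
        out = impute_and_average(df, n_imputations=5, n_iter=3, seed=0)
        beta = np.polyfit(x[1:], y[1:], 1)
        pred = beta[0] * x[0] + beta[1]
        resid_sd = np.sqrt(1 - 0.81)
        assert abs(out.loc[0, "y"] - pred) < 2 * resid_sd
        # observed cells untouched
        assert np.array_equal(out["x"], df["x"])


class TestFactorability:
    def test_two_variable_kmo_is_half(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.6 * x + rng.normal(size=500)
        kmo, _, _ = kmo_bartlett(np.column_stack([x, y]))
        assert kmo == pytest.approx(0.5, abs=1e-10)

    def test_independent_items_bartlett_near_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5000, 6))
        _, chi2, p = kmo_bartlett(x)
        assert p > 0.05

    def test_structured_cohort_exceeds_gate(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        kmo, chi2, p = kmo_bartlett(x)
        assert kmo > 0.60
        assert p < 0.001


class TestFactorCount:
    def test_identity_map_argmin_zero(self):
        curve = map_criterion(np.eye(8), 3)
        assert np.nanargmin(curve) == 0

    def test_two_factor_structure(self):
        rng = np.random.default_rng(5)
        lam = np.zeros((10, 2))
        lam[:5, 0] = 0.7
        lam[5:, 1] = 0.7
        f = rng.normal(size=(4000, 2))
        x = f @ lam.T + np.sqrt(1 - 0.49) * rng.normal(size=(4000, 10))
        r = np.corrcoef(x, rowvar=False)
        assert np.nanargmin(map_criterion(r, 5)) == 2

    def test_five_factor_cohort_map(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        r = np.corrcoef(x, rowvar=False)
        assert np.nanargmin(map_criterion(r, 9)) == 5

    def test_vss_one_factor_peak(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=(3000, 1))
        x = 0.8 * f + 0.6 * rng.normal(size=(3000, 8))
        r = np.corrcoef(x, rowvar=False)
        curve = vss_criterion(r, 4, complexity=1)
        assert np.nanargmax(curve) == 0  # k = 1

    def test_vss_identity_degenerate_warns(self):
        with pytest.warns(UserWarning):
            curve = vss_criterion(np.eye(6), 3)
        assert np.isnan(curve).all()

    def test_five_factor_cohort_vss(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        r = np.corrcoef(x, rowvar=False)
        curve = vss_criterion(r, 7, complexity=1)
        assert np.nanargmax(curve) + 1 in (4, 5)

    def test_kmax_bounds(self):
        with pytest.raises(ValueError):
            map_criterion(np.eye(4), 4)


class TestPAF:
    def test_one_factor_closed_form(self):
        """Uniform off-diagonals L^2 imply loadings L for a one-factor model."""
        p, load = 8, 0.8
        r = np.full((p, p), load**2)
        np.fill_diagonal(r, 1.0)
        sol = paf_oblimin(r, 1)
        assert np.allclose(sol.loadings[:, 0], load, atol=0.01)
        assert sol.converged

    def test_two_block_recovery(self):
        rng = np.random.default_rng(7)
        lam = np.zeros((12, 2))
        lam[:6, 0] = 0.8
        lam[6:, 1] = 0.8
        f = rng.normal(size=(4000, 2))
        x = f @ lam.T + 0.6 * rng.normal(size=(4000, 12))
        sol = paf_oblimin(np.corrcoef(x, rowvar=False), 2)
        perm, signs = match_factors(lam, sol.loadings)
        cong = tucker_congruence(lam, sol.loadings[:, perm] * signs)
        assert np.diag(cong).min() >= 0.99

    def test_identity_degenerate_communalities(self):
        sol = paf_oblimin(np.eye(10), 2)
        assert sol.communalities.max() < 0.1

    def test_communalities_rotation_invariant(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        r = np.corrcoef(x, rowvar=False)
        rotated = paf_oblimin(r, 5, rotate=True)
        unrotated = paf_oblimin(r, 5, rotate=False)
        h2_rot = np.einsum(
            "ij,jk,ik->i", rotated.loadings, rotated.factor_corr, rotated.loadings
        )
        assert np.allclose(h2_rot, np.sum(unrotated.loadings**2, axis=1), atol=1e-6)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            paf_oblimin(np.eye(5), 5)


class TestRetention:
    @pytest.mark.parametrize(
        "loading,expected", [(0.46, 0), (0.45, None), (0.44, None)]
    )
    def test_cut_is_strict(self, loading, expected):
        from ctrlcascade.factors import FactorSolution

        lam = np.array([[loading, 0.1]])
        sol = FactorSolution(lam, np.eye(2), np.sum(lam**2, 1), 1, True)
        assert retain_loadings(sol)[0] == expected

    def test_cross_loader_max_rule(self):
        from ctrlcascade.factors import FactorSolution

        lam = np.array([[0.5, 0.6]])
        sol = FactorSolution(lam, np.eye(2), np.sum(lam**2, 1), 1, True)
        assert retain_loadings(sol)[0] == 1


class TestScores:
    def test_recovery_of_true_latents(self, five_factor_cohort):
        x, f_true, truth = five_factor_cohort
        model = PrincipalAxisFactorAnalysis(n_factors=5).fit(x)
        perm, signs = match_factors(truth.loadings_matrix, model.loadings_)
        s = factor_scores(model, x)[:, perm] * signs
        for j in range(5):
            assert np.corrcoef(s[:, j], f_true[:, j])[0, 1] >= 0.9

    def test_identical_subjects_identical_scores(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        model = PrincipalAxisFactorAnalysis(n_factors=5).fit(x)
        s = model.transform(np.vstack([x[:1], x[:1]]))
        assert np.array_equal(s[0], s[1])

    def test_scores_standardized(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        model = PrincipalAxisFactorAnalysis(n_factors=5).fit(x)
        s = factor_scores(model, x)
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(s.std(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_sklearn_params_roundtrip(self):
        m = PrincipalAxisFactorAnalysis(n_factors=3, gamma=0.5)
        m2 = PrincipalAxisFactorAnalysis(**m.get_params())
        assert m2.n_factors == 3 and m2.gamma == 0.5


class TestCrossValidation:
    def test_near_noiseless_items_near_perfect_stability(self):
        # zero unique noise would make R singular (regression scores undefined);
        # high communalities are the well-posed version of the determinism check
        rng = np.random.default_rng(8)
        lam = np.zeros((8, 2))
        lam[:4, 0] = rng.uniform(0.9, 0.95, 4)
        lam[4:, 1] = rng.uniform(0.9, 0.95, 4)
        f = rng.normal(size=(1000, 2))
        x = f @ lam.T + 0.3 * rng.normal(size=(1000, 8))
        _, rho = crossval_scores(x, k=2, seed=0)
        assert rho.min() > 0.999

    def test_five_factor_stability(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        _, rho = crossval_scores(x, k=5, seed=0)
        assert rho.min() >= 0.99

    def test_explicit_folds_reproducible(self, five_factor_cohort):
        x, _, _ = five_factor_cohort
        folds = np.arange(len(x)) % 10
        _, rho_a = crossval_scores(x, k=5, folds=folds)
        _, rho_b = crossval_scores(x, k=5, folds=folds)
        assert np.array_equal(rho_a, rho_b)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            crossval_scores(np.zeros((30, 4)), k=5)
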