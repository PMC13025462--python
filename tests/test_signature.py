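"""L1 logistic solver, stability selection, scores, ROC and adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitosig import _l1, signature as sig


def _logistic_data(rng, n=80, p=6, strong=2, scale=1.2):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:strong] = scale * np.array([1.0, -0.8][:strong])
    prob = 1 / (1 + np.exp(-(0.3 + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if len(np.unique(y)) < 2:  # pragma: no cover - seeded data has both classes
        y[0] = 1 - y[0]
    return X, y


class TestStandardize:
    def test_two_point_feature(self):
        # ddof = n-1 (the R scale() convention): values (1, 3) have mean 2
        # and SD sqrt(2), so they map to -1/sqrt(2), +1/sqrt(2)
        Z, params = sig.standardize(pd.DataFrame({"f": [1.0, 3.0]}))
        np.testing.assert_allclose(Z["f"].to_numpy(),
                                   [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert params.mean[0] == 2.0 and params.sd[0] == pytest.approx(np.sqrt(2))

    def test_params_idempotent_on_scaled_data(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)))
        Z, _ = sig.standardize(X)
        _, params2 = sig.standardize(Z)
        np.testing.assert_allclose(params2.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(params2.sd, 1.0, atol=1e-12)

    def test_out_of_sample_inverse(self, rng):
        X = pd.DataFrame(rng.normal(5, 2, size=(30, 3)), columns=list("abc"))
        held = pd.DataFrame(rng.normal(5, 2, size=(10, 3)), columns=list("abc"))
        _, params = sig.standardize(X)
        back = params.inverse_transform(params.transform(held))
        np.testing.assert_allclose(back.to_numpy(), held.to_numpy(), atol=1e-10)

    def test_zero_variance_feature_reported(self, rng):
        X = pd.DataFrame({"ok": rng.normal(size=8), "flat": np.ones(8)})
        Z, params = sig.standardize(X)
        assert params.dropped_zero_var == ["flat"]
        assert list(Z.columns) == ["ok"]


class TestL1Logistic:
    def test_full_shrinkage_above_lambda_max(self, rng):
        X, y = _logistic_data(rng)
        lmax = _l1.lambda_max(X, y)
        fit = sig.fit_l1_logistic(X, y, lmax * 1.0001)
        assert (fit.coef == 0).all()
        assert fit.intercept == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                              abs=1e-8)

    def test_unpenalized_matches_newton(self, rng):
        X, y = _logistic_data(rng, n=120, p=4, scale=0.8)
        import statsmodels.api as sm

        fit = sig.fit_l1_logistic(X, y, 0.0, tol=1e-14)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef.to_numpy()], ref.params, atol=1e-6)

    def test_kkt_conditions_hold(self, rng):
        X, y = _logistic_data(rng, n=100, p=8)
        lmax = _l1.lambda_max(X, y)
        for frac in (0.5, 0.1, 0.02):
            fit = sig.fit_l1_logistic(X, y, frac * lmax, tol=1e-14)
            assert _l1.kkt_violation(X, y, fit.coef.to_numpy(), fit.intercept,
                                     frac * lmax) < 1e-6

    def test_beats_two_feature_grid(self, rng):
        X, y = _logistic_data(rng, n=40, p=2, scale=1.0)
        lmax = _l1.lambda_max(X, y)
        for lam in (0.7 * lmax, 0.2 * lmax, 0.02 * lmax):
            fit = sig.fit_l1_logistic(X, y, lam, tol=1e-14)
            grid_min = _grid_objective_minimum(X, y, lam)
            ours = _l1.logistic_objective(X, y, fit.coef.to_numpy(),
                                          fit.intercept, lam)
            assert ours <= grid_min + 1e-6

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            sig.fit_l1_logistic(X, np.ones(10), 0.1)


def _grid_objective_minimum(X, y, lam, half_width=3.0, n_grid=201):
    """Brute-force 201x201 coefficient grid with the intercept profiled
    out by vectorized 1-D Newton at every grid point."""
    b1 = np.linspace(-half_width, half_width, n_grid)
    b2 = np.linspace(-half_width, half_width, n_grid)
    B1, B2 = np.meshgrid(b1, b2, indexing="ij")
    B = np.stack([B1.ravel(), B2.ravel()])      # (2, G)
    eta_x = X @ B                               # (n, G)
    b0 = np.zeros(B.shape[1])
    for _ in range(60):
        pr = 1 / (1 + np.exp(-(eta_x + b0)))
        g = (pr - y[:, None]).mean(axis=0)
        h = (pr * (1 - pr)).mean(axis=0)
        step = g / np.maximum(h, 1e-12)
        b0 -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = eta_x + b0
    nll = np.mean(np.logaddexp(0, eta) - y[:, None] * eta, axis=0)
    return float((nll + lam * np.abs(B).sum(axis=0)).min())


class TestLambdaSelection:
    def test_single_point_grid_returned(self, rng):
        X, y = _logistic_data(rng)
        lam, _, _ = sig.select_lambda_cv(X, y, lambda_grid=[0.123])
        assert lam == 0.123

    def test_pure_noise_rarely_selects_features(self):
        hits = 0
        for seed in range(50):
            gen = np.random.default_rng(1000 + seed)
            X = gen.normal(size=(60, 30))
            y = np.r_[np.ones(30), np.zeros(30)]
            lam, grid, _ = sig.select_lambda_cv(X, y, rng=gen)
            fit = sig.fit_l1_logistic(X, y, lam)
            if (fit.coef != 0).sum() <= 1:
                hits += 1
        assert hits >= 40  # >= 80% of repeats

    def test_planted_signal_always_recovered(self):
        for seed in range(50):
            gen = np.random.default_rng(2000 + seed)
            n = 60
            y = np.r_[np.ones(20), np.zeros(40)]
            X = gen.normal(size=(n, 10)) * 0.3
            X[:, 0] += 4.0 * y  # overwhelming feature: delta 4, SD 0.3
            Z, _ = sig.standardize(pd.DataFrame(X))
            lam, _, _ = sig.select_lambda_cv(Z, y, rng=gen)
            fit = sig.fit_l1_logistic(Z, y, lam)
            assert fit.coef.iloc[0] != 0.0

    def test_folds_cannot_exceed_minority(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.r_[np.ones(3), np.zeros(17)]
        with pytest.raises(ValueError, match="minority"):
            sig.select_lambda_cv(X, y, k=5)


class TestAuroc:
    def test_pairwise_example(self):
        scores = [0.9, 0.8, 0.7, 0.85]
        labels = [1, 1, 0, 0]
        assert sig.auroc(scores, labels) == pytest.approx(0.75)

    def test_perfect_and_inverted(self, rng):
        s = np.r_[rng.uniform(1, 2, 20), rng.uniform(0, 0.9, 30)]
        y = np.r_[np.ones(20), np.zeros(30)]
        assert sig.auroc(s, y) == 1.0
        assert sig.auroc(s, 1 - y) == pytest.approx(1 - sig.auroc(s, y))

    def test_matches_brute_force_concordance(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 200))
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                y[:2] = [0, 1]
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            pos, neg = s[y == 1], s[y == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert sig.auroc(s, y) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sig.auroc([1, 2], [1, 1])


class TestRocCurve:
    def test_minimal_case(self):
        c = sig.roc_curve([0.9, 0.1], [1, 0])
        np.testing.assert_allclose(c.fpr, [0, 0, 1])
        np.testing.assert_allclose(c.tpr, [0, 1, 1])
        assert c.auc == 1.0

    def test_perfect_separation_passes_corner(self, rng):
        s = np.r_[rng.uniform(1, 2, 10), rng.uniform(0, 0.9, 15)]
        y = np.r_[np.ones(10), np.zeros(15)]
        c = sig.roc_curve(s, y)
        assert any((f == 0 and t == 1) for f, t in zip(c.fpr, c.tpr))

    def test_area_equals_auroc(self, rng):
        s = np.round(rng.normal(size=200), 1)
        y = (rng.random(200) < 0.4).astype(int)
        c = sig.roc_curve(s, y)
        assert c.auc == pytest.approx(sig.auroc(s, y), abs=1e-12)

    def test_monotone_with_unit_endpoints(self, rng):
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        c = sig.roc_curve(s, y)
        assert (np.diff(c.fpr) >= 0).all() and (np.diff(c.tpr) >= 0).all()
        assert (c.fpr[0], c.tpr[0]) == (0, 0) and (c.fpr[-1], c.tpr[-1]) == (1, 1)


class TestScore:
    def test_printed_coefficient_arithmetic(self):
        # two-term formula with weights 0.142 and 0.018 on z-scaled values
        formula = {"ECI1": 0.142, "CKMT1A": 0.018}
        scaling = sig.ScalingParams(["ECI1", "CKMT1A"], np.zeros(2), np.ones(2), [])
        X = pd.DataFrame({"ECI1": [0.0, 1.0], "CKMT1A": [0.0, 1.0]})
        s = sig.compute_score(X, formula, scaling)
        assert s.iloc[0] == 0.0
        assert s.iloc[1] == pytest.approx(0.160)

    def test_linearity_in_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        scaling = sig.ScalingParams(["a", "b"], np.zeros(2), np.ones(2), [])
        s1 = sig.compute_score(X, {"a": 0.5, "b": -0.2}, scaling)
        s2 = sig.compute_score(X, {"a": 1.0, "b": -0.4}, scaling)
        np.testing.assert_allclose(s2.to_numpy(), 2 * s1.to_numpy(), atol=1e-12)

    def test_missing_feature_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 1)), columns=["a"])
        scaling = sig.ScalingParams(["a"], np.zeros(1), np.ones(1), [])
        with pytest.raises(KeyError, match="ghost"):
            sig.compute_score(X, {"ghost": 1.0}, scaling)


class TestStabilitySelection:
    def _separating_data(self, seed=0, n_pos=15, n_neg=30, p=12):
        gen = np.random.default_rng(seed)
        X = gen.normal(size=(n_pos + n_neg, p)) * 0.2
        y = np.r_[np.ones(n_pos), np.zeros(n_neg)]
        X[:, 0] += 6.0 * y  # margin far above noise
        return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), y

    def test_perfect_separator_has_frequency_one(self):
        X, y = self._separating_data()
        res = sig.bootstrap_stability(X, y, n_iterations=100, seed=5)
        assert res.selection_frequency["f0"] == 1.0
        assert "f0" in res.retained_features

    def test_single_iteration_frequencies_are_binary(self):
        X, y = self._separating_data(seed=3)
        res = sig.bootstrap_stability(X, y, n_iterations=1, seed=1)
        assert set(res.selection_frequency.unique()) <= {0.0, 1.0}

    def test_same_seed_bit_identical(self):
        X, y = self._separating_data(seed=2)
        a = sig.bootstrap_stability(X, y, n_iterations=12, seed=9)
        b = sig.bootstrap_stability(X, y, n_iterations=12, seed=9)
        assert a.to_json_dict() == b.to_json_dict()

    def test_substreams_keep_early_iterations_stable(self):
        X, y = self._separating_data(seed=4)
        short = sig.bootstrap_stability(X, y, n_iterations=5, seed=7)
        long = sig.bootstrap_stability(X, y, n_iterations=10, seed=7)
        a = short.iterations.drop(columns=["selected_features"])
        b = long.iterations.drop(columns=["selected_features"]).iloc[:5]
        pd.testing.assert_frame_equal(a, b)

    def test_empty_retained_set_flagged_not_raised(self):
        gen = np.random.default_rng(12)
        X = pd.DataFrame(gen.normal(size=(40, 20)))
        y = np.r_[np.ones(12), np.zeros(28)]
        res = sig.bootstrap_stability(X, y, n_iterations=10, seed=3)
        if res.no_stable_features:
            with pytest.raises(ValueError, match="no stable features"):
                res.score()

    def test_json_round_trip_artifacts(self, tmp_path):
        X, y = self._separating_data(seed=6)
        res = sig.bootstrap_stability(X, y, n_iterations=8, seed=2)
        path = tmp_path / "model.json"
        res.save_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["retained_features"] == [str(f) for f in res.retained_features]
        assert loaded["n_iterations"] == 8


class TestMultivariableLogistic:
    def test_intercept_only_recovers_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        out = sig.multivariable_logistic(None, pd.DataFrame(index=range(100)), y)
        odds = out.loc["intercept", "odds_ratio"]
        assert odds / (1 + odds) == pytest.approx(0.3, abs=1e-6)

    def test_matches_independent_irls(self, rng):
        n = 120
        score = rng.normal(size=n)
        covs = pd.DataFrame({"prior_therapy": rng.random(n) < 0.3,
                             "sarcomatoid": rng.random(n) < 0.2})
        eta = -1.0 + 1.2 * score
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        out = sig.multivariable_logistic(score, covs, y)
        X = np.column_stack([np.ones(n), score,
                             covs["prior_therapy"].astype(float),
                             covs["sarcomatoid"].astype(float)])
        beta = np.zeros(4)
        for _ in range(50):  # hand-rolled IRLS oracle
            p = 1 / (1 + np.exp(-X @ beta))
            W = p * (1 - p)
            H = X.T @ (X * W[:, None])
            step = np.linalg.solve(H, X.T @ (y - p))
            beta += step
            if np.abs(step).max() < 1e-12:
                break
        np.testing.assert_allclose(np.log(out["odds_ratio"].to_numpy()),
                                   beta, atol=1e-6)

    def test_null_covariate_ci_covers_one(self):
        cover = 0
        for seed in range(50):
            gen = np.random.default_rng(3000 + seed)
            n = 200
            score = gen.normal(size=n)
            noise_cov = gen.random(n) < 0.5
            y = (gen.random(n) < 1 / (1 + np.exp(-score))).astype(float)
            out = sig.multivariable_logistic(
                score, pd.DataFrame({"noise": noise_cov}), y)
            lo, hi = out.loc["noise", ["ci95_low", "ci95_high"]]
            if lo <= 1.0 <= hi:
                cover += 1
        assert cover >= 45  # >= 90%

    def test_rank_deficient_design_rejected(self, rng):
        n = 50
        score = rng.normal(size=n)
        covs = pd.DataFrame({"dup": score})
        y = (rng.random(n) < 0.5).astype(float)
        covs["dup2"] = covs["dup"]
        with pytest.raises(ValueError, match="rank"):
            sig.multivariable_logistic(score, covs, y)


@pytest.fixture(scope="module")
def strong_fit():
    """Cohort with an unmistakable planted signature and its fitted model."""
    from mitosig import synthetic as syn

    spec = syn.SyntheticCohortSpec(
        n_case=12, n_control=30, n_analytes=40, n_mito_flagged=20,
        planted_up=((0, 4.0), (1, 3.5)), planted_down=(),
        within_group_sd=0.5, seed=77)
    data, _ = syn.generate_cohort(spec)
    log2 = data.log2()
    res = sig.StabilitySelection.from_dataset(log2).fit(n_iterations=20, seed=0)
    assert not res.no_stable_features
    return data, log2, res


class TestSubsetSensitivity:
    def test_identity_subset_matches_overall(self, strong_fit):
        data, log2, res = strong_fit
        table, curves, skipped = sig.subset_sensitivity(
            log2, res, subsets={"all": np.ones(data.n_samples, bool)})
        assert table.loc["all", "auroc"] == pytest.approx(res.full_auroc)

    def test_two_sample_subset_and_skip(self, strong_fit):
        data, log2, res = strong_fit
        y = (data.samples["subtype"] == "ChRCC").to_numpy()
        pair = np.zeros(data.n_samples, bool)
        pair[np.flatnonzero(y)[0]] = True
        pair[np.flatnonzero(~y)[0]] = True
        only_ctrl = ~y
        table, curves, skipped = sig.subset_sensitivity(
            log2, res, subsets={"pair": pair, "ctrl_only": only_ctrl})
        assert "ctrl_only" in skipped
        assert set(table.index) == {"pair"}
        assert 0.0 <= table.loc["pair", "auroc"] <= 1.0
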