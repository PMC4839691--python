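"""Penalized logistic regression: solver, scoring, CV machinery."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import expit

from acimage.fit import (ACIModel, balance_indices, balance_set,
                         classification_rate, cross_validate, deviance,
                         fit_aci, fit_penalized_logistic, make_folds,
                         refit_full, roughness_penalty, select_lambda,
                         standardize, summarize_cv)


def _toy_problem(n=200, p=40, signal=0.3, seed=0):
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, p))
    beta = signal * rng.standard_normal(p)
    r = (rng.random(n) < expit(Z @ beta)).astype(float)
    return standardize(Z)[0], r


def _trial_frame(r, correct):
    n = len(r)
    return pd.DataFrame({"trial": np.arange(1, n + 1),
                         "session": np.ones(n, dtype=int),
                         "response": r.astype(int), "correct": correct})


class TestFolds:
    def test_partition(self):
        folds = make_folds(10_000, n_folds=10, seed=1)
        vals, counts = np.unique(folds, return_counts=True)
        assert list(vals) == list(range(1, 11))
        assert (counts == 1000).all()

    def test_seeded(self):
        assert np.array_equal(make_folds(100, seed=4), make_folds(100, seed=4))
        assert not np.array_equal(make_folds(100, seed=4),
                                  make_folds(100, seed=5))

    def test_indivisible(self):
        with pytest.raises(ValueError):
            make_folds(101, n_folds=10)


class TestBalancing:
    def test_majority_subsampled(self):
        correct = np.r_[np.ones(790, dtype=bool), np.zeros(210, dtype=bool)]
        idx = balance_indices(correct, seed=0)
        assert len(idx) == 420
        assert correct[idx].sum() == 210

    def test_already_balanced_unchanged(self):
        correct = np.r_[np.ones(50, dtype=bool), np.zeros(50, dtype=bool)]
        idx = balance_indices(correct, seed=0)
        assert np.array_equal(idx, np.arange(100))

    def test_seed_changes_members_not_size(self):
        # 6-trial toy set: 4 correct, 2 incorrect -> always keeps 4,
        # the retained correct pair varies with the seed
        correct = np.array([1, 1, 1, 1, 0, 0], dtype=bool)
        sets = {tuple(balance_indices(correct, seed=s)) for s in range(30)}
        assert all(len(s) == 4 for s in sets)
        assert len(sets) > 1
        # every possible subset keeps both incorrect trials
        assert all({4, 5} <= set(s) for s in sets)

    def test_one_class_absent(self):
        with pytest.raises(ValueError):
            balance_indices(np.ones(10, dtype=bool))

    def test_frame_view(self):
        df = _trial_frame(np.r_[np.ones(8), np.zeros(2)],
                          np.r_[np.ones(8, dtype=bool),
                                np.zeros(2, dtype=bool)])
        sub = balance_set(df, seed=1)
        assert len(sub) == 4
        assert sub["correct"].sum() == 2


class TestSolver:
    def test_matches_generic_convex_minimizer(self):
        # independent oracle: generic quasi-Newton on the identical
        # objective (ridge-only penalty, lambda=0 with fixed 1e-6 ridge)
        Z, r = _toy_problem()
        beta, b = fit_penalized_logistic(Z, r, lam=0.0, ridge=1e-6,
                                         shape=(8, 5), tol=1e-8)
        Pl = (1e-6 * sp.eye(Z.shape[1])).tocsr()

        def fun(w):
            z = w[0] + Z @ w[1:]
            return (-2 * (r @ z - np.logaddexp(0, z).sum())
                    + w[1:] @ (Pl @ w[1:]))

        res = minimize(fun, np.zeros(Z.shape[1] + 1), method="L-BFGS-B",
                       options={"gtol": 1e-10, "ftol": 1e-15,
                                "maxiter": 20_000})
        ours = fun(np.concatenate([[b], beta]))
        assert abs(ours - res.fun) / abs(res.fun) < 1e-6

    def test_huge_lambda_shrinks_everything(self):
        Z, r = _toy_problem(n=100, p=20)
        beta, b = fit_penalized_logistic(Z, r, lam=1e8, shape=(4, 5))
        assert np.max(np.abs(beta)) <= 1e-3

    def test_separable_data_stays_finite(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((20, 12))
        r = (Z[:, 0] > 0).astype(float)     # perfectly separable
        beta, b = fit_penalized_logistic(standardize(Z)[0], r, lam=1.0,
                                         shape=(3, 4))
        assert np.all(np.isfinite(beta))
        p = expit(b + standardize(Z)[0] @ beta)
        assert deviance(r, np.clip(p, 1e-12, 1 - 1e-12)) > 0

    def test_smoothness_penalty_prefers_smooth_maps(self):
        # same data, larger lambda -> smaller total variation of beta
        Z, r = _toy_problem(n=300, p=24, signal=0.8, seed=2)
        tv = []
        for lam in (1e-2, 1e2):
            beta, _ = fit_penalized_logistic(Z, r, lam=lam, shape=(4, 6))
            m = beta.reshape(4, 6)
            tv.append(np.abs(np.diff(m, axis=0)).sum()
                      + np.abs(np.diff(m, axis=1)).sum())
        assert tv[1] < tv[0]

    def test_rejects_degenerate_inputs(self):
        Z, r = _toy_problem(n=20, p=6)
        with pytest.raises(ValueError):
            fit_penalized_logistic(Z, r, lam=-1.0, shape=(2, 3))
        with pytest.raises(ValueError):
            fit_penalized_logistic(Z, np.ones(20), lam=1.0, shape=(2, 3))


class TestPenalty:
    def test_structure(self):
        P = roughness_penalty((3, 4), eps_ridge=0.0)
        assert P.shape == (12, 12)
        # constant vector is in the null space of the pure difference
        # penalty; the ridge removes it
        c = np.ones(12)
        assert np.allclose(P @ c, 0.0)
        P2 = roughness_penalty((3, 4), eps_ridge=1e-3)
        assert np.allclose(P2 @ c, 1e-3 * c)

    def test_quadratic_form_is_sum_of_squared_differences(self):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((3, 4))
        v = m.ravel(order="C")
        P = roughness_penalty((3, 4), eps_ridge=0.0)
        expected = (np.diff(m, axis=0) ** 2).sum() + \
                   (np.diff(m, axis=1) ** 2).sum()
        assert np.allclose(v @ (P @ v), expected)


class TestScoring:
    def test_chance_deviance_1000_trials(self):
        r = np.r_[np.ones(500), np.zeros(500)]
        p = np.full(1000, 0.5)
        assert deviance(r, p) == pytest.approx(1386.294, abs=1e-3)

    def test_perfect_prediction(self):
        r = np.r_[np.ones(5), np.zeros(5)]
        p = np.where(r == 1, 1 - 1e-12, 1e-12)
        assert deviance(r, p) == pytest.approx(0.0, abs=1e-9)

    def test_single_trial(self):
        assert deviance(np.array([1.0]), np.array([0.25])) == \
            pytest.approx(2.7726, abs=1e-4)

    def test_classification_rate(self):
        r = np.ones(10)
        assert classification_rate(r, np.full(10, 0.9)) == 100.0
        r = np.r_[np.ones(5), np.zeros(5)]
        assert classification_rate(r, np.full(10, 0.5)) == 50.0
        rng = np.random.default_rng(0)
        r = rng.permutation(np.r_[np.ones(5000), np.zeros(5000)])
        p = rng.random(10_000)
        assert abs(classification_rate(r, p) - 50.0) < 1.5


class TestModel:
    def _model(self, p=12):
        return ACIModel(beta=np.zeros((3, 4)), intercept=0.0, lam=1.0,
                        beta_std=np.zeros(p), mean=np.zeros(p),
                        scale=np.ones(p))

    def test_zero_model_predicts_half(self):
        m = self._model()
        assert np.allclose(m.predict_proba(np.random.rand(5, 12)), 0.5)

    def test_large_intercept_saturates(self):
        m = self._model()
        m.intercept = 10.0
        assert np.all(m.predict_proba(np.zeros((3, 12))) >= 0.9999)

    def test_hand_computed_logistic(self):
        m = self._model(p=2)
        m.beta_std = np.array([1.0, -2.0])
        m.intercept = 0.5
        S = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 0.5]])
        expect = expit(0.5 + S @ m.beta_std)
        assert np.allclose(m.predict_proba(S), expect, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            self._model().predict_proba(np.zeros((2, 7)))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = ACIModel(beta=rng.standard_normal((3, 4)), intercept=0.3,
                     lam=10.0, beta_std=rng.standard_normal(12),
                     mean=rng.standard_normal(12), scale=np.ones(12),
                     cvd=123.4, cvr=61.0, label="O1")
        m.save(tmp_path / "m.npz")
        back = ACIModel.load(tmp_path / "m.npz")
        assert np.array_equal(back.beta, m.beta)
        assert back.cvd == m.cvd and back.label == "O1"


class TestCrossValidation:
    def _synthetic_dataset(self, n=600, shape=(6, 8), seed=0, smooth=True):
        # responses from a smooth latent map over standardized
        # predictors; 'correct' flags assigned so balancing keeps most
        rng = np.random.default_rng(seed)
        p = shape[0] * shape[1]
        X = rng.standard_normal((n, p))
        ch = np.arange(shape[0])[:, None]
        fr = np.arange(shape[1])[None, :]
        t = np.exp(-0.5 * ((ch - 3) ** 2 / 4 + (fr - 4) ** 2 / 6))
        beta = (t / np.linalg.norm(t)).ravel() * (0.8 if smooth else 0.0)
        r = (rng.random(n) < expit(X @ beta)).astype(int)
        correct = rng.random(n) < 0.7
        return X, _trial_frame(np.asarray(r, float), correct), shape

    def test_single_lambda_grid(self):
        X, trials, shape = self._synthetic_dataset()
        cv = cross_validate(X, trials, lambda_grid=[10.0], seed=0,
                            n_folds=5, shape=shape)
        s = summarize_cv(cv)
        assert len(s) == 1 and s["lambda"].iloc[0] == 10.0
        assert select_lambda(cv) == 10.0

    def test_cv_curve_is_u_shaped_for_smooth_truth(self):
        X, trials, shape = self._synthetic_dataset(n=1000, seed=1)
        cv = cross_validate(X, trials, lambda_grid=[1e-3, 1e1, 1e6],
                            seed=0, n_folds=5, shape=shape)
        s = summarize_cv(cv).set_index("lambda")["mean_cvd"]
        assert s[1e1] < s[1e-3]
        assert s[1e1] < s[1e6]

    def test_shuffled_responses_score_at_chance(self):
        X, trials, shape = self._synthetic_dataset(n=1000, seed=2,
                                                   smooth=False)
        cv = cross_validate(X, trials, lambda_grid=[1e2], seed=0,
                            n_folds=5, shape=shape)
        assert 47 <= summarize_cv(cv)["mean_cvr"].iloc[0] <= 53

    def test_two_observer_selection_minimizes_cohort_mean(self):
        grid = [1.0, 10.0, 100.0]
        cv_a = pd.DataFrame({"lambda": grid, "fold": 1,
                             "cvd": [10.0, 12.0, 20.0],
                             "cvr": [60.0] * 3})
        cv_b = pd.DataFrame({"lambda": grid, "fold": 1,
                             "cvd": [30.0, 11.0, 12.0],
                             "cvr": [60.0] * 3})
        # per-observer minima at 1.0 and 10.0; cohort mean minimized at 10
        assert select_lambda([cv_a, cv_b]) == 10.0

    def test_tie_breaks_toward_smoother(self):
        grid = [1.0, 10.0]
        cv = pd.DataFrame({"lambda": grid, "fold": 1, "cvd": [5.0, 5.0],
                           "cvr": [60.0, 60.0]})
        assert select_lambda(cv) == 10.0

    def test_refit_beats_null_model(self):
        X, trials, shape = self._synthetic_dataset(n=800, seed=3)
        m = refit_full(X, trials, lam=10.0, seed=0, shape=shape)
        bal = balance_indices(trials["correct"].to_numpy(), seed=0)
        r = trials["response"].to_numpy()[bal]
        p = m.predict_proba(X[bal])
        null_dev = -2 * len(r) * np.log(0.5)
        assert deviance(r, p) <= null_dev

    def test_fit_aci_end_to_end(self):
        X, trials, shape = self._synthetic_dataset(n=600, seed=4)
        m = fit_aci(X, trials, lambda_grid=[1e0, 1e2], seed=0, n_folds=5,
                    shape=shape, label="toy")
        assert m.beta.shape == shape
        assert np.isfinite(m.cvd) and 0 <= m.cvr <= 100
        assert m.lam in (1e0, 1e2)
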