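"""Statistical primitives against independent oracles: exact rank-sum
enumeration, a permutation resampler, a hand-coded Pearson formula, a
Newton maximum-likelihood logistic solver, and R's lme4 for the
random-intercept model."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from tdpengine.stats import (
    ContractError,
    fit_logistic,
    fit_mixed_logistic,
    pearson_chi2,
    posthoc_contrasts,
    rank_sum_test,
    two_by_two,
)


def exact_ranksum_p(x, y):
    """Two-sided p by enumerating all rank assignments (tie-free only)."""
    combined = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(combined)) + 1.0
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(y)
    us = []
    for idx in itertools.combinations(range(len(combined)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lo = min(u_obs, n1n2 - u_obs)
    return ((us <= lo).sum() + (us >= n1n2 - lo).sum()) / len(us)


class TestRankSum:
    def test_separated_triplets(self):
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.10, abs=1e-12)
        assert p == pytest.approx(
            exact_ranksum_p(np.array([1., 2., 3.]), np.array([4., 5., 6.])))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(20)[:5].astype(float)
        y = np.setdiff1d(np.arange(20), x)[:7].astype(float)
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_identical_multisets_tie_corrected_p_is_one(self):
        _, p = rank_sum_test([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == 1.0
        _, p = rank_sum_test([3, 3, 3], [3, 3, 3])
        assert p == 1.0

    def test_asymptotic_vs_permutation_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.5, 1.0, 30)
        _, p = rank_sum_test(x, y)
        combined = np.concatenate([x, y])
        ranks = np.argsort(np.argsort(combined)) + 1.0
        n1 = len(x)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        n1n2 = n1 * len(y)
        lo = min(u_obs, n1n2 - u_obs)
        reps = 100_000
        perm = np.argsort(rng.random((reps, len(combined))), axis=1)[:, :n1]
        us = ranks[perm].sum(axis=1) - n1 * (n1 + 1) / 2
        p_perm = ((us <= lo).sum() + (us >= n1n2 - lo).sum()) / reps
        assert p == pytest.approx(p_perm, abs=0.01)

    def test_empty_input_contract_error(self):
        with pytest.raises(ContractError):
            rank_sum_test([], [1.0])


class TestTwoByTwo:
    def test_hsa_group_comparison_or(self):
        # LATE-NC 155 present / 425 absent vs No-TDP-43 66 / 1270
        r = two_by_two([[155, 425], [66, 1270]])
        assert r.odds_ratio == pytest.approx(155 * 1270 / (425 * 66),
                                             rel=1e-12)
        assert r.odds_ratio == pytest.approx(7.018, abs=5e-4)
        assert r.ci_low < r.odds_ratio < r.ci_high

    def test_balanced_table(self):
        r = two_by_two([[10, 10], [10, 10]])
        assert r.odds_ratio == 1.0 and r.chi2 == 0.0 and r.chi2_p == 1.0

    def test_matches_one_predictor_logistic(self):
        a, b, c, d = 12, 30, 7, 44
        r = two_by_two([[a, b], [c, d]])
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        g = np.r_[np.ones(a + b), np.zeros(c + d)]
        X = pd.DataFrame({"const": np.ones_like(y), "g": g})
        fit = fit_logistic(X, y)
        assert r.odds_ratio == pytest.approx(np.exp(fit.params["g"]),
                                             rel=1e-6)

    def test_zero_margin_non_estimable(self):
        r = two_by_two([[0, 10], [0, 12]])
        assert not r.estimable

    def test_zero_cell_continuity_policy(self):
        r = two_by_two([[0, 10], [5, 5]])
        assert r.continuity_added and np.isfinite(r.odds_ratio)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_chi2_matches_hand_pearson(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(5, 60, size=(2, 2)).astype(float)
        chi2, _ = pearson_chi2(t)
        row, col, n = t.sum(1), t.sum(0), t.sum()
        expected = np.outer(row, col) / n
        assert chi2 == pytest.approx(((t - expected) ** 2 / expected).sum(),
                                     rel=1e-12)


def newton_logit(X, y, tol=1e-12):
    """Independent ML oracle: Newton-Raphson on the logistic score."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        p = 1 / (1 + np.exp(-X @ beta))
        grad = X.T @ (y - p)
        H = X.T @ (X * (p * (1 - p))[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta


class TestLogistic:
    def test_twelve_row_fixture_matches_newton_oracle(self):
        X = pd.DataFrame({
            "const": np.ones(12),
            "x1": [0.5, -1.2, 0.3, 2.0, -0.7, 1.1, -0.2, 0.9, -1.5, 0.4,
                   1.8, -0.9],
            "x2": [1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0],
        })
        y = np.array([1, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 0], float)
        fit = fit_logistic(X, y)
        oracle = newton_logit(X, y)
        assert np.abs(fit.params.values - oracle).max() < 1e-6

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        fit = fit_logistic(pd.DataFrame({"const": np.ones(n), "x": x}), y)
        assert np.exp(fit.params["x"]) == pytest.approx(1.0, abs=0.15)


class TestContrasts:
    def _fit(self, rng, n=800):
        g = rng.integers(0, 3, n)
        X = pd.DataFrame({
            "const": np.ones(n),
            "cat_b": (g == 1).astype(float),
            "cat_c": (g == 2).astype(float),
        })
        eta = -0.3 + 0.8 * X["cat_b"] + 1.4 * X["cat_c"]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        return X, np.asarray(y, float), g

    def test_self_contrast_is_null(self):
        rng = np.random.default_rng(0)
        X, y, _ = self._fit(rng)
        fit = fit_logistic(X, y)
        c = posthoc_contrasts(fit, [("cat_b", "cat_b")])[0]
        assert c.estimate == 0.0 and c.p_value == 1.0

    def test_reference_switch_invariance(self):
        """A b-vs-c contrast equals the b coefficient after refitting with
        c as the reference level (to 1e-8), and so does its p-value."""
        rng = np.random.default_rng(1)
        X, y, g = self._fit(rng)
        fit = fit_logistic(X, y)
        c = posthoc_contrasts(fit, [("cat_b", "cat_c")])[0]
        X2 = pd.DataFrame({
            "const": np.ones(len(y)),
            "cat_a": (g == 0).astype(float),
            "cat_b": (g == 1).astype(float),
        })
        refit = fit_logistic(X2, y)
        assert c.estimate == pytest.approx(refit.params["cat_b"], abs=1e-8)
        se_refit = np.sqrt(refit.cov.loc["cat_b", "cat_b"])
        assert c.se == pytest.approx(se_refit, abs=1e-8)
        assert c.p_value == pytest.approx(
            refit.term_or("cat_b").p_value, abs=1e-8)

    def test_non_estimable_skipped_with_note(self):
        rng = np.random.default_rng(2)
        X, y, _ = self._fit(rng)
        fit = fit_logistic(X, y)
        fit.params["cat_b"] = np.nan
        c = posthoc_contrasts(fit, [("cat_b", "cat_c")])[0]
        assert not c.estimable and c.note


class TestMixedLogistic:
    def test_single_group_degenerates(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        mf = fit_mixed_logistic(X, y, np.zeros(n, int))
        sf = fit_logistic(X, y)
        assert np.allclose(mf.params, sf.params, atol=1e-8)
        assert "single-level" in mf.note

    def test_matches_lme4_glmer(self, tmp_path):
        """Fixed effects, their SEs, and the intercept SD agree with
        lme4::glmer (adaptive quadrature, nAGQ=25) on a simulated
        two-level dataset."""
        if shutil.which("Rscript") is None:
            pytest.xfail("Rscript not on PATH")
        rng = np.random.default_rng(11)
        n, J = 600, 8
        x = rng.normal(size=n)
        g = rng.integers(0, J, n)
        u = rng.normal(0, 0.8, J)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.9 * x + u[g])))
             ).astype(int)
        mf = fit_mixed_logistic(pd.DataFrame({"const": np.ones(n), "x": x}),
                                y, g)
        csv_path = tmp_path / "mm.csv"
        pd.DataFrame({"y": y, "x": x, "g": g}).to_csv(csv_path, index=False)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv_path}");'
            'm <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=25);'
            'cat(fixef(m), sqrt(diag(as.matrix(vcov(m)))),'
            '    sqrt(unlist(VarCorr(m))), sep="\\n")')
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        b0, b1, se0, se1, sd = map(float, proc.stdout.split())
        assert mf.params["const"] == pytest.approx(b0, abs=2e-3)
        assert mf.params["x"] == pytest.approx(b1, abs=2e-3)
        assert np.sqrt(mf.cov.loc["const", "const"]) == pytest.approx(
            se0, abs=5e-3)
        assert np.sqrt(mf.cov.loc["x", "x"]) == pytest.approx(se1, abs=5e-3)
        assert mf.sigma_center == pytest.approx(sd, abs=5e-3)
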