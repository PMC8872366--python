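"""Stratified-interaction WQS estimation: index arithmetic, constrained
optimizer behaviour, ensemble averaging, holdout-stage inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wqsmix.cohort import COVARIATE_COLS
from wqsmix.wqs import (
    WQS,
    CoefficientTable,
    WeightSet,
    compute_index,
    ensemble_weights,
    equi_weight_threshold,
    fit_index_model,
    fit_single_bootstrap,
    stratum_slope,
)


def uniform_weights(c=26, n_strata=2):
    strata = ("boy", "girl")[:n_strata]
    return WeightSet(
        np.full((n_strata, c), 1.0 / (n_strata * c)),
        chemicals=[f"chem{j}" for j in range(c)],
        strata=strata,
    )


class TestThresholdAndSlopes:
    @pytest.mark.parametrize(
        "c,n_strata,expected", [(26, 2, 1 / 52), (1, 1, 1.0), (10, 1, 0.1)]
    )
    def test_equi_weight_threshold(self, c, n_strata, expected):
        assert equi_weight_threshold(c, n_strata) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "b1,b12,stratum,expected",
        [(-2.13, 1.98, "girl", -0.15), (-2.13, 1.98, "boy", -2.13),
         (-2.0, 0.0, "girl", -2.0), (0.0, 0.0, "girl", 0.0)],
    )
    def test_stratum_slope(self, b1, b12, stratum, expected):
        coefs = CoefficientTable(
            params=pd.Series({"Intercept": 0.0, WQS: b1, "WQS:Female": b12})
        )
        assert stratum_slope(coefs, stratum) == pytest.approx(expected)

    def test_unknown_stratum_rejected(self):
        coefs = CoefficientTable(params=pd.Series({"Intercept": 0.0}))
        with pytest.raises(ValueError):
            stratum_slope(coefs, "other")


class TestWeightSet:
    def test_simplex_violations_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            WeightSet(np.full((2, 26), 0.01), chemicals=[f"c{j}" for j in range(26)])
        w = np.full((2, 26), 1 / 52)
        w[0, 0], w[0, 1] = -0.01, 1 / 52 + 0.01
        with pytest.raises(ValueError, match="nonnegative"):
            WeightSet(w, chemicals=[f"c{j}" for j in range(26)])

    def test_threshold_is_one_over_2c(self):
        assert uniform_weights().threshold == pytest.approx(1 / 52)


class TestComputeIndex:
    def test_uniform_weights_all_nines(self):
        w = uniform_weights()
        q = np.full((4, 26), 9.0)
        sex = np.array([0, 1, 0, 1])
        assert np.allclose(compute_index(q, w, sex), 4.5)

    def test_zero_scores_zero_index(self):
        w = uniform_weights()
        assert np.allclose(compute_index(np.zeros((3, 26)), w, np.array([0, 1, 0])), 0.0)

    def test_index_bounds_under_decile_scoring(self, rng):
        w = uniform_weights()
        q = rng.integers(0, 10, size=(50, 26)).astype(float)
        idx = compute_index(q, w, rng.integers(0, 2, size=50))
        assert (idx >= 0).all() and (idx <= 9).all()

    def test_invalid_sex_rejected(self):
        with pytest.raises(ValueError, match="sex"):
            compute_index(np.zeros((2, 26)), uniform_weights(), np.array([0, 2]))


class TestFitIndexModel:
    def test_exact_recovery_without_noise(self, rng):
        n = 60
        index = rng.uniform(0, 9, n)
        sex = rng.integers(0, 2, n)
        y = 95.0 - 2.0 * index
        coefs = fit_index_model(index, None, sex, y)
        assert coefs.beta0 == pytest.approx(95.0, abs=1e-8)
        assert coefs.beta1 == pytest.approx(-2.0, abs=1e-10)
        assert coefs.beta2 == pytest.approx(0.0, abs=1e-8)

    def test_recovers_generating_coefficients(self, cohort678):
        from wqsmix.synthetic import true_index

        cohort, quantiles = cohort678
        index = true_index(quantiles, cohort.sex, cohort.truth)
        coefs = fit_index_model(index, cohort.covariates, cohort.sex, cohort.outcome)
        # single-cohort estimate: within ~3 SEs of the generating slope
        assert abs(coefs.beta1 - cohort.truth.beta1) < 3 * coefs.se[WQS]

    def test_rank_deficiency_names_columns(self, rng):
        n = 40
        index = rng.uniform(0, 9, n)
        sex = rng.integers(0, 2, n)
        cov = pd.DataFrame({"dup": index})
        with pytest.raises(ValueError, match="collinear"):
            fit_index_model(index, cov, sex, rng.normal(size=n))

    def test_null_calibration_ci_covers_zero(self, cohort678, rng):
        """With the outcome permuted, the 95% CI for the index slope should
        cover 0 in at least 93 of 100 permutations."""
        cohort, quantiles = cohort678
        w = WeightSet(
            np.full((2, 26), 1 / 52), chemicals=quantiles.chemicals
        )
        index = compute_index(quantiles.scores, w, cohort.sex)
        covered = 0
        y = cohort.outcome.copy()
        for _ in range(100):
            yp = rng.permutation(y)
            coefs = fit_index_model(index, cohort.covariates, cohort.sex, yp)
            lo = coefs.beta1 - 1.96 * coefs.se[WQS]
            hi = coefs.beta1 + 1.96 * coefs.se[WQS]
            covered += lo <= 0 <= hi
        assert covered >= 93


def grid_search_rss(scores, covariates, sex, y, step=0.01):
    """Independent oracle: exhaustive profiled-RSS search on the 0.01-step
    3-simplex (single-stratum toy problems only)."""
    n = len(y)
    x0 = np.ones((n, 1))
    best = (np.inf, None)
    m = int(round(1 / step))
    for i, j in itertools.product(range(m + 1), repeat=2):
        if i + j > m:
            continue
        w = np.array([i, j, m - i - j]) / m
        wqs = scores @ w
        x = np.column_stack([x0, wqs])
        b, *_ = np.linalg.lstsq(x, y, rcond=None)
        if b[1] > 0:  # negative-direction constraint
            b, *_ = np.linalg.lstsq(x0, y, rcond=None)
            b = np.array([b[0], 0.0])
        r = y - x @ b
        rss = float(r @ r)
        if rss < best[0]:
            best = (rss, w)
    return best


class TestBootstrapFit:
    def test_noiseless_single_weight_recovery(self, rng):
        n, c = 300, 5
        q = rng.integers(0, 10, size=(n, c)).astype(float)
        sex = rng.integers(0, 2, size=n)
        y = 100.0 - 2.0 * np.where(sex == 0, q[:, 1], 0.0)
        fit = fit_single_bootstrap(q, None, sex, y, seed=1, resample=False)
        assert fit.weights.weights[0, 1] >= 0.95
        assert fit.coefficients.beta1 == pytest.approx(-2.0, abs=0.05)

    def test_matches_grid_search_oracle(self, rng):
        """Constrained optimizer vs exhaustive 0.01-grid simplex search."""
        n, c = 150, 3
        q = rng.integers(0, 10, size=(n, c)).astype(float)
        sex = np.zeros(n, dtype=int)
        w_true = np.array([0.6, 0.3, 0.1])
        y = 90.0 - 1.5 * (q @ w_true) + rng.normal(0, 1.0, n)
        rss_grid, w_grid = grid_search_rss(q, None, sex, y)
        fit = fit_single_bootstrap(q, None, sex, y, seed=0, resample=False)
        assert fit.objective <= rss_grid + 1e-8
        assert np.abs(fit.weights.weights[0] - w_grid).max() <= 0.02

    def test_direction_constraint_pins_positive_trend(self, rng):
        n, c = 200, 4
        q = rng.integers(0, 10, size=(n, c)).astype(float)
        sex = rng.integers(0, 2, size=n)
        y = 80.0 + 2.0 * q.mean(axis=1)  # trend opposite to the constraint
        fit = fit_single_bootstrap(q, None, sex, y, direction="negative", seed=3,
                                   resample=False)
        assert fit.coefficients.beta1 == pytest.approx(0.0, abs=1e-8)

    def test_beta1_sign_constraint_holds_across_resamples(self, cohort200):
        cohort, quantiles = cohort200
        for seed in range(5):
            fit = fit_single_bootstrap(
                quantiles.scores, cohort.covariates, cohort.sex, cohort.outcome,
                direction="negative", seed=seed, n_restarts=1,
            )
            assert fit.coefficients.beta1 <= 1e-10
            w = fit.weights
            assert np.all(w.weights >= 0)
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-8)

    def test_pure_noise_gives_weak_effect(self, rng):
        """With y independent of the exposures, the fitted index explains
        little: the per-stratum effect per index SD stays well under the
        outcome SD.  (beta1 itself is scale-ambiguous: a tiny stratum block
        can carry an arbitrarily steep slope.)"""
        n, c = 400, 6
        q = rng.integers(0, 10, size=(n, c)).astype(float)
        sex = rng.integers(0, 2, size=n)
        y = rng.normal(100, 10, n)
        fit = fit_single_bootstrap(q, None, sex, y, seed=2, resample=False)
        idx = compute_index(q, fit.weights, sex)
        boys = sex == 0
        eff_boys = fit.coefficients.beta1 * idx[boys].std(ddof=1)
        eff_girls = stratum_slope(fit.coefficients, "girl") * idx[~boys].std(ddof=1)
        assert abs(eff_boys) < 5.0
        assert abs(eff_girls) < 5.0

    def test_monotone_signal_in_noise_level(self):
        """Mean estimated weight on truly active chemicals does not decrease
        as the residual SD shrinks."""
        import dataclasses

        from wqsmix.synthetic import default_truth, simulate_cohort

        active = dict(zip(range(3), [20.0, 6.0, 1.0]))
        means = []
        for sigma in active.values():
            truth = default_truth(sigma=sigma)
            cohort, quantiles = simulate_cohort(n=400, seed=31, truth=truth)
            fits = [
                fit_single_bootstrap(
                    quantiles.scores, cohort.covariates, cohort.sex, cohort.outcome,
                    seed=s, n_restarts=1,
                )
                for s in range(8)
            ]
            w = ensemble_weights(fits).flat
            means.append(w[cohort.truth.true_weights > 0].mean())
        assert means[0] <= means[1] + 0.01
        assert means[1] <= means[2] + 0.01


class TestEnsembleWeights:
    def _fit_with(self, flat, c=3):
        w = np.asarray(flat, dtype=float).reshape(2, c)
        ws = WeightSet(w, chemicals=[f"c{j}" for j in range(c)])
        coefs = CoefficientTable(
            params=pd.Series({"Intercept": 0.0, WQS: -1.0}),
            se=pd.Series({WQS: 0.5}),
        )
        from wqsmix.wqs import BootstrapFit

        return BootstrapFit(weights=ws, coefficients=coefs, objective=1.0,
                            converged=True, seed=0)

    def test_mean_of_two_one_hots(self):
        f1 = self._fit_with([1, 0, 0, 0, 0, 0])
        f2 = self._fit_with([0, 1, 0, 0, 0, 0])
        avg = ensemble_weights([f1, f2])
        assert np.allclose(avg.flat, [0.5, 0.5, 0, 0, 0, 0])

    def test_identical_fits_idempotent(self):
        f = self._fit_with([0.2, 0.3, 0.1, 0.1, 0.2, 0.1])
        avg = ensemble_weights([f, f, f])
        assert np.allclose(avg.flat, f.weights.flat)

    def test_no_converged_fits_rejected(self):
        f = self._fit_with([1, 0, 0, 0, 0, 0])
        f.converged = False
        with pytest.raises(ValueError, match="converged"):
            ensemble_weights([f])

    def test_signal_weighted_mode(self):
        f1 = self._fit_with([1, 0, 0, 0, 0, 0])
        f2 = self._fit_with([0, 1, 0, 0, 0, 0])
        f2.coefficients.se[WQS] = 0.1  # |t| five times larger
        avg = ensemble_weights([f1, f2], mode="signal_weighted")
        assert avg.flat[1] > avg.flat[0]
        assert avg.flat.sum() == pytest.approx(1.0)
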