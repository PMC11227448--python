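"""Two-limit Tobit likelihood, fitting, diagnostics and report table."""

import subprocess
import textwrap

import numpy as np
import pytest

from lueff.tobit import (
    TobitFit,
    driver_table,
    fit_two_limit_tobit,
    loglik_two_limit,
    pseudo_r2_from_values,
    vif,
)


def _simulate(seed, n, beta, sigma, x_sd=1.6):
    rng = np.random.default_rng(seed)
    k = len(beta) - 1
    X = np.column_stack([np.ones(n), rng.normal(0, x_sd, (n, k))])
    y = np.clip(X @ np.asarray(beta) + rng.normal(0, sigma, n), 0.0, 1.0)
    return y, X


class TestLoglik:
    def test_reduces_to_gaussian_when_uncensored(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        beta = np.array([0.5, 0.05])
        y = np.clip(X @ beta + rng.normal(0, 0.02, 50), 0.2, 0.8)  # interior
        sigma = 0.02
        resid = y - X @ beta
        gauss = np.sum(
            -np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * (resid / sigma) ** 2
        )
        assert loglik_two_limit(beta, sigma, y, X) == pytest.approx(gauss, abs=1e-10)

    def test_all_upper_censored_monotone_in_linear_predictor(self):
        X = np.ones((10, 1))
        y = np.ones(10)
        lls = [loglik_two_limit(np.array([b]), 0.3, y, X) for b in (0.5, 1.0, 2.0)]
        assert lls[0] < lls[1] < lls[2]

    def test_hand_computed_three_point_value(self):
        # y=(0, 0.5, 1), x=(0, 1, 2), beta=(0.2, 0.3), sigma=0.5:
        # logPhi(-0.4) + [-log 0.5 - log(2 pi)/2] + logPhi(-0.4)
        y = np.array([0.0, 0.5, 1.0])
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        ll = loglik_two_limit(np.array([0.2, 0.3]), 0.5, y, X)
        assert ll == pytest.approx(-2.356659451023881, abs=1e-12)

    def test_nonpositive_sigma_errors(self):
        with pytest.raises(ValueError, match="sigma"):
            loglik_two_limit(np.zeros(1), 0.0, np.zeros(2), np.ones((2, 1)))


class TestFit:
    def test_uncensored_matches_least_squares(self):
        rng = np.random.default_rng(1)
        n = 1000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = np.clip(0.5 + 0.05 * X[:, 1] + rng.normal(0, 0.03, n), 0, 1)
        assert not np.any((y == 0) | (y == 1))
        fit = fit_two_limit_tobit(y, X)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, rtol=1e-3)

    def test_likelihood_never_decreases_from_start(self):
        for seed in range(5):
            y, X = _simulate(seed, 400, [0.6, 0.1, -0.2], 0.15)
            fit = fit_two_limit_tobit(y, X)
            beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
            sigma0 = max(float(np.std(y - X @ beta0)), 1e-3)
            assert fit.loglik >= loglik_two_limit(beta0, sigma0, y, X) - 1e-9

    def test_matches_r_survreg_interval_censoring(self, tmp_path):
        """Cross-check against the survival package's gaussian AFT fit, an
        independent MLE of the same censored likelihood."""
        y, X = _simulate(3, 300, [0.6, 0.1, -0.2], 0.15)
        fit = fit_two_limit_tobit(y, X, names=["const", "x1", "x2"])
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([y, X[:, 1:]]), delimiter=",",
                   header="y,x1,x2", comments="")
        script = textwrap.dedent(f"""
            suppressMessages(library(survival))
            d <- read.csv("{csv}")
            lo <- ifelse(d$y<=0, NA, ifelse(d$y>=1, 1, d$y))
            hi <- ifelse(d$y<=0, 0, ifelse(d$y>=1, NA, d$y))
            f <- survreg(Surv(lo, hi, type="interval2") ~ x1 + x2,
                         data=d, dist="gaussian")
            cat(coef(f), f$scale, sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        np.testing.assert_allclose(fit.beta, vals[:3], atol=1e-4)
        assert fit.sigma == pytest.approx(vals[3], abs=1e-4)

    def test_all_censored_fails_loudly(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(ValueError, match="censored"):
            fit_two_limit_tobit(np.ones(20), X)

    def test_rank_deficient_design_errors(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_two_limit_tobit(np.clip(0.5 + 0.1 * x, 0, 1), X)

    def test_covariate_rescaling_invariance(self):
        y, X = _simulate(4, 800, [0.6, 0.1, -0.2], 0.15)
        fit1 = fit_two_limit_tobit(y, X)
        X2 = X.copy()
        X2[:, 1] *= 10.0
        fit2 = fit_two_limit_tobit(y, X2)
        assert fit2.beta[1] == pytest.approx(fit1.beta[1] / 10.0, rel=1e-4)
        np.testing.assert_allclose(fit2.z, fit1.z, atol=1e-5)
        np.testing.assert_allclose(fit2.p_values, fit1.p_values, atol=1e-6)
        assert fit2.pseudo_r2 == pytest.approx(fit1.pseudo_r2, abs=1e-6)


class TestDiagnostics:
    def test_pseudo_r2_perfect_fit(self):
        y = np.linspace(0.1, 0.9, 20)
        assert pseudo_r2_from_values(y.copy(), y) == pytest.approx(1.0)

    def test_pseudo_r2_constant_fitted_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pseudo_r2_from_values(np.full(5, 0.3), np.linspace(0, 1, 5))

    def test_vif_orthogonal_columns(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.ones(n), np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n)])
        v = vif(X, ["const", "s", "c"])
        np.testing.assert_allclose(v.to_numpy(), 1.0, atol=1e-10)
        assert "const" not in v.index

    def test_vif_correlated_pair_closed_form(self):
        # population correlation 0.8 imposed exactly via Gram construction
        rng = np.random.default_rng(5)
        a = rng.normal(size=4000)
        b_raw = rng.normal(size=4000)
        # orthonormalize empirically, then mix with exact weights
        a = (a - a.mean()) / a.std()
        b_raw = b_raw - b_raw.mean()
        b_raw -= a * (a @ b_raw) / (a @ a)
        b_raw /= b_raw.std()
        b = 0.8 * a + np.sqrt(1 - 0.64) * b_raw
        X = np.column_stack([np.ones(4000), a, b])
        v = vif(X, ["const", "a", "b"])
        np.testing.assert_allclose(v.to_numpy(), 1.0 / (1.0 - 0.64), rtol=1e-9)

    def test_vif_duplicated_column_errors(self):
        x = np.random.default_rng(6).normal(size=30)
        with pytest.raises(ValueError, match="rank deficient"):
            vif(np.column_stack([np.ones(30), x, x]))


class TestDriverTable:
    def _fit(self):
        names = ["const", "pop_density", "natura_share", "road_density",
                 "slope_pct", "elev_m", "n_lulc", "dist_heritage_m"]
        k = len(names)
        return TobitFit(
            beta=np.array([0.6, 0.1, 0.02, -0.1, 0.17, 0.0001, -0.26, 0.001]),
            sigma=0.2,
            se=np.full(k + 1, 0.05),
            loglik=-10.0,
            pseudo_r2=0.28,
            names=names,
            n_obs=100,
            n_lower=0,
            n_upper=5,
            converged=True,
        )

    def test_groups_follow_driver_taxonomy(self):
        tbl = driver_table(self._fit())
        assert tbl.loc["pop_density", "group"] == "socio-economic"
        assert tbl.loc["n_lulc", "group"] == "socio-economic"
        assert tbl.loc["slope_pct", "group"] == "natural"
        assert tbl.loc["elev_m", "group"] == "natural"
        assert tbl.loc["natura_share", "group"] == "political"
        assert tbl.loc["road_density", "group"] == "technological"
        assert tbl.loc["dist_heritage_m", "group"] == "cultural"

    def test_row_order_matches_fit(self):
        fit = self._fit()
        assert list(driver_table(fit).index) == fit.names

    def test_significance_stars(self):
        fit = self._fit()
        # z = beta / 0.05: 0.17/0.05=3.4 -> p~7e-4 -> ***; 0.02/0.05=0.4 -> none
        tbl = driver_table(fit)
        assert tbl.loc["slope_pct", "sig"] == "***"
        assert tbl.loc["natura_share", "sig"] == ""

    def test_unknown_covariate_errors(self):
        fit = self._fit()
        fit.names[1] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            driver_table(fit)
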