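import numpy as np
import pandas as pd
import pytest

from oracles import composed_error_logpdf, conditional_mean_u
from phcdea import sfa
from phcdea.panel import PanelDataset


def _design(z):
    return np.column_stack([np.ones(len(z)), z])


class TestLoglikelihood:
    def test_gamma_zero_is_gaussian_ols(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=30)
        s = 1 + 2 * z + rng.normal(size=30)
        D = _design(z)
        beta, *_ = np.linalg.lstsq(D, s, rcond=None)
        resid = s - D @ beta
        s2 = resid @ resid / len(s)
        ll = sfa.sfa_loglikelihood(beta, s2, 0.0, s, D)
        ll_gauss = -0.5 * len(s) * (np.log(2 * np.pi * s2) + 1.0)
        assert ll == pytest.approx(ll_gauss, abs=1e-10)

    def test_matches_quadrature_oracle(self):
        """Tiny hand-set dataset: likelihood equals the numerically
        integrated v+u convolution density summed over observations."""
        s = np.array([0.5, -0.3, 1.2, 0.0, 2.1])
        z = np.array([0.1, -0.5, 0.7, 0.0, 1.5])
        beta = np.array([0.2, 0.4])
        sigma_v, sigma_u = 0.6, 0.9
        sigma_sq = sigma_v ** 2 + sigma_u ** 2
        gamma = sigma_u ** 2 / sigma_sq
        D = _design(z)
        eps = s - D @ beta
        expected = sum(composed_error_logpdf(e, sigma_v, sigma_u) for e in eps)
        got = sfa.sfa_loglikelihood(beta, sigma_sq, gamma, s, D)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_scaling_identity(self):
        """Scaling slacks, f and both sigmas by c shifts loglik by -n ln c."""
        rng = np.random.default_rng(2)
        z = rng.normal(size=20)
        s = 1 + z + rng.normal(size=20)
        D = _design(z)
        beta = np.array([1.0, 1.0])
        sigma_sq, gamma, c = 1.3, 0.6, 7.0
        ll = sfa.sfa_loglikelihood(beta, sigma_sq, gamma, s, D)
        ll_c = sfa.sfa_loglikelihood(beta * c, sigma_sq * c ** 2, gamma, s * c, D)
        assert ll_c == pytest.approx(ll - len(s) * np.log(c), abs=1e-9)

    def test_invalid_parameters_rejected(self):
        D = _design(np.zeros(3))
        with pytest.raises(ValueError):
            sfa.sfa_loglikelihood([0, 0], -1.0, 0.5, np.zeros(3), D)
        with pytest.raises(ValueError):
            sfa.sfa_loglikelihood([0, 0], 1.0, 1.5, np.zeros(3), D)
        with pytest.raises(ValueError):
            sfa.sfa_loglikelihood([np.nan, 0], 1.0, 0.5, np.zeros(3), D)


class TestFit:
    def test_pure_noise_recovers_ols(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=400)
        s = 2 + 0.5 * z + rng.normal(scale=0.8, size=400)
        fit = sfa.fit_sfa(s, z[:, None])
        D = _design(z)
        beta_ols, *_ = np.linalg.lstsq(D, s, rcond=None)
        assert fit.gamma < 0.3
        np.testing.assert_allclose(fit.beta, beta_ols, atol=0.15)
        assert fit.loglik >= fit.loglik_ols - 1e-6

    def test_parameter_recovery_n2000(self):
        """beta=(1,2), sigma_v=0.5, sigma_u=1.0 -> gamma=0.8; estimates
        within 3 Monte-Carlo standard errors at n=2000."""
        rng = np.random.default_rng(5)
        n = 2000
        z = rng.normal(size=n)
        s = 1 + 2 * z + rng.normal(scale=0.5, size=n) + np.abs(rng.normal(scale=1.0, size=n))
        fit = sfa.fit_sfa(s, z[:, None])
        # MC se of the slope is ~ sigma_eps/sqrt(n) ~ 0.02; intercept larger
        assert fit.beta[1] == pytest.approx(2.0, abs=3 * 0.03)
        assert fit.beta[0] == pytest.approx(1.0, abs=3 * 0.06)
        assert fit.gamma == pytest.approx(0.8, abs=0.1)

    def test_rank_deficient_rejected(self):
        z = np.ones((10, 2))
        with pytest.raises(ValueError, match="rank"):
            sfa.fit_sfa(np.arange(10.0), z)

    def test_lr_stat_nonnegative_and_reported(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=200)
        s = 1 + z + np.abs(rng.normal(scale=1.0, size=200)) + rng.normal(scale=0.3, size=200)
        fit = sfa.fit_sfa(s, z[:, None])
        assert fit.lr_stat >= 0
        assert fit.lr_stat == pytest.approx(2 * (fit.loglik - fit.loglik_ols), abs=1e-8)


class TestLRTest:
    def test_gamma_zero_not_rejected(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=300)
        s = 1 + z + rng.normal(size=300)
        fit = sfa.fit_sfa(s, z[:, None])
        lr, p, reject = sfa.lr_test_gamma(fit)
        assert not reject or lr < 4  # borderline noise allowed, no strong rejection

    def test_power_under_strong_inefficiency(self):
        """gamma = 0.9 (sigma_u = 3 sigma_v): LR rejects at 5% in >= 95%."""
        rejections = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            n = 500
            z = rng.normal(size=n)
            s = (1 + z + rng.normal(scale=np.sqrt(0.1), size=n)
                 + np.abs(rng.normal(scale=np.sqrt(0.9), size=n)))
            fit = sfa.fit_sfa(s, z[:, None])
            _, _, reject = sfa.lr_test_gamma(fit)
            rejections += reject
        assert rejections >= 0.95 * reps

    def test_lr_invariant_to_env_rescaling(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=300)
        s = 1 + 2 * z + rng.normal(scale=0.5, size=300) + np.abs(rng.normal(size=300))
        lr1 = sfa.fit_sfa(s, z[:, None]).lr_stat
        lr2 = sfa.fit_sfa(s, (3.0 * z + 5.0)[:, None]).lr_stat
        assert lr1 == pytest.approx(lr2, rel=1e-3)


class TestJLMS:
    def test_zero_inefficiency_limit(self):
        assert np.all(sfa.jlms_conditional_mu(np.array([-2.0, 0.0, 3.0]), 1.0, 0.0) == 0)

    def test_quadrature_oracle_at_zero(self):
        got = sfa.jlms_conditional_mu(np.array([0.0]), 1.0, 1.0)[0]
        assert got == pytest.approx(conditional_mean_u(0.0, 1.0, 1.0), abs=1e-6)

    @pytest.mark.parametrize("eps", [-1.5, -0.2, 0.4, 2.0])
    def test_quadrature_oracle_general(self, eps):
        got = sfa.jlms_conditional_mu(np.array([eps]), 0.7, 1.3)[0]
        assert got == pytest.approx(conditional_mean_u(eps, 0.7, 1.3), abs=1e-6)

    def test_positive_and_increasing(self):
        vals = sfa.jlms_conditional_mu(np.linspace(-3, 3, 13), 1.0, 1.0)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) > 0)


class TestAdjust:
    def _panel_and_fits(self, fitted, nu):
        rows = []
        for i, (f, v) in enumerate(zip(fitted, nu)):
            rows.append({"dmu": f"d{i}", "year": 2000, "region": "east",
                         "i1": 100.0, "o1": 10.0, "z1": float(i)})
        panel = PanelDataset(pd.DataFrame(rows), input_cols=("i1",),
                             output_cols=("o1",), env_cols=("z1",))
        obs = pd.DataFrame({"dmu": [f"d{i}" for i in range(len(fitted))],
                            "year": 2000, "slack": 0.0,
                            "fitted": fitted, "eps": 0.0, "cond_mu": 0.0,
                            "nu_hat": nu})
        fit = sfa.SFAFit(input_name="i1", beta=np.zeros(2), sigma_sq=1.0,
                         gamma=0.5, loglik=0.0, loglik_ols=0.0, lr_stat=0.0,
                         converged=True, beta_se=None, obs=obs)
        return panel, {"i1": fit}

    def test_printed_formula_substitution(self):
        """f=(10,30), nu=(2,-1) -> adjustments (+20, +3)."""
        panel, fits = self._panel_and_fits([10.0, 30.0], [2.0, -1.0])
        adj = sfa.adjust_inputs(panel, fits)
        got = adj.panel.sorted_data()["i1"].to_numpy()
        np.testing.assert_allclose(got, [120.0, 103.0])

    def test_zero_spread_is_identity(self):
        panel, fits = self._panel_and_fits([5.0, 5.0], [0.3, 0.3])
        adj = sfa.adjust_inputs(panel, fits)
        np.testing.assert_allclose(adj.panel.sorted_data()["i1"], 100.0)

    def test_invariant_to_constant_f_shift(self):
        p1, f1 = self._panel_and_fits([10.0, 30.0], [2.0, -1.0])
        p2, f2 = self._panel_and_fits([110.0, 130.0], [2.0, -1.0])
        a1 = sfa.adjust_inputs(p1, f1).panel.sorted_data()["i1"]
        a2 = sfa.adjust_inputs(p2, f2).panel.sorted_data()["i1"]
        np.testing.assert_allclose(a1, a2)

    def test_missing_fit_rejected(self):
        panel, fits = self._panel_and_fits([10.0, 30.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="no SFA fit"):
            sfa.adjust_inputs(panel, {})

    def test_double_max_observation_unchanged(self):
        """The observation attaining both max f and max nu keeps its input."""
        panel, fits = self._panel_and_fits([10.0, 30.0], [-1.0, 2.0])
        adj = sfa.adjust_inputs(panel, fits)
        got = adj.panel.sorted_data()["i1"].to_numpy()
        np.testing.assert_allclose(got, [123.0, 100.0])

    def test_adjustment_nonnegative_on_pipeline_run(self, small_run):
        panel, _, result = small_run
        before = panel.sorted_data()
        after = result.adjusted.panel.sorted_data()
        for col in panel.input_cols:
            diff = after[col].to_numpy() - before[col].to_numpy()
            nu_spread = np.ptp(result.fits[col].obs["nu_hat"].to_numpy())
            assert np.all(diff >= -1e-9)
            # smallest adjustment is bounded by the noise-term spread
            assert diff.min() <= nu_spread + 1e-9
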