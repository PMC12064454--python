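"""Estimation: likelihood oracles, moments, fit behaviour, fit indices."""

import numpy as np
import pytest

from dyadcfm.estimation import (
    ClusterData,
    FitConfig,
    build_cluster_data,
    dense_loglikelihood,
    fit,
    fit_indices,
    loglikelihood,
    pooled_moments,
)
from dyadcfm.model import ParameterSet, build_spec, implied_moments
from dyadcfm.synthetic import default_params, generate_panel

from conftest import random_theta, tiny_spec


def _random_clusters(rng, p_w, p_z, sizes):
    out = []
    for i, n in enumerate(sizes):
        out.append(
            ClusterData(
                dyad_id=i,
                Y=rng.normal(size=(n, p_w)) * 2 + 1,
                z=rng.normal(size=p_z) if p_z else np.empty(0),
            )
        )
    return out


class TestPooledMoments:
    def test_hand_computation_two_clusters(self):
        # clusters {0,2} and {4,6}: S_PW = ((0-1)^2+(2-1)^2+(4-5)^2+(6-5)^2)/(4-2) = 2
        data = [
            ClusterData(0, np.array([[0.0], [2.0]]), np.empty(0)),
            ClusterData(1, np.array([[4.0], [6.0]]), np.empty(0)),
        ]
        S_pw, S_b, sizes = pooled_moments(data)
        assert S_pw[0, 0] == pytest.approx(2.0)
        # cluster means 1, 5 about grand mean 3: sum n*(d^2)/(J-1) = (2*4+2*4)/1
        assert S_b[0, 0] == pytest.approx(16.0)
        assert list(sizes) == [2, 2]

    def test_identical_rows_give_zero_within(self):
        data = [
            ClusterData(0, np.ones((3, 2)), np.empty(0)),
            ClusterData(1, np.full((4, 2), 7.0), np.empty(0)),
        ]
        S_pw, _, _ = pooled_moments(data)
        np.testing.assert_allclose(S_pw, 0.0, atol=1e-14)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="single cluster"):
            pooled_moments([ClusterData(0, np.ones((3, 1)), np.empty(0))])


class TestLoglikelihood:
    def test_standard_normal_single_observation(self):
        """1 cluster, 1 day, 1 variable, Sigma_W=1, Sigma_B=0, mu=0, y=0."""
        spec = tiny_spec(1)
        ps = ParameterSet(spec, {
            "psi(ETA)@within": 0.5, "theta(y0)@within": 0.5,
            "psi(ETA)@between": 0.0, "theta(y0)@between": 0.0, "mu(y0)": 0.0,
        })
        data = [ClusterData(0, np.zeros((1, 1)), np.empty(0))]
        assert loglikelihood(spec, ps, data) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_zero_between_reduces_to_independent_days(self):
        from scipy.stats import norm

        spec = tiny_spec(1)
        ps = ParameterSet(spec, {
            "psi(ETA)@within": 1.5, "theta(y0)@within": 0.5,
            "psi(ETA)@between": 0.0, "theta(y0)@between": 0.0, "mu(y0)": 0.3,
        })
        rng = np.random.default_rng(0)
        y = rng.normal(size=(6, 1))
        data = [ClusterData(0, y[:4], np.empty(0)), ClusterData(1, y[4:], np.empty(0))]
        expected = norm.logpdf(y.ravel(), loc=0.3, scale=np.sqrt(2.0)).sum()
        assert loglikelihood(spec, ps, data) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("name,sizes", [
        ("daily_qol", (1, 2, 3, 5)),     # p_w=6: max dim 30
        ("post_qol", (2, 3, 4)),         # p_w=4, p_z=2
        ("post_prep", (1, 5, 7)),
        ("daily_rs", (2, 4)),
    ])
    def test_structured_equals_dense_oracle(self, name, sizes):
        """Structured evaluation matches the brute-force dense covariance
        on every instance with n_j * p <= 60, over random parameter draws."""
        spec = build_spec(name)
        p_z = spec.between.p - spec.within.p
        rng = np.random.default_rng(17)
        data = _random_clusters(rng, spec.within.p, p_z, sizes)
        for k in range(15):
            ps = random_theta(spec, rng)
            ll_fast = loglikelihood(spec, ps, data)
            ll_dense = dense_loglikelihood(spec, ps, data)
            assert ll_fast == pytest.approx(ll_dense, abs=1e-8)

    def test_non_pd_returns_minus_inf(self):
        spec = tiny_spec(2)
        ps = ParameterSet(spec, {
            "psi(ETA)@within": -2.0, "theta(y0)@within": 0.1, "theta(y1)@within": 0.1,
            "psi(ETA)@between": 1.0, "theta(y0)@between": 0.1, "theta(y1)@between": 0.1,
            "mu(y0)": 0.0, "mu(y1)": 0.0,
        })
        data = [ClusterData(0, np.zeros((2, 2)), np.empty(0))]
        assert loglikelihood(spec, ps, data) == -np.inf


class TestFit:
    def test_deterministic(self, model1_fit):
        spec, data, res = model1_fit
        res2 = fit(spec, data, FitConfig())
        for k in spec.param_names:
            assert res2.theta_hat.values[k] == pytest.approx(
                res.theta_hat.values[k], abs=1e-10
            )

    def test_monotone_likelihood_trace(self):
        params = default_params(seed=55)
        panel, post = generate_panel(params)
        spec = build_spec("daily_rs")
        data = build_cluster_data(panel, post, spec)
        res = fit(spec, data, FitConfig(track_trace=True, compute_se=False,
                                        compute_fit_indices=False))
        t = np.array(res.trace)
        assert len(t) > 5
        assert np.all(np.diff(t) >= -1e-6)

    def test_saturated_model_chi2_zero(self):
        """A df=0 specification reproduces the saturated likelihood:
        chi-square vanishes and RMSEA/TLI are not applicable."""
        spec = tiny_spec(2)
        assert spec.df == 0
        rng = np.random.default_rng(1)
        params = default_params(seed=14, n_dyads=60)
        panel, _ = generate_panel(params)
        sub = panel.pivot_table(index=["dyad_id", "day"], columns="role",
                                values="wda", aggfunc="first").dropna()
        data = [
            ClusterData(d, g.to_numpy(), np.empty(0))
            for d, g in sub.groupby(level="dyad_id")
        ]
        res = fit(spec, data, FitConfig())
        assert res.converged
        assert abs(res.chi2) < 1e-6
        assert res.fit["rmsea"] is None and res.fit["tli"] is None
        assert res.fit["cfi"] == 1.0

    def test_balanced_design_matches_moment_estimator(self):
        """With complete 14-day data, full ML equals the Muthén-type
        moment-based estimator (two-Wishart discrepancy on S_PW and the
        cluster-mean covariance), a known exact equivalence under balance."""
        from scipy.optimize import minimize
        from dyadcfm.estimation import _Compiled

        params = default_params(seed=31, missing_rate=0.0)
        panel, post = generate_panel(params)
        spec = build_spec("daily_qol")
        data = build_cluster_data(panel, post, spec)
        assert len({cd.n_j for cd in data}) == 1  # balanced
        res = fit(spec, data, FitConfig(compute_se=False, compute_fit_indices=False,
                                        gtol=1e-9, ftol=1e-14))

        n = data[0].n_j
        J, N = len(data), n * len(data)
        S_pw, _, _ = pooled_moments(data)
        means = np.vstack([cd.Y.mean(axis=0) for cd in data])
        comp = _Compiled(spec)
        is_var = comp.is_var

        def discrepancy(x):
            nat = x.copy()
            nat[is_var] = np.exp(nat[is_var])
            Sw, Sb, mu = comp.moments(nat)
            Sn = Sb + Sw / n
            try:
                iw = np.linalg.inv(Sw)
                inn = np.linalg.inv(Sn)
            except np.linalg.LinAlgError:
                return 1e12
            sw, ldw = np.linalg.slogdet(Sw)
            sn, ldn = np.linalg.slogdet(Sn)
            if sw <= 0 or sn <= 0:
                return 1e12
            D = means - mu
            S_mean = D.T @ D / J
            return (N - J) * (ldw + np.sum(iw * S_pw)) + J * (ldn + np.sum(inn * S_mean))

        # exact identity: the structured per-cluster likelihood equals the
        # moment-based two-Wishart discrepancy up to the data constant
        from dyadcfm.estimation import _Prepared

        prep = _Prepared(data, spec.within.p, 0)
        x_ml = res.theta_hat.to_vector()
        x_ml[is_var] = np.log(x_ml[is_var])
        assert -2.0 * (res.loglik - prep.const) == pytest.approx(
            discrepancy(x_ml), rel=1e-12
        )
        # independent minimization of the moment discrepancy from its own
        # start lands on the same estimates
        from dyadcfm.estimation import _start_vector, _Compiled as _C

        x0 = _start_vector(spec, prep, comp)
        out = minimize(discrepancy, x0, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-9})
        nat = out.x.copy()
        nat[is_var] = np.exp(nat[is_var])
        np.testing.assert_allclose(nat, res.theta_hat.to_vector(), atol=1e-4, rtol=1e-3)

    def test_fiml_estimates_stable_under_mcar_deletion(self):
        """MCAR day deletion at 10% moves every standardized parameter by
        less than 0.05 at 2000 dyads (FIML consistency)."""
        from dyadcfm.synthetic import apply_mcar_mask

        params = default_params(seed=61, n_dyads=2000, missing_rate=0.0)
        panel, post = generate_panel(params)
        spec = build_spec("daily_qol")
        cfg = FitConfig(compute_se=False, compute_fit_indices=False)
        res_full = fit(spec, build_cluster_data(panel, post, spec), cfg)
        panel_m = apply_mcar_mask(panel, 0.10, seed=99)
        res_miss = fit(spec, build_cluster_data(panel_m, post, spec), cfg)
        for k, v in res_full.beta.items():
            assert abs(v - res_miss.beta[k]) < 0.05, k

    def test_consistency_at_large_n(self):
        """Estimates approach the generating values as the number of dyads
        grows (correctness of the ML implementation; at the emulated
        study's own size the ML estimator carries visible O(1/J) bias)."""
        from dyadcfm.synthetic import _parameter_set

        params = default_params(seed=71, n_dyads=3000, missing_rate=0.0)
        panel, post = generate_panel(params)
        spec = build_spec("daily_qol")
        res = fit(spec, build_cluster_data(panel, post, spec),
                  FitConfig(compute_se=False, compute_fit_indices=False))
        truth = {k: v for k, v in _parameter_set(params).values.items()
                 if k in spec.param_names}
        assert res.theta_hat.values["WDA->CDC@within"] == pytest.approx(
            truth["WDA->CDC@within"], abs=0.45
        )
        assert res.theta_hat.values["WDA->CDC@between"] == pytest.approx(
            truth["WDA->CDC@between"], abs=0.25
        )
        for k in truth:
            if k.startswith("mu("):
                assert res.theta_hat.values[k] == pytest.approx(truth[k], abs=0.4)

    def test_mixedlm_cross_check_univariate(self):
        """Saturated two-level variance components for one indicator agree
        with statsmodels MixedLM (independent ML implementation)."""
        import statsmodels.formula.api as smf
        from dyadcfm.estimation import _Prepared, _fit_saturated

        params = default_params(seed=23, n_dyads=100)
        panel, _ = generate_panel(params)
        sub = panel[panel["role"] == "PLWH"][["dyad_id", "wda"]].dropna()
        data = [
            ClusterData(d, g[["wda"]].to_numpy(), np.empty(0))
            for d, g in sub.groupby("dyad_id")
        ]
        prep = _Prepared(data, 1, 0)
        ll, Sw, Sb, mu, ok = _fit_saturated(prep)
        md = smf.mixedlm("wda ~ 1", sub, groups=sub["dyad_id"]).fit(reml=False)
        assert mu[0] == pytest.approx(md.params["Intercept"], abs=1e-3)
        assert Sw[0, 0] == pytest.approx(md.scale, rel=1e-3)
        assert Sb[0, 0] == pytest.approx(
            float(md.cov_re.iloc[0, 0]), rel=1e-2, abs=1e-3
        )

    def test_unidentified_spec_rejected(self):
        spec = tiny_spec(1)  # 1 indicator, latent + residual free: df < 0
        with pytest.raises(ValueError, match="not identified"):
            fit(spec, [ClusterData(0, np.zeros((2, 1)), np.empty(0))])


class TestFitIndices:
    def test_cfi_direct_formula(self):
        # chi2_m=10, df=5, chi2_b=110, df_b=10 -> CFI = 1 - 5/100 = 0.95
        out = fit_indices(
            loglik_m=-5.0, df_m=5, loglik_sat=0.0, loglik_base=-55.0,
            df_base=10, n_obs=100,
        )
        assert out["chi2"] == pytest.approx(10.0)
        assert out["cfi"] == pytest.approx(0.95)
        # TLI = ((11) - (2)) / (11 - 1) = 0.9
        assert out["tli"] == pytest.approx(0.9)
        assert out["rmsea"] == pytest.approx(np.sqrt(5.0 / 500.0))

    def test_perfect_fit(self):
        spec = build_spec("daily_qol")
        ps = random_theta(spec, np.random.default_rng(2))
        mom = implied_moments(spec, ps)
        out = fit_indices(
            loglik_m=-10.0, df_m=4, loglik_sat=-10.0, loglik_base=-80.0,
            df_base=10, n_obs=50, S_PW=mom.sigma_within, S_B=mom.sigma_between,
            implied=mom,
        )
        assert out["chi2"] == 0.0
        assert out["cfi"] == 1.0 and out["rmsea"] == 0.0
        assert out["srmr_within"] == pytest.approx(0.0, abs=1e-12)
        assert out["srmr_between"] == pytest.approx(0.0, abs=1e-12)

    def test_df_zero_reports_not_applicable(self):
        out = fit_indices(-5.0, 0, -5.0, -50.0, 10, 100)
        assert out["rmsea"] is None and out["tli"] is None


def test_day_level_fiml_drops_incomplete_days(default_panel):
    params, panel, post = default_panel
    spec = build_spec("daily_qol")
    data = build_cluster_data(panel, post, spec)
    # every retained day is complete for both partners
    assert all(np.isfinite(cd.Y).all() for cd in data)
    # missing person-days reduce cluster sizes below the full 14
    assert min(cd.n_j for cd in data) < 14 <= max(cd.n_j for cd in data)
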