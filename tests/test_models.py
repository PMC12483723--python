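"""Structural layers: implied moments, df counting, identification."""

import numpy as np
import pytest

from ordalt.models import (
    SpecError,
    build_spec,
    check_identification,
    count_df,
    model_stats,
    recover_params,
    reduced_form_moments,
    sample_admissible_theta,
    structural_moments,
)
from ordalt.simulate import SimScenario, simulate


def _theta(spec, **values):
    th = np.zeros(spec.n_free)
    idx = {n: k for k, n in enumerate(spec.param_names)}
    for name, val in values.items():
        th[idx[name]] = val
    return th, idx


class TestLGMMoments:
    def test_zero_growth_variance_gives_identity(self):
        spec = build_spec("lgm", "alt2_inv", 4, 4, placement="theta")
        th, idx = _theta(spec, **{"tau[0][2]": 2.0})
        for t in range(4):
            th[idx[f"theta[0][{t}]"]] = 1.0
        mom = structural_moments(spec, th)
        np.testing.assert_allclose(mom.mu_star, 0.0)
        np.testing.assert_allclose(mom.sigma_star, np.eye(4), atol=1e-14)

    def test_variance_at_last_occasion_closed_form(self):
        # psi_aa=1, psi_bb=0.25, psi_ab=0, theta=1, T=4: var_4 = 1 + 9*0.25 + 1
        spec = build_spec("lgm", "alt2_inv", 4, 4, placement="theta")
        th, idx = _theta(
            spec,
            **{"tau[0][2]": 2.0, "psi[0][0][0]": 1.0, "psi[0][1][1]": 0.25},
        )
        for t in range(4):
            th[idx[f"theta[0][{t}]"]] = 1.0
        mom = structural_moments(spec, th)
        assert mom.sigma_star[3, 3] == pytest.approx(4.25)
        mu2, S2 = reduced_form_moments(spec, th)
        np.testing.assert_allclose(mom.sigma_star, S2, atol=1e-12)

    def test_slope_mean_produces_linear_trend(self):
        spec = build_spec("lgm", "alt2_inv", 5, 4, placement="theta")
        th, idx = _theta(spec, **{"tau[0][2]": 2.0, "mu_beta[0]": 0.5})
        for t in range(5):
            th[idx[f"theta[0][{t}]"]] = 1.0
        mom = structural_moments(spec, th)
        np.testing.assert_allclose(mom.mu_star, 0.5 * np.arange(5), atol=1e-14)


class TestAR1Moments:
    def test_zero_coefficients_return_psi(self):
        spec = build_spec("ar1", "alt2_inv", 4, 4)
        th, idx = _theta(spec, **{"m1[0]": 0.3, "p11[0][0]": 1.5})
        for t in range(1, 4):
            th[idx[f"theta[0][{t}]"]] = 0.8
            th[idx[f"nu[0][{t}]"]] = 0.1
        mom = structural_moments(spec, th)
        np.testing.assert_allclose(np.diag(mom.sigma_star), [1.5, 0.8, 0.8, 0.8])
        np.testing.assert_allclose(mom.mu_star, [0.3, 0.1, 0.1, 0.1])

    def test_stationary_autocovariance_geometric_decay(self):
        # rho = 0.5, theta = 1, var(y1) = 4/3: cov(y_t, y_{t+k}) = (4/3) 0.5^k
        spec = build_spec("ar1", "alt2_inv", 5, 4, stationary=True)
        th, idx = _theta(spec, **{"p11[0][0]": 4.0 / 3.0, "rho[0]": 0.5})
        for t in range(1, 5):
            th[idx[f"theta[0][{t}]"]] = 1.0
        mom = structural_moments(spec, th)
        for t in range(5):
            for k in range(5 - t):
                assert mom.sigma_star[t, t + k] == pytest.approx((4 / 3) * 0.5**k)

    def test_stationary_moments_match_simulation(self):
        spec = build_spec("ar1", "alt2_inv", 5, 4, stationary=True)
        th, idx = _theta(spec, **{"p11[0][0]": 4.0 / 3.0, "rho[0]": 0.5})
        for t in range(1, 5):
            th[idx[f"theta[0][{t}]"]] = 1.0
        _, latent = simulate(SimScenario(spec, th, n=10**6), seed=5, return_latent=True)
        mom = structural_moments(spec, th)
        se = 4 * (4 / 3) / np.sqrt(10**6) * 3  # crude 4-MC-SE bound
        assert np.max(np.abs(np.cov(latent.T) - mom.sigma_star)) < se


class TestALTMoments:
    def test_nesting_reduces_to_lgm_when_rho_zero(self):
        alt = build_spec("alt", "alt2_inv", 5, 4)
        th, idx = _theta(
            alt,
            **{
                "tau[0][2]": 2.0,
                "mu_alpha[0]": 0.2,
                "mu_beta[0]": 0.1,
                "psi[0][0]": 0.5,
                "psi[1][1]": 0.1,
                "psi[1][0]": 0.05,
                "m1[0]": 0.2,
                "p11[0][0]": 0.65,
                "p1g[0][0]": 0.5,
                "p1g[0][1]": 0.05,
            },
        )
        for t in range(1, 5):
            th[idx[f"theta[0][{t}]"]] = 1.0
        mom = structural_moments(alt, th)
        # with rho = 0 and y1 sharing the growth structure, occasions t >= 2
        # reproduce the growth model's moments exactly
        lam = np.column_stack([np.ones(5), np.arange(5.0)])
        psi = np.array([[0.5, 0.05], [0.05, 0.1]])
        expected = lam @ psi @ lam.T + np.eye(5)
        np.testing.assert_allclose(
            mom.sigma_star[1:, 1:], expected[1:, 1:], atol=1e-12
        )
        np.testing.assert_allclose(mom.mu_star[1:], (lam @ [0.2, 0.1])[1:], atol=1e-14)

    def test_nesting_reduces_to_ar1_when_growth_absent(self):
        alt = build_spec("alt", "alt2_inv", 5, 4)
        th, idx = _theta(alt, **{"m1[0]": 0.3, "p11[0][0]": 1.2})
        for t in range(1, 5):
            th[idx[f"rho[0][{t}]"]] = 0.4
            th[idx[f"theta[0][{t}]"]] = 0.9
        ar1 = build_spec("ar1", "alt2_inv", 5, 4)
        th2, idx2 = _theta(ar1, **{"m1[0]": 0.3, "p11[0][0]": 1.2})
        for t in range(1, 5):
            th2[idx2[f"rho[0][{t}]"]] = 0.4
            th2[idx2[f"theta[0][{t}]"]] = 0.9
        np.testing.assert_allclose(
            structural_moments(alt, th).sigma_star,
            structural_moments(ar1, th2).sigma_star,
            atol=1e-14,
        )

    @pytest.mark.parametrize(
        "family,par,T,C,kw",
        [
            ("lgm", "alt1_inv", 5, 4, {"placement": "theta"}),
            ("ar1", "standard", 5, 4, {}),
            ("alt", "alt1_inv", 5, 4, {}),
            ("alt", "alt2_inv", 6, 4, {}),
            ("alt", "alt1_inv", 6, (2, 4, 4), {}),
        ],
    )
    def test_reduced_form_oracle_agreement(self, family, par, T, C, kw, rng):
        spec = build_spec(family, par, T, C, **kw)
        for _ in range(5):
            th = sample_admissible_theta(spec, rng)
            mom = structural_moments(spec, th)
            mu2, S2 = reduced_form_moments(spec, th)
            np.testing.assert_allclose(mom.mu_star, mu2, atol=1e-12)
            np.testing.assert_allclose(mom.sigma_star, S2, atol=1e-12)

    # shared per-series values for the decoupling check
    _SERIES = {
        "tau": [-0.6, 0.4, 1.3],
        "rho": 0.35,
        "theta": 0.8,
        "mu_alpha": 0.1,
        "mu_beta": -0.05,
        "psi_aa": 0.3,
        "psi_ab": 0.02,
        "psi_bb": 0.05,
        "p1a": 0.12,
        "p1b": 0.01,
    }

    def _series_theta(self, spec, v):
        vals = {}
        s = self._SERIES
        for c, tv in enumerate(s["tau"]):
            vals[f"tau[{v}][{c}]"] = tv
        for t in range(1, spec.T):
            vals[f"rho[{v}][{t}]"] = s["rho"]
            vals[f"theta[{v}][{t}]"] = s["theta"]
        vals[f"mu_alpha[{v}]"] = s["mu_alpha"]
        vals[f"mu_beta[{v}]"] = s["mu_beta"]
        a, b = 2 * v, 2 * v + 1
        if spec.V > 1:
            vals[f"psi[{a}][{a}]"] = s["psi_aa"]
            vals[f"psi[{b}][{a}]"] = s["psi_ab"]
            vals[f"psi[{b}][{b}]"] = s["psi_bb"]
        else:
            vals["psi[0][0]"] = s["psi_aa"]
            vals["psi[1][0]"] = s["psi_ab"]
            vals["psi[1][1]"] = s["psi_bb"]
        vals[f"p1g[{v}][{a}]"] = s["p1a"]
        vals[f"p1g[{v}][{b}]"] = s["p1b"]
        return vals

    def test_malt_blocks_decouple_without_cross_effects(self):
        malt = build_spec("alt", "alt1_inv", 4, (4, 4), cross_lagged=True, concomitant=True)
        vals = {**self._series_theta(malt, 0), **self._series_theta(malt, 1)}
        th, _ = _theta(malt, **vals)  # every coupling left at zero
        mom = structural_moments(malt, th)
        np.testing.assert_allclose(mom.sigma_star[:4, 4:], 0.0, atol=1e-12)
        uni = build_spec("alt", "alt1_inv", 4, 4)
        thu, _ = _theta(uni, **self._series_theta(uni, 0))
        momu = structural_moments(uni, thu)
        np.testing.assert_allclose(mom.sigma_star[:4, :4], momu.sigma_star, atol=1e-12)
        np.testing.assert_allclose(mom.sigma_star[4:, 4:], momu.sigma_star, atol=1e-12)

    def test_malt_concomitant_covariance_propagates(self):
        malt = build_spec("alt", "alt1_inv", 4, (4, 4), cross_lagged=True, concomitant=True)
        vals = {**self._series_theta(malt, 0), **self._series_theta(malt, 1)}
        for t in range(1, 4):
            vals[f"conc[0][1][{t}]"] = 0.3
        th, _ = _theta(malt, **vals)
        mom = structural_moments(malt, th)
        # same-occasion cross covariance at t=2 (first AR step): conc itself
        assert mom.sigma_star[1, 5] == pytest.approx(0.3)
        # t=3: rho_a rho_b cov(t=2) + conc
        assert mom.sigma_star[2, 6] == pytest.approx(0.35 * 0.35 * 0.3 + 0.3)
        _, latent = simulate(
            SimScenario(malt, th, n=400000), seed=17, return_latent=True
        )
        emp = np.cov(latent.T)
        assert abs(emp[1, 5] - 0.3) < 0.012  # ~4 MC SE
        assert abs(emp[2, 6] - mom.sigma_star[2, 6]) < 0.015


class TestDegreesOfFreedom:
    @pytest.mark.parametrize(
        "family,par,T,C,kw,expected",
        [
            # counting oracle: stats = T(C-1) + T(T-1)/2 minus free parameters
            ("saturated", "alt1_inv", 6, 4, {}, 5),
            ("saturated", "alt2_inv", 6, 4, {}, 5),
            ("lgm", "standard", 4, 4, {"placement": "delta"}, 3),
            ("lgm", "standard", 4, 4, {"placement": "theta"}, 3),
            ("lgm", "alt1_inv", 4, 4, {"placement": "delta"}, 8),
            ("lgm", "alt1_inv", 4, 4, {"placement": "theta"}, 8),
            ("lgm", "alt2_inv", 4, 4, {"placement": "delta"}, 8),
            ("ar1", "standard", 5, 4, {}, 6),
            ("ar1", "alt1", 5, 4, {}, 6),
            ("ar1", "alt2", 5, 4, {}, 6),
            ("ar1", "alt1_inv", 5, 4, {}, 10),
            ("ar1", "alt2_inv", 5, 4, {}, 10),
            ("alt", "alt1_inv", 5, 4, {}, 7),
            ("alt", "alt2_inv", 5, 4, {}, 7),
        ],
    )
    def test_df_counting(self, family, par, T, C, kw, expected):
        assert count_df(build_spec(family, par, T, C, **kw)) == expected

    def test_binary_ar1_rows_share_df(self):
        dfs = {
            count_df(build_spec("ar1", p, 4, 2))
            for p in ["standard", "bin_myt", "bin_mm", "bin_joreskog"]
        }
        assert dfs == {3}

    def test_lgm_standard_vs_alternative_df_differ(self):
        std = count_df(build_spec("lgm", "standard", 4, 4))
        alt = count_df(build_spec("lgm", "alt1_inv", 4, 4))
        assert std != alt

    def test_stationarity_constraints_add_df_one_per_equality(self):
        free = build_spec("ar1", "standard", 5, 4)
        stat = build_spec("ar1", "standard", 5, 4, stationary=True)
        # rho_2 = .. = rho_5 collapses T-2 = 3 parameters into equalities
        assert count_df(stat) - count_df(free) == 3


class TestIdentification:
    def test_alt_needs_five_waves(self):
        assert check_identification(build_spec("alt", "alt1_inv", 5, 4), n_draws=4)["identified"]
        rep4 = check_identification(build_spec("alt", "alt1_inv", 4, 4), n_draws=4)
        assert not rep4["identified"]
        assert rep4["null_space"]  # reports the trading-off parameters

    @pytest.mark.parametrize(
        "family,par,kw",
        [
            ("lgm", "standard", {"placement": "delta"}),
            ("lgm", "standard", {"placement": "theta"}),
            ("lgm", "alt1_inv", {"placement": "delta"}),
            ("lgm", "alt1_inv", {"placement": "theta"}),
            ("lgm", "alt2_inv", {"placement": "delta"}),
            ("ar1", "standard", {}),
            ("ar1", "alt1_inv", {}),
            ("ar1", "alt2_inv", {}),
        ],
    )
    def test_lgm_and_ar1_identified_at_four_waves(self, family, par, kw):
        assert check_identification(build_spec(family, par, 4, 4, **kw), n_draws=4)["identified"]


class TestSpecErrors:
    def test_alt2_with_binary_only_panel(self):
        with pytest.raises(SpecError, match="binary"):
            build_spec("lgm", "alt2", 4, 2)

    def test_delta_placement_rejected_with_autoregression(self):
        with pytest.raises(SpecError):
            build_spec("ar1", "alt1_inv", 4, 4, placement="delta")

    def test_lgm_is_univariate(self):
        with pytest.raises(SpecError):
            build_spec("lgm", "standard", 4, (4, 4))


def test_recovery_is_exact_on_manifold(rng):
    for family, par, T, C, kw in [
        ("saturated", "alt1_inv", 5, 4, {}),
        ("lgm", "alt1_inv", 4, 4, {"placement": "theta"}),
        ("ar1", "standard", 5, 4, {}),
        ("ar1", "bin_mm", 5, 2, {}),
    ]:
        spec = build_spec(family, par, T, C, **kw)
        th = sample_admissible_theta(spec, rng)
        mom = structural_moments(spec, th)
        d = np.sqrt(np.diag(mom.sigma_star))
        Tn = spec.T
        std_tau = [
            (mom.tau[v] - mom.mu_star[v * Tn : (v + 1) * Tn, None])
            / d[v * Tn : (v + 1) * Tn, None]
            for v in range(spec.V)
        ]
        R = mom.sigma_star / np.outer(d, d)
        th2 = recover_params(spec, std_tau, R)
        np.testing.assert_allclose(
            model_stats(spec, th), model_stats(spec, th2), atol=1e-12
        )
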