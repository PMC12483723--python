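"""Stage-1 layer: thresholds, polychorics, parameterization maps, invariance."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import multivariate_normal

from ordalt.auxiliary import (
    AuxiliaryEstimate,
    build_auxiliary,
    estimate_thresholds,
    invariance_ratio_diagnostic,
    polychoric_rho,
    reparameterize,
)
from ordalt.auxiliary import test_threshold_invariance as invariance_fit
from ordalt.bvn import rectangle_probs
from ordalt.models import Parameterization as P, SpecError
from ordalt.panel import MarginTable, panel_from_array
from ordalt.estimation import compute_sample_stats, dwls_fit


def _margin(counts):
    counts = np.atleast_2d(np.asarray(counts))
    return MarginTable(counts=counts, n=int(counts[0].sum()))


class TestThresholds:
    def test_binary_median_split(self):
        ts = estimate_thresholds(_margin([[5, 5]]))
        assert ts.tau[0, 0] == pytest.approx(0.0)

    def test_quartile_categories_match_normal_quantiles(self):
        ts = estimate_thresholds(_margin([[25, 25, 25, 25]]))
        np.testing.assert_allclose(ts.tau[0], [ndtri(0.25), 0.0, ndtri(0.75)], atol=1e-12)

    def test_empty_extreme_category_flagged_infinite(self):
        ts = estimate_thresholds(_margin([[10, 0]]))
        assert ts.tau[0, 0] == np.inf
        assert ts.flags

    def test_empty_interior_category_flagged_degenerate(self):
        ts = estimate_thresholds(_margin([[4, 0, 6]]))
        assert "tied" in ts.flags[0]
        cuts = ts.cuts(0)
        with pytest.raises(ValueError):
            polychoric_rho(np.ones((3, 3)), cuts, cuts)


class TestPolychoric:
    def test_independence_table_gives_zero(self):
        marg = np.array([0.2, 0.3, 0.5])
        table = np.outer(marg, marg) * 1000
        cuts = np.concatenate([[-np.inf], ndtri(np.cumsum(marg))[:-1], [np.inf]])
        rho, flags = polychoric_rho(table, cuts, cuts)
        assert rho == pytest.approx(0.0, abs=2e-3)

    def test_diagonal_2x2_hits_positive_boundary(self):
        cuts = np.array([-np.inf, 0.0, np.inf])
        rho, flags = polychoric_rho(np.diag([50, 50]), cuts, cuts)
        assert rho > 0.999
        assert any("boundary" in f for f in flags)

    def test_monte_carlo_recovery_rho_half(self):
        rng = np.random.default_rng(12)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=10000)
        cuts = np.array([-np.inf, -0.6745, 0.0, 0.6745, np.inf])
        x = np.digitize(z[:, 0], cuts[1:-1])
        y = np.digitize(z[:, 1], cuts[1:-1])
        table = np.zeros((4, 4))
        np.add.at(table, (x, y), 1)
        tx = estimate_thresholds(_margin([np.bincount(x, minlength=4)])).cuts(0)
        ty = estimate_thresholds(_margin([np.bincount(y, minlength=4)])).cuts(0)
        rho, _ = polychoric_rho(table, tx, ty)
        assert rho == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        true_rho = rng.uniform(-0.8, 0.8)
        cuts = np.concatenate([[-np.inf], np.sort(rng.normal(size=3)), [np.inf]])
        probs = rectangle_probs(cuts, cuts, true_rho)
        table = rng.multinomial(2000, probs.ravel()).reshape(4, 4)

        def loglik(r):
            p = np.maximum(rectangle_probs(cuts, cuts, r), 1e-12)
            return np.sum(table * np.log(p))

        grid = np.linspace(-0.999, 0.999, 4001)
        ll = np.array([loglik(r) for r in grid])
        best = grid[np.argmax(ll)]
        fine = np.linspace(best - 1e-3, best + 1e-3, 2001)
        best = fine[np.argmax([loglik(r) for r in fine])]
        rho, _ = polychoric_rho(table, cuts, cuts)
        assert rho == pytest.approx(best, abs=1e-4)


class TestParameterizationMaps:
    @pytest.fixture(scope="class")
    def panel(self):
        from ordalt.models import build_spec, sample_admissible_theta
        from ordalt.simulate import SimScenario, simulate

        gen = build_spec("saturated", "standard", 4, 4)
        th = sample_admissible_theta(gen, np.random.default_rng(8))
        return simulate(SimScenario(gen, th, n=3000), seed=8)

    def test_standard_row_is_zero_one_correlation(self, panel):
        aux = build_auxiliary(panel, P.STANDARD)
        assert np.all(aux.mu_star == 0) and np.all(aux.sigma_star == 1)
        assert aux.is_correlation

    def test_alt1_first_occasion_matches_standard(self, panel):
        std = build_auxiliary(panel, P.STANDARD)
        alt1 = build_auxiliary(panel, P.ALT1)
        assert alt1.mu_star[0, 0] == 0 and alt1.sigma_star[0, 0] == 1
        np.testing.assert_allclose(alt1.thresholds[0].tau[0], std.thresholds[0].tau[0])

    def test_alt2_closed_form(self):
        # standard thresholds (-0.5, 0.5, 1.0): sd = 1/(tau2 - tau1) = 1,
        # mu = -tau1 * sd = 0.5, remaining threshold shifts to 1.5
        from ordalt.models import _scales_from_std

        mu, sd, tmod = _scales_from_std(P.ALT2, np.array([[-0.5, 0.5, 1.0]]))
        assert sd[0] == pytest.approx(1.0)
        assert mu[0] == pytest.approx(0.5)
        np.testing.assert_allclose(tmod[0], [0.0, 1.0, 1.5])

    @pytest.mark.parametrize("target", [P.ALT1, P.ALT2])
    def test_round_trip_is_identity(self, panel, target):
        std = build_auxiliary(panel, P.STANDARD)
        alt = reparameterize(std, target)
        back = reparameterize(alt, P.STANDARD)
        np.testing.assert_allclose(back.P_star, std.P_star, atol=1e-10)
        for v in range(panel.V):
            np.testing.assert_allclose(
                back.thresholds[v].tau, std.thresholds[v].tau, atol=1e-10
            )

    def test_cell_probabilities_invariant_across_rows(self, panel):
        # P(y = c) from (tau, mu, sd) identical under every just-identified row
        from scipy.special import ndtr

        rows = [P.STANDARD, P.ALT1, P.ALT2]
        probs = []
        for row in rows:
            aux = build_auxiliary(panel, row)
            z = (aux.thresholds[0].tau - aux.mu_star[0][:, None]) / aux.sigma_star[0][:, None]
            probs.append(ndtr(z))
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-10)
        np.testing.assert_allclose(probs[0], probs[2], atol=1e-10)

    def test_mapping_into_invariance_row_is_refused(self, panel):
        std = build_auxiliary(panel, P.STANDARD)
        with pytest.raises(SpecError):
            reparameterize(std, P.ALT1_INV)

    def test_alt2_requires_three_categories(self):
        panel = panel_from_array(np.tile([0, 1, 0, 1], (30, 1)), T=4, C=2)
        with pytest.raises(SpecError):
            build_auxiliary(panel, P.ALT2)


class TestInvarianceDiagnostics:
    def _aux_with_thresholds(self, tau):
        tau = np.asarray(tau, float)
        T, K = tau.shape
        from ordalt.auxiliary import ThresholdSet

        return AuxiliaryEstimate(
            thresholds=[ThresholdSet(tau=tau)],
            mu_star=np.zeros((1, T)),
            sigma_star=np.ones((1, T)),
            P_star=np.eye(T),
            parameterization=P.STANDARD,
            T=T,
            C=(K + 1,),
        )

    def test_identical_thresholds_give_unit_ratios(self):
        aux = self._aux_with_thresholds([[-1.0, 0.0, 1.0]] * 3)
        rep = invariance_ratio_diagnostic(aux)
        for ratios in rep[0]["ratios"].values():
            np.testing.assert_allclose(ratios, 1.0)
        assert not rep[0]["inconsistent_occasion_pairs"]

    def test_scaled_shifted_thresholds_keep_equal_ratios(self):
        base = np.array([-1.0, 0.0, 1.0])
        aux = self._aux_with_thresholds([base, 2 * base + 0.3])
        rep = invariance_ratio_diagnostic(aux)
        ratios = rep[0]["ratios"][(0, 1)]
        np.testing.assert_allclose(ratios, 0.5)
        assert not rep[0]["inconsistent_occasion_pairs"]

    def test_single_perturbed_threshold_raises_flag(self):
        base = np.array([-1.0, 0.0, 1.0])
        tau2 = base.copy()
        tau2[1] = 0.5
        aux = self._aux_with_thresholds([base, tau2])
        rep = invariance_ratio_diagnostic(aux)
        assert (0, 1) in rep[0]["inconsistent_occasion_pairs"]

    def test_binary_diagnostic_undefined(self):
        aux = self._aux_with_thresholds([[0.3], [0.4]])
        with pytest.raises(SpecError):
            invariance_ratio_diagnostic(aux)


class TestInvarianceTest:
    @pytest.fixture(scope="class")
    def invariant_panel(self):
        # truly invariant thresholds: saturated process with constant tau
        from ordalt.models import build_spec
        from ordalt.simulate import SimScenario, simulate

        spec = build_spec("saturated", "alt1_inv", 6, 4)
        theta = np.zeros(spec.n_free)
        idx = {n: k for k, n in enumerate(spec.param_names)}
        for c, val in enumerate([-0.7, 0.2, 1.1]):
            theta[idx[f"tau[0][{c}]"]] = val
        for t in range(1, 6):
            theta[idx[f"mu[0][{t}]"]] = 0.05 * t
            theta[idx[f"sigma2[0][{t}]"]] = 1.0 + 0.1 * t
        for i in range(6):
            for j in range(i + 1, 6):
                theta[idx[f"r[{i}][{j}]"]] = 0.45 ** abs(i - j)
        return simulate(SimScenario(spec, theta, n=5000), seed=99)

    def test_df_matches_counting_oracle(self, invariant_panel):
        fit = invariance_fit(invariant_panel, P.ALT1_INV)
        # T(C-1) - [(C-1) + 2(T-1)] = 18 - 13 = 5
        assert fit.df == 5

    def test_alt1_and_alt2_invariance_fits_agree(self, invariant_panel):
        f1 = invariance_fit(invariant_panel, P.ALT1_INV)
        f2 = invariance_fit(invariant_panel, P.ALT2_INV)
        assert f1.df == f2.df
        assert abs(f1.n * f1.F_min - f2.n * f2.F_min) < 1e-6
        assert f1.chi2_adj == pytest.approx(f2.chi2_adj, abs=1e-6)

    def test_true_invariance_is_not_rejected(self, invariant_panel):
        fit = invariance_fit(invariant_panel, P.ALT1_INV)
        assert fit.p_value > 0.05

    def test_binary_panel_refused(self):
        panel = panel_from_array(np.tile([0, 1, 0], (30, 1)), T=3, C=2)
        with pytest.raises(SpecError):
            invariance_fit(panel, P.ALT1_INV)

    def test_constrained_build_reports_fit(self, invariant_panel):
        aux = build_auxiliary(invariant_panel, P.ALT1_INV)
        assert aux.fit is not None and aux.fit.df == 5
        # invariant thresholds: one row repeated
        np.testing.assert_allclose(
            aux.thresholds[0].tau, np.tile(aux.thresholds[0].tau[0], (6, 1))
        )
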