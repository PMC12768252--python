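"""Edge-tension regression: exact round trips, noise recovery, biphasic fit."""

import math

import numpy as np
import pytest

from guvkinetics import (
    MembraneConstants,
    PoreModelParams,
    TensionRatePoint,
    bootstrap_gamma,
    ExperimentDesign,
    aggregate_rate,
    fit_biphasic,
    fit_edge_tension,
    gamma_confidence_interval,
    predict_rate_curve,
    rupture_rate,
    simulate_tension_grid,
)

SIGMAS = [5e-3, 6e-3, 7e-3, 8e-3, 10e-3]
B = 1.76e-3
CONST = MembraneConstants()


def noiseless_points(gamma, A, sigmas=SIGMAS, noise=None, rng=None):
    pts = []
    for s in sigmas:
        k = rupture_rate(PoreModelParams(Gamma=gamma, sigma_e=s, B=B, A=A), CONST)
        if noise is not None:
            k *= math.exp(rng.normal(0.0, noise))
        pts.append(TensionRatePoint(sigma_e=s, k_r=k, k_r_se=0.1 * k))
    return pts


class TestFitEdgeTension:
    def test_exact_recovery_on_noiseless_rates(self):
        fit = fit_edge_tension(noiseless_points(5e-12, 100.0), B=B, constants=CONST)
        assert fit.Gamma == pytest.approx(5e-12, rel=1e-12)
        assert fit.A == pytest.approx(100.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-math.pi * (5e-12) ** 2 / CONST.kBT, rel=1e-12)

    def test_mean_recovery_under_lognormal_noise(self):
        rng = np.random.default_rng(123)
        gammas = []
        for _ in range(500):
            pts = noiseless_points(5e-12, 100.0, noise=0.1, rng=rng)
            gammas.append(fit_edge_tension(pts, B=B, constants=CONST).Gamma)
        assert np.mean(gammas) == pytest.approx(5e-12, rel=0.02)

    def test_increasing_rates_rejected_as_nonphysical(self):
        # rates increasing in 1/(sigma+B): slope would come out positive
        pts = [
            TensionRatePoint(sigma_e=5e-3, k_r=0.5),
            TensionRatePoint(sigma_e=7e-3, k_r=0.1),
            TensionRatePoint(sigma_e=10e-3, k_r=0.01),
        ]
        with pytest.raises(ValueError, match="non-physical"):
            fit_edge_tension(pts, B=B, constants=CONST)

    def test_too_few_tensions_rejected(self):
        pts = noiseless_points(5e-12, 100.0, sigmas=[5e-3, 8e-3])
        with pytest.raises(ValueError, match="3 distinct"):
            fit_edge_tension(pts, B=B, constants=CONST)

    def test_mixed_peptide_contents_rejected(self):
        pts = noiseless_points(5e-12, 100.0)
        bad = pts[:-1] + [
            TensionRatePoint(sigma_e=10e-3, k_r=pts[-1].k_r, gra_mole_percent=3.0)
        ]
        with pytest.raises(ValueError, match="mix"):
            fit_edge_tension(bad, B=B, constants=CONST)

    def test_gamma_invariant_to_frequency_factor(self):
        g1 = fit_edge_tension(noiseless_points(6e-12, 50.0), B=B, constants=CONST).Gamma
        g2 = fit_edge_tension(noiseless_points(6e-12, 5000.0), B=B, constants=CONST).Gamma
        assert g1 == pytest.approx(g2, rel=1e-10)

    def test_weighted_fit_matches_unweighted_on_noiseless_data(self):
        pts = noiseless_points(6e-12, 100.0)
        fu = fit_edge_tension(pts, B=B, constants=CONST, weighting="none")
        fw = fit_edge_tension(pts, B=B, constants=CONST, weighting="inverse-variance")
        assert fw.Gamma == pytest.approx(fu.Gamma, rel=1e-10)


class TestGammaUncertainty:
    def test_delta_se_within_20pct_of_bootstrap(self):
        # a single 5-tension fit leaves only 3 residual dof, so the delta SE
        # is itself noisy; averaging both estimators over replicate designs
        # gives the well-conditioned comparison
        sigmas = [1.5e-3, 1.8e-3, 2.1e-3, 2.4e-3, 2.8e-3]
        deltas, boots = [], []
        for rep in range(30):
            design = ExperimentDesign(
                gra_mole_percents=[0.0],
                sigma_targets=sigmas,
                true_gamma=6e-12,
                true_A=100.0,
                n_vesicles_per_trial=15,
                n_trials=3,
                seed=300 + rep,
            )
            records, _ = simulate_tension_grid(design)
            pts = []
            for s in sigmas:
                grp = [r for r in records if r.sigma_e == s]
                fit = aggregate_rate(grp, method="mle", pooled=True)
                pts.append(TensionRatePoint(sigma_e=s, k_r=fit.k_r, k_r_se=fit.k_r_se))
            efit = fit_edge_tension(pts, B=design.B, constants=CONST)
            boot = bootstrap_gamma(
                records, B=design.B, constants=CONST, n_boot=200, seed=900 + rep,
                estimator="mle",
            )
            deltas.append(efit.Gamma_se)
            boots.append(float(boot.std(ddof=1)))
        assert np.mean(deltas) == pytest.approx(np.mean(boots), rel=0.2)

    def test_confidence_interval_brackets_point_estimate(self):
        fit = fit_edge_tension(noiseless_points(6e-12, 100.0), B=B, constants=CONST)
        lo, hi = gamma_confidence_interval(fit, 0.95)
        assert lo <= fit.Gamma <= hi


class TestEndToEndRecovery:
    def test_generating_gamma_within_ci_in_most_replicates(self):
        # simulate the full design (15 vesicles x 3 trials x 5 tensions) and
        # check the 95% CI covers the generating edge tension >= 90% of runs
        sigmas = [1.5e-3, 1.8e-3, 2.1e-3, 2.4e-3, 2.8e-3]
        cover = 0
        n_rep = 100
        for rep in range(n_rep):
            design = ExperimentDesign(
                gra_mole_percents=[0.0],
                sigma_targets=sigmas,
                true_gamma=6e-12,
                true_A=100.0,
                n_vesicles_per_trial=15,
                n_trials=3,
                seed=rep,
            )
            records, _ = simulate_tension_grid(design)
            pts = []
            for s in sigmas:
                grp = [r for r in records if r.sigma_e == s]
                fit = aggregate_rate(grp, method="ls", pooled=True)
                pts.append(TensionRatePoint(sigma_e=s, k_r=fit.k_r, k_r_se=fit.k_r_se))
            efit = fit_edge_tension(pts, B=design.B, constants=CONST)
            lo, hi = gamma_confidence_interval(efit, 0.95)
            cover += lo <= 6e-12 <= hi
        assert cover / n_rep >= 0.90


class TestFitBiphasic:
    def test_exact_quadratic_through_three_points(self):
        # Gamma(phi) = 9.6 - 50 phi + 400 phi^2 pN, i.e. a = -50, b = -400 pN
        phi = np.array([0.0, 0.02, 0.05])
        gamma = (9.6 - 50 * phi + 400 * phi**2) * 1e-12
        fit = fit_biphasic(phi, gamma)
        assert fit.Gamma0 == pytest.approx(9.6e-12, rel=1e-9)
        assert fit.a == pytest.approx(-50e-12, rel=1e-9)
        assert fit.b == pytest.approx(-400e-12, rel=1e-9)

    def test_fourth_consistent_point_changes_nothing(self):
        phi = np.array([0.0, 0.02, 0.05, 0.03])
        gamma = (9.6 - 50 * phi + 400 * phi**2) * 1e-12
        fit = fit_biphasic(phi, gamma)
        assert fit.a == pytest.approx(-50e-12, rel=1e-8)
        assert fit.residual_sum_of_squares == pytest.approx(0.0, abs=1e-40)

    def test_minimized_rss_matches_grid_refinement(self):
        # seven non-quadratic (phi, Gamma) pairs: a biphasic edge-tension
        # profile with a minimum at intermediate peptide content
        phi = np.array([0.0, 0.0001, 0.0005, 0.001, 0.01, 0.03, 0.05])
        gamma = np.array([9.6, 5.6, 3.4, 4.5, 6.5, 6.3, 6.8]) * 1e-12
        fit = fit_biphasic(phi, gamma)
        X = np.column_stack([np.ones_like(phi), phi, phi**2])

        def rss(c0, c1, c2):
            r = gamma - (c0 + c1 * phi + c2 * phi**2)
            return float(r @ r)

        best = rss(fit.Gamma0, fit.a, -fit.b)
        # brute-force refinement around the solution must not find better
        rng = np.random.default_rng(9)
        for _ in range(2000):
            d = rng.normal(scale=[1e-13, 1e-11, 1e-10])
            assert rss(fit.Gamma0 + d[0], fit.a + d[1], -fit.b + d[2]) >= best - 1e-38

    def test_too_few_or_collinear_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_biphasic([0.0, 0.05], [9e-12, 4e-12])
        with pytest.raises(ValueError):
            fit_biphasic([0.0, 0.0, 0.0], [9e-12, 4e-12, 5e-12])

    def test_phi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_biphasic([0.0, 0.5, 1.5], [9e-12, 4e-12, 5e-12])


class TestPredictRateCurve:
    def test_reproduces_fitted_line_at_fit_points(self):
        pts = noiseless_points(5e-12, 100.0)
        fit = fit_edge_tension(pts, B=B, constants=CONST)
        preds = predict_rate_curve(fit, SIGMAS, B=B, constants=CONST)
        for p, pred in zip(pts, preds):
            assert math.log(pred) == pytest.approx(math.log(p.k_r), abs=1e-10)

    def test_strictly_increasing_in_tension(self):
        fit = fit_edge_tension(noiseless_points(5e-12, 100.0), B=B, constants=CONST)
        preds = predict_rate_curve(fit, np.linspace(3e-3, 12e-3, 50), B=B, constants=CONST)
        assert np.all(np.diff(preds) > 0)

    def test_refit_of_predictions_is_idempotent(self):
        fit = fit_edge_tension(noiseless_points(5e-12, 100.0), B=B, constants=CONST)
        grid = np.array([4e-3, 5.5e-3, 7e-3, 9e-3])
        preds = predict_rate_curve(fit, grid, B=B, constants=CONST)
        refit = fit_edge_tension(
            [TensionRatePoint(sigma_e=s, k_r=k) for s, k in zip(grid, preds)],
            B=B,
            constants=CONST,
        )
        assert refit.Gamma == pytest.approx(fit.Gamma, rel=1e-10)
        assert refit.A == pytest.approx(fit.A, rel=1e-8)
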