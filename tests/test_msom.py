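import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

import camsom
from camsom import (
    CommunityHyperparams,
    MCMCConfig,
    ModelSpec,
    SimulationScenario,
    cell_loglik,
    detection_prob,
    fit_msom,
    gelman_rubin,
    latent_abundance_pmf,
    marginal_cell_loglik,
)
from camsom.histories import DetectionHistory


class TestDetectionProb:
    @pytest.mark.parametrize(
        "r,z,expected", [(0.3, 0, 0.0), (0.3, 1, 0.3), (0.5, 2, 0.75), (1.0, 3, 1.0), (0.0, 7, 0.0)]
    )
    def test_known_values(self, r, z, expected):
        assert detection_prob(r, z) == pytest.approx(expected, abs=1e-15)

    def test_monotone_in_r_and_z_over_grid(self):
        rs = np.linspace(0, 1, 21)
        zs = np.arange(0, 30)
        p = detection_prob(rs[:, None], zs[None, :])
        assert (np.diff(p, axis=0) >= -1e-15).all()  # non-decreasing in r
        assert (np.diff(p, axis=1) >= -1e-15).all()  # non-decreasing in Z
        assert (p >= 0).all() and (p <= 1).all()
        # p -> 1 as Z grows for r > 0
        assert detection_prob(0.2, 500) == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            detection_prob(1.2, 1)
        with pytest.raises(ValueError):
            detection_prob(0.5, -1)


class TestCellLoglik:
    def test_empty_site_certain_nondetection(self):
        assert cell_loglik(0, 10, 0.7, 0) == 0.0

    def test_closed_form_binomial(self):
        # Y=3, V=10, r=0.5, Z=1 -> p=0.5
        expected = math.log(math.comb(10, 3)) + 10 * math.log(0.5)
        assert cell_loglik(3, 10, 0.5, 1) == pytest.approx(expected, abs=1e-12)

    def test_impossible_event_is_neg_inf(self):
        assert cell_loglik(1, 10, 0.4, 0) == -np.inf

    def test_domain_violation_raises(self):
        with pytest.raises(ValueError):
            cell_loglik(11, 10, 0.4, 1)


class TestMarginalCellLoglik:
    def test_certain_detection_reduces_to_poisson_zero_mass(self):
        for lam in (0.3, 1.0, 2.5):
            assert marginal_cell_loglik(0, 1, 1.0, lam, z_max=60) == pytest.approx(
                -lam, abs=1e-10
            )

    def test_monotone_nondecreasing_in_z_max(self):
        vals = [marginal_cell_loglik(3, 10, 0.2, 4.0, z_max=z) for z in (2, 5, 10, 30, 60)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] - vals[-2] < 1e-9  # converged

    def test_truncation_warning(self):
        with pytest.warns(UserWarning, match="tail mass"):
            marginal_cell_loglik(0, 5, 0.2, 30.0, z_max=35)

    def test_monte_carlo_oracle_single_case(self):
        Y, V, r, lam = 2, 10, 0.3, 1.5
        rng = np.random.default_rng(5)
        Z = rng.poisson(lam, size=200_000)
        probs = np.exp(cell_loglik(Y, V, r, Z))
        est, se = probs.mean(), probs.std(ddof=1) / np.sqrt(Z.size)
        assert np.exp(marginal_cell_loglik(Y, V, r, lam, 80)) == pytest.approx(
            est, abs=3 * se
        )


class TestGelmanRubin:
    def test_matches_published_formula_arithmetic(self):
        x = np.array(
            [[1.0, 2, 3, 4, 5, 6, 7, 8, 9, 10], [2.0, 4, 3, 5, 4, 6, 5, 7, 6, 8]]
        )
        m, n = x.shape
        W = (x[0].var(ddof=1) + x[1].var(ddof=1)) / 2
        B_over_n = np.var([x[0].mean(), x[1].mean()], ddof=1)
        vhat = (n - 1) / n * W + B_over_n
        expected = math.sqrt((m + 1) / m * vhat / W - (n - 1) / (m * n))
        assert gelman_rubin(x) == pytest.approx(expected, abs=1e-12)

    def test_iid_chains_converge_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 10_000))
        assert gelman_rubin(x) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 500)) + np.array([[-10.0], [10.0]])
        assert gelman_rubin(x) > 1.1

    def test_zero_within_chain_variance_warns_not_nan(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            out = gelman_rubin(np.ones((2, 20)))
        assert out == 1.0
        with pytest.warns(UserWarning):
            out = gelman_rubin(np.vstack([np.zeros(20), np.ones(20)]))
        assert np.isinf(out)

    def test_agrees_with_arviz_on_converged_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 2000))
        ours = gelman_rubin(x)
        theirs = float(az.rhat(az.convert_to_dataset(x))["x"].values)
        # different estimators (arviz is rank-normalized split-Rhat), but both
        # must sit hard against 1 for iid chains
        assert abs(ours - theirs) < 0.01


def _tiny_history():
    Y = np.array([[2, 0, 4], [1, 3, 0]])
    V = np.array([5, 5, 5])
    stations = pd.DataFrame(
        {
            "station_id": ["A", "B", "C"],
            "dogs_allowed": [0, 1, 1],
            "distance_km": [1.0, 2.0, 4.0],
        }
    )
    stations["distance_scaled"] = camsom.scale_distances(stations["distance_km"])
    hist = DetectionHistory(Y=Y, V=V, species=["s1", "s2"], stations=["A", "B", "C"])
    return hist, stations


class TestSampler:
    def test_fixed_seed_fixes_draws_bit_for_bit(self):
        hist, stations = _tiny_history()
        spec = ModelSpec(n_aug=2, z_max=20)
        cfg = MCMCConfig(n_chains=2, n_iter=300, burn_in=100, thin=2, seed=11)
        a = fit_msom(hist, stations, spec, cfg)
        b = fit_msom(hist, stations, spec, cfg)
        np.testing.assert_array_equal(a.coef, b.coef)
        np.testing.assert_array_equal(a.Z, b.Z)
        for k in a.hyper:
            np.testing.assert_array_equal(a.hyper[k], b.hyper[k])

    def test_latent_updates_match_exact_enumeration(self):
        """Rao-Blackwell consistency: the empirical distribution of stored Z
        draws must match the average of the exact per-draw full-conditional
        pmfs computed by independent enumeration."""
        hist, stations = _tiny_history()
        spec = ModelSpec(n_aug=0, z_max=15, adapt_z_max=False)
        cfg = MCMCConfig(n_chains=2, n_iter=6000, burn_in=1000, thin=1, seed=3)
        draws = fit_msom(hist, stations, spec, cfg)
        X = np.column_stack(
            [
                np.ones(3),
                stations["distance_scaled"],
                stations["dogs_allowed"].astype(float),
                stations["distance_scaled"] * stations["dogs_allowed"],
            ]
        )
        C, D = draws.w.shape[:2]
        for (i, j) in [(0, 0), (1, 1), (0, 2)]:
            pmf = np.zeros(16)
            for c in range(C):
                for d in range(D):
                    lam = float(np.exp(draws.coef[c, d, i] @ X[j]))
                    r = float(expit(draws.const[c, d, i]))
                    pmf += latent_abundance_pmf(hist.Y[i, j], hist.V[j], r, lam, 15)
            pmf /= C * D
            emp = np.bincount(draws.Z[:, :, i, j].reshape(-1), minlength=16) / (C * D)
            assert np.abs(emp - pmf).max() < 0.02

    def test_augmented_allzero_species_inclusion_below_omega(self, short_model1_fit):
        draws = short_model1_fit
        aug = draws.augmented
        mean_w_aug = draws.w[:, :, aug].mean()
        mean_omega = draws.hyper["omega"].mean()
        assert mean_w_aug < mean_omega

    def test_single_species_posterior_matches_marginal_mle(self):
        # one species, effect-free truth, many stations and occasions: the
        # posterior of (log lambda, logit r) should concentrate near the
        # maximizer of the Z-marginalized likelihood.
        hp = CommunityHyperparams(
            mu_beta=(0.7, 0.0, 0.0, 0.0), sigma_beta=(0, 0, 0, 0),
            mu_detect=logit(0.3), sigma_detect=0.0,
        )
        sc = SimulationScenario(seed=21, n_species=1, n_stations_per_stratum=20,
                                hyperparams=hp)
        stations = camsom.simulate_stations(sc)
        params = camsom.draw_species_params(hp, 1, 2)
        Z = camsom.simulate_abundance(params, stations, 3)
        hist = camsom.simulate_histories(Z, params, 25, 4)
        Y, V = hist.Y[0], 25

        def nll(theta):
            loglam, logitr = theta
            return -sum(
                marginal_cell_loglik(int(y), V, float(expit(logitr)),
                                     float(np.exp(loglam)), 60)
                for y in Y
            )

        mle = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead").x
        cfg = MCMCConfig(n_chains=2, n_iter=3000, burn_in=1500, thin=3, seed=5)
        draws = fit_msom(hist, stations, ModelSpec(n_aug=0, z_max=60), cfg)
        b0 = draws.coef[:, :, 0, 0].reshape(-1)
        det = draws.const[:, :, 0].reshape(-1)
        assert abs(b0.mean() - mle[0]) < 3 * b0.std(ddof=1)
        assert abs(det.mean() - mle[1]) < 3 * det.std(ddof=1)

    def test_null_community_shrinks_coefficient_spread(self):
        # data simulated with exchangeable species (zero hyper-SD on the
        # distance effect) should yield a visibly smaller posterior for that
        # community SD than data with strong heterogeneity
        base = dict(mu_beta=(0.3, 0.0, 0.0, 0.0), mu_detect=-1.0, sigma_detect=0.3)
        cfg = MCMCConfig(n_chains=2, n_iter=1200, burn_in=600, thin=3, seed=6)
        meds = {}
        for label, sd in (("null", 0.0), ("hetero", 1.2)):
            hp = CommunityHyperparams(sigma_beta=(0.4, sd, 0.2, 0.1), **base)
            ds = camsom.simulate_dataset(
                SimulationScenario(seed=31, n_species=20, hyperparams=hp)
            )
            draws = fit_msom(ds.history, ds.stations, ModelSpec(n_aug=5), cfg)
            meds[label] = np.median(draws.hyper["sigma_distance"])
        assert meds["null"] < meds["hetero"]

    def test_save_load_round_trip(self, short_model1_fit, tmp_path):
        path = tmp_path / "draws.npz"
        short_model1_fit.save(path)
        back = type(short_model1_fit).load(path)
        np.testing.assert_array_equal(back.Z, short_model1_fit.Z)
        np.testing.assert_array_equal(back.coef, short_model1_fit.coef)
        assert back.species == short_model1_fit.species
        assert back.variant == short_model1_fit.variant
        for k, v in short_model1_fit.hyper.items():
            np.testing.assert_array_equal(back.hyper[k], v)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(n_chains=1)
        with pytest.raises(ValueError):
            ModelSpec(variant="both")
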