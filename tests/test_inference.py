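"""Sampler correctness, convergence diagnostics and posterior summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit, logit

from conftest import make_fake_fit
from cooccupy.covariates import DesignMatrix
from cooccupy.inference import (
    MCMCConfig,
    coefficient_contrast,
    fit,
    gelman_rubin,
    predict_detection,
    sif_curve,
    species_interaction_factor,
)
from cooccupy.model import HYPOTHESES, LikelihoodEngine
from cooccupy.records import DetectionHistory


class TestGelmanRubin:
    def test_iid_chains_near_one(self, rng):
        x = rng.normal(size=(4, 1000))
        assert gelman_rubin(x) <= 1.05

    def test_disjoint_chains_flag(self, rng):
        x = np.stack([rng.normal(0, 1, 500), rng.normal(50, 1, 500)])
        assert gelman_rubin(x) > 1.1

    def test_matches_between_within_formula(self, rng):
        x = rng.normal(size=(3, 100))
        halves = x.reshape(6, 50)
        W = halves.var(axis=1, ddof=1).mean()
        B = 50 * halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((50 - 1) / 50 * W + B / 50) / W)
        assert gelman_rubin(x) == pytest.approx(expected, abs=1e-12)

    def test_single_chain_is_domain_error(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.normal(size=(1, 100)))


class TestMCMCConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(seed=None)
        with pytest.raises(ValueError):
            MCMCConfig(seed=1, n_burnin=10, n_iter=10)
        with pytest.raises(ValueError):
            MCMCConfig(seed=1, thin=0)
        assert MCMCConfig.field_protocol(seed=1).n_retained == 10_000

    def test_estimator_requires_seed(self, small_sim):
        from cooccupy.inference import ConditionalTwoSpeciesOccupancy

        est = ConditionalTwoSpeciesOccupancy()
        with pytest.raises(ValueError, match="random_state"):
            est.fit(small_sim["dm"], (small_sim["hist_a"], small_sim["hist_b"]))


class TestFit:
    def test_fit_shapes_and_convergence(self, h2_fit):
        cfg = h2_fit.config
        C, S, d = h2_fit.draws.shape
        assert (C, S) == (cfg.n_chains, cfg.n_retained)
        assert d == HYPOTHESES["H2"].n_coef
        assert h2_fit.loglik.shape == (C, S, h2_fit.n_sites)
        assert h2_fit.rhat.shape == (d,)
        assert np.all(np.isfinite(h2_fit.rhat))

    def test_stored_pointwise_loglik_matches_recomputation(self, h2_fit, small_sim):
        """The saved pointwise matrix is the likelihood at the saved draws."""
        eng = LikelihoodEngine(
            small_sim["hist_a"], small_sim["hist_b"], small_sim["dm"], HYPOTHESES["H2"]
        )
        idx = [0, 7, 100]
        for i in idx:
            np.testing.assert_allclose(
                h2_fit.loglik[0, i], eng.pointwise(h2_fit.draws[0, i]), atol=1e-10
            )

    def test_all_missing_site_contributes_factor_one(self, small_sim):
        """Adding a never-surveyed site leaves the posterior bit-identical."""
        ha, hb, dm = small_sim["hist_a"], small_sim["hist_b"], small_sim["dm"]
        n, T = ha.matrix.shape

        def extend(h):
            return DetectionHistory(
                h.species,
                h.sites + ["Zpad"],
                np.vstack([h.matrix, np.full((1, T), np.nan)]),
                np.vstack([h.effort, np.zeros((1, T), dtype=int)]),
                h.occasion_length,
            )

        dm2 = DesignMatrix(
            site_ids=dm.site_ids + ["Zpad"],
            X_det=np.vstack([dm.X_det, np.zeros((1, 4))]),
            X_occ=np.vstack([dm.X_occ, np.zeros((1, 2))]),
            means=dm.means, sds=dm.sds,
        )
        cfg = MCMCConfig(seed=99, n_chains=2, n_iter=400, n_burnin=200, thin=2)
        f1 = fit((ha, hb), dm, "H2", cfg)
        f2 = fit((extend(ha), extend(hb)), dm2, "H2", cfg)
        np.testing.assert_array_equal(f1.draws, f2.draws)
        np.testing.assert_array_equal(f2.loglik[:, :, -1], 0.0)

    def test_prior_only_run_recovers_prior_moments(self, small_sim):
        cfg = MCMCConfig(seed=7, n_chains=3, n_iter=6000, n_burnin=2000, thin=2,
                         prior_sd=10.0, prior_only=True)
        f = fit((small_sim["hist_a"], small_sim["hist_b"]), small_sim["dm"], "H1", cfg)
        x = f.flat_draws
        assert abs(x.mean()) < 2.0
        assert 8.0 < x.std() < 12.0


class TestContrast:
    def test_identical_vectors_give_zero_and_none(self):
        d = np.zeros((30, HYPOTHESES["H2"].n_coef))
        f = make_fake_fit("H2", draws=d)
        c = coefficient_contrast(f, "RH")
        assert c.mean == 0.0 and c.label == "none"

    def test_interval_excluding_zero_is_significant(self, rng):
        hyp = HYPOTHESES["H2"]
        d = np.zeros((4000, hyp.n_coef))
        # pB intercept minus rB intercept centered near -1.28 with narrow spread
        d[:, 6 + 5] = rng.normal(-1.28, 0.4, 4000)  # pB_int (after psiA,psiB blocks + pA)
        f = make_fake_fit("H2", draws=d)
        c = coefficient_contrast(f, "intercept")
        assert c.label == "significant"
        assert c.bci95[1] < 0

    def test_bcis_are_empirical_quantiles(self, rng):
        hyp = HYPOTHESES["H2"]
        d = rng.normal(size=(500, hyp.n_coef))
        f = make_fake_fit("H2", draws=d)
        c = coefficient_contrast(f, "DR")
        diff = f.coef_draws("pB")[:, 1] - f.coef_draws("rB")[:, 1]
        np.testing.assert_allclose(c.bci95, np.quantile(diff, [0.025, 0.975]), atol=1e-12)
        np.testing.assert_allclose(c.bci85, np.quantile(diff, [0.075, 0.925]), atol=1e-12)

    def test_significance_labels_are_monotone(self, rng):
        """'significant' implies the 85% interval excludes zero too."""
        for _ in range(50):
            hyp = HYPOTHESES["H2"]
            d = rng.normal(rng.normal(0, 1), abs(rng.normal(0, 1)) + 0.1,
                           size=(200, hyp.n_coef))
            c = coefficient_contrast(make_fake_fit("H2", draws=d), "RC")
            if c.label == "significant":
                assert c.bci85[0] > 0 or c.bci85[1] < 0

    def test_h1_has_no_contrast(self):
        f = make_fake_fit("H1")
        with pytest.raises(ValueError):
            coefficient_contrast(f, "RH")


class TestPredictDetection:
    def test_mean_covariates_reduce_to_intercept(self, rng):
        d = rng.normal(size=(200, HYPOTHESES["H2"].n_coef))
        f = make_fake_fit("H2", draws=d)
        p = predict_detection(f, leopard_state="absent")
        np.testing.assert_allclose(p.draws, expit(f.coef_draws("pB")[:, 0]), atol=1e-14)

    def test_five_draw_hand_computation(self):
        hyp = HYPOTHESES["H2"]
        d = np.zeros((5, hyp.n_coef))
        # rB block is the last 5 columns: intercept 0.2*k, slope on DR = 1
        d[:, -5] = 0.2 * np.arange(5)
        d[:, -4] = 1.0
        f = make_fake_fit("H2", draws=d)
        x = np.array([0.5, 0.0, 0.0, 0.0])
        p = predict_detection(f, x, leopard_state="present")
        want = expit(0.2 * np.arange(5) + 0.5)
        np.testing.assert_allclose(p.draws, want, atol=1e-14)
        assert p.probability == pytest.approx(want.mean())

    def test_present_absent_difference_is_drawwise(self, h2_fit):
        a = predict_detection(h2_fit, leopard_state="present")
        b = predict_detection(h2_fit, leopard_state="absent")
        diff = a.draws - b.draws
        np.testing.assert_allclose(
            diff,
            expit(h2_fit.coef_draws("rBa")[:, 0]) - expit(h2_fit.coef_draws("pB")[:, 0]),
            atol=1e-14,
        )

    def test_raw_values_rejected(self, h2_fit):
        with pytest.raises(ValueError, match="unstandardized"):
            predict_detection(h2_fit, [1500.0, 2000.0, 1.5, 5.2])


class TestSIF:
    def test_equal_detection_probabilities_give_unity(self, rng):
        p = rng.random(100)
        psi = rng.random(100)
        np.testing.assert_allclose(species_interaction_factor(psi, p, p), 1.0, atol=1e-15)

    def test_dominant_certain_presence_gives_unity(self, rng):
        pB, rB = rng.random(50), rng.random(50)
        np.testing.assert_allclose(species_interaction_factor(1.0, pB, rB), 1.0, atol=1e-15)

    def test_worked_value(self):
        assert species_interaction_factor(0.5, 0.2, 0.4) == pytest.approx(4.0 / 3.0, abs=1e-15)

    def test_sign_tracks_detection_difference(self, rng):
        psi = rng.uniform(0.05, 0.95, 500)
        pB = rng.uniform(0.01, 0.99, 500)
        rB = rng.uniform(0.01, 0.99, 500)
        sif = species_interaction_factor(psi, pB, rB)
        np.testing.assert_array_equal(sif > 1, rB > pB)
        np.testing.assert_array_equal(sif < 1, rB < pB)

    def test_curve_from_posterior(self, h2_fit):
        curve = sif_curve(h2_fit, "RH", grid=np.linspace(-2, 2, 9))
        assert curve.covariate == "logRH"
        assert curve.grid.shape == curve.mean.shape == (9,)
        assert np.all(curve.mean > 0)
        assert np.all(curve.lo95 <= curve.mean) and np.all(curve.mean <= curve.hi95)

    def test_curve_rejects_h1(self):
        with pytest.raises(ValueError):
            sif_curve(make_fake_fit("H1"), "RH")
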