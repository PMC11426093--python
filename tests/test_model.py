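"""Likelihood core: link, exact marginalization, nesting, normalization."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.special import expit

from cooccupy.covariates import DesignMatrix
from cooccupy.model import (
    HYPOTHESES,
    LikelihoodEngine,
    ParamSet,
    dataset_log_likelihood,
    link_probabilities,
    site_log_likelihood,
)
from cooccupy.records import DetectionHistory


def _dm(rng, n=4):
    return DesignMatrix(
        site_ids=[f"S{i}" for i in range(n)],
        X_det=rng.normal(size=(n, 4)),
        X_occ=rng.normal(size=(n, 2)),
        means={}, sds={},
    )


def _params(hyp_id, rng=None, scale=1.5, fill=None):
    hyp = HYPOTHESES[hyp_id]
    coef = {}
    for name, kind in hyp.blocks():
        size = 3 if kind == "occ" else 5
        if fill is not None:
            coef[name] = np.full(size, float(fill))
        else:
            coef[name] = rng.normal(0, scale, size)
    return ParamSet(hypothesis=hyp, coef=coef)


def _hist(matrix, species="x"):
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    effort = np.where(np.isnan(m), 0, 10)
    return DetectionHistory(species, [f"S{i}" for i in range(m.shape[0])], m, effort)


def brute_site_loglik(pr, hA, hB, conditional):
    """Oracle: enumerate the four latent states and multiply occasion terms."""
    total = 0.0
    for zA, zB in itertools.product((0, 1), (0, 1)):
        w = (pr["psiA"] if zA else 1 - pr["psiA"]) * (pr["psiB"] if zB else 1 - pr["psiB"])
        lik = 1.0
        for a, b in zip(hA, hB):
            if math.isnan(a):
                continue
            pa = pr["pA"] * zA
            lik *= pa if a == 1 else 1 - pa
            if zA == 0:
                q = pr["pB"]
            elif conditional and a == 1:
                q = pr["rBA"]
            else:
                q = pr["rBa"]
            q *= zB
            lik *= q if b == 1 else 1 - q
        total += w * lik
    return math.log(total) if total > 0 else -math.inf


class TestLink:
    def test_zero_coefficients_give_half(self, rng):
        dm = _dm(rng)
        pr = link_probabilities(_params("H4", fill=0.0), dm)
        for v in pr.values():
            np.testing.assert_allclose(v, 0.5)

    def test_monotone_and_tied_roles_identical(self, rng):
        dm = _dm(rng)
        pr = link_probabilities(_params("H2", rng=rng), dm, site=1)
        assert pr["rBa"] == pr["rBA"]  # tied under H2
        p1 = link_probabilities(_params("H1", rng=rng), dm, site=0)
        assert p1["pB"] == p1["rBa"] == p1["rBA"]

    def test_matches_manual_inverse_logit(self, rng):
        dm = _dm(rng)
        ps = _params("H4", rng=rng)
        pr = link_probabilities(ps, dm, site=2)
        x = np.concatenate([[1.0], dm.X_det[2]])
        assert pr["pA"] == pytest.approx(float(expit(ps.coef["pA"] @ x)), abs=1e-14)
        z = np.concatenate([[1.0], dm.X_occ[2]])
        assert pr["psiB"] == pytest.approx(float(expit(ps.coef["psiB"] @ z)), abs=1e-14)


class TestSiteLikelihood:
    def test_one_occasion_both_detected_certain_occupancy(self, rng):
        # psi^A = psi^B = 1, p^A = p^B = 0.5, D^A = D^B = 1 -> log(0.25)
        dm = _dm(rng)
        ps = _params("H1", fill=0.0)
        ps.coef["psiA"][:] = [1000.0, 0, 0]
        ps.coef["psiB"][:] = [1000.0, 0, 0]
        dm.X_det[:] = 0.0
        ll = site_log_likelihood(ps, HYPOTHESES["H1"], np.array([1.0]), np.array([1.0]), dm, 0)
        assert ll == pytest.approx(math.log(0.25), abs=1e-12)

    def test_impossible_event_is_minus_infinity(self, rng):
        dm = _dm(rng)
        ps = _params("H1", fill=0.0)
        ps.coef["psiA"][:] = [-1000.0, 0, 0]  # psi^A = 0 but A was detected
        ll = site_log_likelihood(ps, HYPOTHESES["H1"], np.array([1.0, 0.0]), np.array([0.0, 0.0]), dm, 0)
        assert ll == -math.inf

    @pytest.mark.parametrize("hyp_id", ["H1", "H2", "H3", "H4"])
    def test_matches_enumeration_oracle(self, hyp_id, rng):
        """Random <=3-occasion sites: exact agreement with brute force."""
        hyp = HYPOTHESES[hyp_id]
        for _ in range(60):
            dm = _dm(rng)
            ps = _params(hyp_id, rng=rng)
            T = int(rng.integers(1, 4))
            hA = rng.integers(0, 2, T).astype(float)
            hB = rng.integers(0, 2, T).astype(float)
            if T > 1 and rng.random() < 0.3:
                hA[0] = hB[0] = np.nan
            site = int(rng.integers(0, 4))
            pr = link_probabilities(ps, dm, site=site)
            got = site_log_likelihood(ps, hyp, hA, hB, dm, site)
            want = brute_site_loglik(pr, hA, hB, hyp.detection_conditional)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("hyp_id", ["H1", "H2", "H3", "H4"])
    def test_outcome_space_sums_to_one(self, hyp_id, rng):
        """Sum of exp(loglik) over all 2^(2T) outcome pairs is 1."""
        dm = _dm(rng)
        ps = _params(hyp_id, rng=rng)
        hyp = HYPOTHESES[hyp_id]
        for T in (1, 2, 3):
            total = 0.0
            for hA in itertools.product((0.0, 1.0), repeat=T):
                for hB in itertools.product((0.0, 1.0), repeat=T):
                    total += math.exp(
                        site_log_likelihood(ps, hyp, np.array(hA), np.array(hB), dm, 0)
                    )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_nesting_is_bitwise(self, rng):
        """Imposing the tie numerically reproduces the simpler hypothesis."""
        dm = _dm(rng)
        hA = np.array([1.0, 0.0, np.nan])
        hB = np.array([0.0, 1.0, np.nan])
        # H2 with p^B := r^B equals H1
        ps2 = _params("H2", rng=rng)
        ps2.coef["pB"] = ps2.coef["rB"].copy()
        ps1 = ParamSet(HYPOTHESES["H1"], {"psiA": ps2.coef["psiA"], "psiB": ps2.coef["psiB"],
                                          "pA": ps2.coef["pA"], "pB": ps2.coef["rB"]})
        a = site_log_likelihood(ps2, HYPOTHESES["H2"], hA, hB, dm, 1)
        b = site_log_likelihood(ps1, HYPOTHESES["H1"], hA, hB, dm, 1)
        assert a == b
        # H4 with r^Ba := r^BA equals H2
        ps4 = _params("H4", rng=rng)
        ps4.coef["rBa"] = ps4.coef["rBA"].copy()
        ps2b = ParamSet(HYPOTHESES["H2"], {"psiA": ps4.coef["psiA"], "psiB": ps4.coef["psiB"],
                                           "pA": ps4.coef["pA"], "pB": ps4.coef["pB"],
                                           "rB": ps4.coef["rBA"]})
        assert site_log_likelihood(ps4, HYPOTHESES["H4"], hA, hB, dm, 1) == site_log_likelihood(
            ps2b, HYPOTHESES["H2"], hA, hB, dm, 1
        )

    def test_occasion_exchangeability(self, rng):
        dm = _dm(rng)
        hA = np.array([1.0, 0.0, 0.0, 1.0])
        hB = np.array([0.0, 1.0, 0.0, 0.0])
        perm = np.array([2, 0, 3, 1])
        for hyp_id in ("H1", "H2"):
            ps = _params(hyp_id, rng=rng)
            hyp = HYPOTHESES[hyp_id]
            # B's occasions may be permuted independently of A's
            a = site_log_likelihood(ps, hyp, hA, hB, dm, 0)
            b = site_log_likelihood(ps, hyp, hA[perm], hB, dm, 0)
            assert a == pytest.approx(b, abs=1e-12)
        for hyp_id in ("H3", "H4"):
            ps = _params(hyp_id, rng=rng)
            hyp = HYPOTHESES[hyp_id]
            # only joint permutation preserves the (D^A_t, D^B_t) pairing
            a = site_log_likelihood(ps, hyp, hA, hB, dm, 0)
            b = site_log_likelihood(ps, hyp, hA[perm], hB[perm], dm, 0)
            assert a == pytest.approx(b, abs=1e-12)


class TestDatasetLikelihood:
    def test_single_and_duplicated_sites(self, rng):
        dm = _dm(rng, n=1)
        ps = _params("H3", rng=rng)
        hA, hB = _hist([[1, 0, 1]]), _hist([[0, 0, 1]])
        total, pw = dataset_log_likelihood(ps, HYPOTHESES["H3"], (hA, hB), dm)
        assert total == pytest.approx(
            site_log_likelihood(ps, HYPOTHESES["H3"], hA.matrix[0], hB.matrix[0], dm, 0)
        )
        dm2 = DesignMatrix(["S0", "S1"], np.vstack([dm.X_det] * 2), np.vstack([dm.X_occ] * 2), means={}, sds={})
        hA2 = _hist(np.vstack([hA.matrix] * 2))
        hB2 = _hist(np.vstack([hB.matrix] * 2))
        total2, pw2 = dataset_log_likelihood(ps, HYPOTHESES["H3"], (hA2, hB2), dm2)
        assert total2 == pytest.approx(2 * total, rel=1e-12)

    def test_sum_of_independent_site_terms(self, rng):
        n = 10
        dm = _dm(rng, n=n)
        ps = _params("H4", rng=rng)
        m = rng.integers(0, 2, (n, 3)).astype(float)
        mB = rng.integers(0, 2, (n, 3)).astype(float)
        hA, hB = _hist(m), _hist(mB)
        total, pw = dataset_log_likelihood(ps, HYPOTHESES["H4"], (hA, hB), dm)
        singles = [
            site_log_likelihood(ps, HYPOTHESES["H4"], m[i], mB[i], dm, i) for i in range(n)
        ]
        np.testing.assert_allclose(pw, singles, atol=1e-12)
        assert total == pytest.approx(sum(singles))

    def test_mismatched_missing_patterns_error(self, rng):
        dm = _dm(rng, n=1)
        ps = _params("H1", fill=0.0)
        hA = _hist([[1.0, np.nan]])
        hB = _hist([[1.0, 0.0]])
        with pytest.raises(ValueError, match="missing pattern"):
            dataset_log_likelihood(ps, HYPOTHESES["H1"], (hA, hB), dm)

    def test_engine_batched_matches_flat(self, rng):
        dm = _dm(rng, n=6)
        hA = _hist(rng.integers(0, 2, (6, 4)).astype(float))
        hB = _hist(rng.integers(0, 2, (6, 4)).astype(float))
        eng = LikelihoodEngine(hA, hB, dm, HYPOTHESES["H2"])
        thetas = rng.normal(size=(3, eng.n_coef))
        batch = eng.pointwise(thetas)
        for c in range(3):
            np.testing.assert_allclose(batch[c], eng.pointwise(thetas[c]), atol=1e-12)
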