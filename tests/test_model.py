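"""Unit and property tests for the core attribution model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import attrinf
from attrinf import (
    BeliefGrid,
    InvalidParameterError,
    InvalidRecordError,
    ModelParams,
    apply_consistency,
    bayes_update,
    bin_to_rating,
    build_joint_prior,
    build_policy_likelihood,
    discretized_binomial_prior,
    partner_change_blend,
    rating_to_bin,
    report_loglik,
    run_subject,
    simulate_reports,
    trajectory_loglik,
)
from attrinf.model import default_xi

from conftest import random_m1_paramsets
from reference_impl import reference_trajectory


def uniform_grid(nb=9):
    return BeliefGrid(np.full((nb, nb), 1.0 / nb**2))


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


class TestDiscretizedPrior:
    def test_symmetric_at_half(self):
        p = discretized_binomial_prior(0.5, 1.0, 9)
        assert np.allclose(p, p[::-1])
        mean_bin = np.arange(1, 10) @ p
        assert mean_bin == pytest.approx(5.0)  # delta = (9+1)/2

    def test_large_uncertainty_flattens_to_uniform(self):
        p = discretized_binomial_prior(0.5, 1e6, 9)
        assert np.allclose(p, 1 / 9, atol=1e-3)

    def test_matches_bruteforce_tempered_pmf(self):
        # independent 9-term enumeration at p0=0.8, u=2
        p0, u = 0.8, 2.0
        pmf = [math.comb(8, k) * p0**k * (1 - p0) ** (8 - k) for k in range(9)]
        powed = np.array([q ** (1 / u) for q in pmf])
        expected = powed / powed.sum()
        assert np.allclose(discretized_binomial_prior(p0, u, 9), expected, atol=1e-12)

    @pytest.mark.parametrize("p0,u", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0),
                                      (0.5, -1.0), (float("nan"), 1.0)])
    def test_rejects_out_of_range(self, p0, u):
        with pytest.raises(InvalidParameterError):
            discretized_binomial_prior(p0, u)


class TestJointPrior:
    def test_uniform_limit(self):
        p = ModelParams.from_free("M3", pHI0=0.5, pSI0=0.5, uPri=1e8, u_pi=1.0,
                                  eta=0.5, w0=0.0, wHI=0.0, wSI=0.0)
        g = build_joint_prior(p)
        assert np.allclose(g.probs, 1 / 81, atol=1e-6)

    def test_outer_product_marginals(self, m3_params):
        g = build_joint_prior(m3_params)
        hi = discretized_binomial_prior(m3_params.pHI0, m3_params.uPri_HI)
        si = discretized_binomial_prior(m3_params.pSI0, m3_params.uPri_SI)
        assert np.allclose(g.marginal_hi(), hi, atol=1e-12)
        assert np.allclose(g.marginal_si(), si, atol=1e-12)

    def test_modal_cell_at_marginal_modes(self):
        p = ModelParams.from_free("M1", pHI0=0.9, pSI0=0.1, uPri_HI=1.0,
                                  uPri_SI=1.0, u_pi=1.0, eta=0.5,
                                  w0=0.0, wHI=0.0, wSI=0.0)
        g = build_joint_prior(p)
        i, j = np.unravel_index(np.argmax(g.probs), g.probs.shape)
        assert i == np.argmax(discretized_binomial_prior(0.9, 1.0))
        assert j == np.argmax(discretized_binomial_prior(0.1, 1.0))


# ---------------------------------------------------------------------------
# policy likelihood
# ---------------------------------------------------------------------------


class TestPolicyLikelihood:
    def test_zero_weights_give_half_everywhere(self):
        lik = build_policy_likelihood(0.0, 0.0, 0.0)
        assert np.allclose(lik.p_unfair, 0.5)

    def test_logistic_value_at_top_bin(self):
        lik = build_policy_likelihood(0.0, 1.0, 0.0)
        # HI bin 9 is 4 above the grid centre delta=5
        expected = 1 / (1 + math.exp(-4.0))
        assert lik.p_unfair[8, 0] == pytest.approx(expected, abs=1e-12)

    def test_slices_complement_exactly(self, rng):
        w = rng.normal(size=3)
        lik = build_policy_likelihood(*w)
        assert np.all(lik.slice(0.0) + lik.slice(0.5) == 1.0)
        assert np.all((lik.p_unfair > 0) & (lik.p_unfair < 1))

    def test_monotone_in_wHI_around_centre(self):
        low = build_policy_likelihood(0.3, 0.2, 0.1).p_unfair
        high = build_policy_likelihood(0.3, 0.8, 0.1).p_unfair
        assert np.all(high[5:, :] > low[5:, :])   # HI > delta
        assert np.all(high[:4, :] < low[:4, :])   # HI < delta


# ---------------------------------------------------------------------------
# update, consistency, change point
# ---------------------------------------------------------------------------


class TestBayesUpdate:
    def test_uniform_prior_returns_normalized_slice(self):
        lik = build_policy_likelihood(-0.5, 0.3, 0.2)
        post = bayes_update(uniform_grid(), lik, 0.0)
        assert np.allclose(post.probs, lik.p_unfair / lik.p_unfair.sum(), atol=1e-12)

    def test_sequential_updates_equal_joint_product(self, m3_params, rng):
        # two updates (unfair then fair) == one elementwise-product update
        lik = build_policy_likelihood(m3_params.w0, m3_params.wHI, m3_params.wSI)
        start = build_joint_prior(m3_params)
        g2 = bayes_update(bayes_update(start, lik, 0.0), lik, 0.5)
        brute = start.probs * lik.p_unfair * (1 - lik.p_unfair)
        assert np.allclose(g2.probs, brute / brute.sum(), atol=1e-12)

    def test_constant_likelihood_leaves_grid_unchanged(self, m3_params):
        lik = build_policy_likelihood(0.0, 0.0, 0.0)
        start = build_joint_prior(m3_params)
        post = bayes_update(start, lik, 0.5)
        assert np.allclose(post.probs, start.probs, atol=1e-12)


class TestConsistency:
    def test_infinite_noise_flattens(self, m3_params):
        g = apply_consistency(build_joint_prior(m3_params), 1e9)
        assert np.allclose(g.probs, 1 / 81, atol=1e-6)

    def test_unit_noise_without_xi_is_identity(self, m3_params):
        start = build_joint_prior(m3_params)
        g = apply_consistency(start, 1.0, xi=0.0)
        assert np.allclose(g.probs, start.probs, atol=1e-12)

    def test_hand_enumerated_two_bin_case(self):
        # [0.8, 0.2] outer [0.5, 0.5]: tempering by u_pi=2 takes square roots
        grid = BeliefGrid(np.outer([0.8, 0.2], [0.5, 0.5]))
        out = apply_consistency(grid, 2.0)
        xi = default_xi(2)
        raw = np.sqrt(np.outer([0.8, 0.2], [0.5, 0.5])) + xi
        assert np.allclose(out.probs, raw / raw.sum(), atol=1e-12)
        assert xi == pytest.approx(0.02 / 4)

    def test_rejects_nonpositive_noise(self, m3_params):
        with pytest.raises(InvalidParameterError):
            apply_consistency(build_joint_prior(m3_params), 0.0)


class TestChangePoint:
    @pytest.mark.parametrize("eta", [0.0, 1.0, 0.5])
    def test_blend_endpoints_and_midpoint(self, m3_params, eta):
        prior = build_joint_prior(m3_params)
        lik = build_policy_likelihood(m3_params.w0, m3_params.wHI, m3_params.wSI)
        post = bayes_update(prior, lik, 0.0)
        out = partner_change_blend(prior, post, eta)
        expected = (1 - eta) * prior.probs + eta * post.probs
        assert np.allclose(out.probs, expected, atol=1e-15)
        if eta == 0.0:
            assert np.array_equal(out.probs, prior.probs)
        if eta == 1.0:
            assert np.array_equal(out.probs, post.probs)

    def test_rejects_eta_outside_unit_interval(self, m3_params):
        g = build_joint_prior(m3_params)
        with pytest.raises(InvalidParameterError):
            partner_change_blend(g, g, 1.5)


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------


class TestRatingBins:
    @pytest.mark.parametrize("rating,expected", [(1, 1), (100, 9), (50, 5),
                                                 (11, 1), (12, 2)])
    def test_boundary_and_midpoint_mapping(self, rating, expected):
        assert rating_to_bin(rating) == expected

    @given(st.integers(min_value=1, max_value=100))
    @settings(deadline=None)
    def test_all_ratings_map_into_range(self, rating):
        b = rating_to_bin(rating)
        assert 1 <= b <= 9

    @given(st.integers(min_value=1, max_value=9))
    @settings(deadline=None)
    def test_bin_centre_roundtrip(self, b):
        assert rating_to_bin(bin_to_rating(b)) == b

    def test_rejects_out_of_range_rating(self):
        with pytest.raises(InvalidRecordError):
            rating_to_bin(0)


class TestReportLoglik:
    def test_uniform_grid_gives_log_one_over_81(self):
        assert report_loglik(uniform_grid(), 3, 7) == pytest.approx(math.log(1 / 81))

    def test_certain_grid_is_near_zero(self):
        probs = np.zeros((9, 9))
        probs[4, 4] = 1.0
        assert report_loglik(BeliefGrid(probs), 5, 5) == pytest.approx(0.0)

    def test_equals_log_of_indexed_cell(self, m3_params):
        g = build_joint_prior(m3_params)
        assert report_loglik(g, 2, 6) == pytest.approx(math.log(g.probs[1, 5]),
                                                       abs=1e-12)

    def test_floor_guards_zero_mass(self):
        probs = np.zeros((9, 9))
        probs[0, 0] = 1.0
        assert report_loglik(BeliefGrid(probs), 9, 9) == pytest.approx(math.log(1e-12))


# ---------------------------------------------------------------------------
# full subject runs
# ---------------------------------------------------------------------------


def make_records(outcomes, hi=50, si=50, per_partner=6):
    recs = []
    for t, o in enumerate(outcomes):
        recs.append(
            attrinf.TrialRecord(
                partner_id=t // per_partner + 1,
                trial_index=t % per_partner + 1,
                outcome=o, hi_rating=hi, si_rating=si,
            )
        )
    return recs


class TestRunSubject:
    def test_no_update_case_scores_tempered_prior(self):
        # constant likelihood (all weights 0) and u_pi=1: only xi moves the grid
        p = ModelParams.from_free("M3", pHI0=0.4, pSI0=0.6, uPri=2.0, u_pi=1.0,
                                  eta=0.5, w0=0.0, wHI=0.0, wSI=0.0)
        traj = run_subject(p, make_records([0.5]))
        prior = build_joint_prior(p)
        regularized = apply_consistency(prior, 1.0)
        expected = report_loglik(regularized, 5, 5)
        assert traj.loglik == pytest.approx(expected, abs=1e-12)

    def test_full_reset_restarts_each_partner(self, m3_params):
        p = ModelParams.from_free("M3", **{**m3_params.free_values(), "eta": 0.0})
        outcomes = [0.0] * 6 + [0.5] * 6 + [0.0] * 6
        traj = run_subject(p, make_records(outcomes))
        prior = build_joint_prior(p)
        # first grid of partners 2 and 3 must equal update(prior), not carry over
        for start in (6, 12):
            fresh = apply_consistency(
                bayes_update(prior, build_policy_likelihood(p.w0, p.wHI, p.wSI),
                             outcomes[start]),
                p.u_pi,
            )
            assert np.allclose(traj.grids[start].probs, fresh.probs, atol=1e-12)

    def test_matches_independent_reference_implementation(self, rng):
        for params in random_m1_paramsets(5, seed=42):
            outcomes = rng.choice([0.0, 0.5], size=18)
            hi = rng.integers(1, 10, size=18)
            si = rng.integers(1, 10, size=18)
            blocks = [0, 6, 12]
            ref_grids, ref_ll = reference_trajectory(
                {k: getattr(params, k) for k in
                 ("pHI0", "pSI0", "uPri_HI", "uPri_SI", "w0", "wHI", "wSI",
                  "u_pi", "eta")},
                outcomes, hi, si, blocks,
            )
            ll = trajectory_loglik(params, outcomes, hi, si, blocks)
            assert abs(ll - ref_ll) <= 1e-12 * max(1.0, abs(ref_ll))
            recs = make_records(outcomes,)
            traj = run_subject(
                params,
                [attrinf.TrialRecord(r.partner_id, r.trial_index, r.outcome,
                                     bin_to_rating(int(h)), bin_to_rating(int(s)))
                 for r, h, s in zip(recs, hi, si)],
            )
            assert np.max(np.abs(np.array(ref_grids)
                                 - np.array([g.probs for g in traj.grids]))) < 1e-12

    def test_jit_and_reference_paths_agree(self, m3_params, rng):
        outcomes = rng.choice([0.0, 0.5], size=18)
        hi = rng.integers(1, 10, size=18)
        si = rng.integers(1, 10, size=18)
        recs = [
            attrinf.TrialRecord(t // 6 + 1, t % 6 + 1, float(outcomes[t]),
                                bin_to_rating(int(hi[t])), bin_to_rating(int(si[t])))
            for t in range(18)
        ]
        assert trajectory_loglik(m3_params, outcomes, hi, si, [0, 6, 12]) == \
            pytest.approx(run_subject(m3_params, recs).loglik, abs=1e-10)

    def test_rejects_empty_and_ungrouped_trials(self, m3_params):
        with pytest.raises(InvalidRecordError):
            run_subject(m3_params, [])
        recs = make_records([0.0, 0.5, 0.0])
        shuffled = [recs[0], recs[2], recs[1]]
        shuffled = [
            attrinf.TrialRecord(pid, r.trial_index, r.outcome, 50, 50)
            for r, pid in zip(shuffled, [1, 2, 1])
        ]
        with pytest.raises(InvalidRecordError):
            run_subject(m3_params, shuffled)


class TestGridNormalizationProperty:
    def test_every_operation_stays_normalized(self, rng):
        for params in random_m1_paramsets(8, seed=7):
            outcomes = rng.choice([0.0, 0.5], size=18)
            recs = make_records(outcomes, hi=int(rng.integers(1, 101)),
                                si=int(rng.integers(1, 101)))
            traj = run_subject(params, recs)
            for g in traj.grids:
                assert abs(g.probs.sum() - 1.0) < 1e-10
                assert np.all(g.probs >= 0)


class TestSimulateReports:
    def test_deterministic_given_seed(self, m3_params):
        outcomes = [0.0, 0.5, 0.0, 0.0, 0.5, 0.5]
        a = simulate_reports(m3_params, outcomes, 99)
        b = simulate_reports(m3_params, outcomes, 99)
        assert a == b

    def test_collapsed_grid_always_reports_top_cell(self):
        # extreme prior concentration and no updating: belief stays at (9, 9)
        p = ModelParams.from_free("M1", pHI0=0.999, pSI0=0.999, uPri_HI=0.05,
                                  uPri_SI=0.05, u_pi=1.0, eta=1.0,
                                  w0=0.0, wHI=0.0, wSI=0.0)
        recs = simulate_reports(p, [0.5] * 6, 3)
        assert all(rating_to_bin(r.hi_rating) == 9 for r in recs)
        assert all(rating_to_bin(r.si_rating) == 9 for r in recs)

    def test_prior_location_shifts_first_trial_ratings(self):
        # Monte-Carlo oracle: higher pHI0 must raise mean first-trial HI rating
        base = dict(uPri=2.0, u_pi=2.0, eta=0.5, w0=-1.0, wHI=0.3, wSI=0.3,
                    pSI0=0.5)
        lo = ModelParams.from_free("M3", pHI0=0.1, **base)
        hi = ModelParams.from_free("M3", pHI0=0.9, **base)
        rng = np.random.default_rng(5)
        lo_mean = np.mean([simulate_reports(lo, [0.5], rng)[0].hi_rating
                           for _ in range(400)])
        hi_mean = np.mean([simulate_reports(hi, [0.5], rng)[0].hi_rating
                           for _ in range(400)])
        assert hi_mean > lo_mean + 20


class TestModelParamsVariants:
    def test_m2_requires_shared_weight(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(pHI0=0.5, pSI0=0.5, uPri_HI=1.0, uPri_SI=1.0, w0=0.0,
                        wHI=0.1, wSI=0.2, u_pi=1.0, eta=0.5, variant="M2")

    def test_m3_requires_shared_uncertainty_and_eight_free_values(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(pHI0=0.5, pSI0=0.5, uPri_HI=1.0, uPri_SI=2.0, w0=0.0,
                        wHI=0.1, wSI=0.1, u_pi=1.0, eta=0.5, variant="M3")
        p = ModelParams.from_free("M3", pHI0=0.5, pSI0=0.5, uPri=1.5, u_pi=1.0,
                                  eta=0.5, w0=0.0, wHI=0.1, wSI=0.2)
        assert p.n_free == 8
        assert set(p.free_values()) == {"pHI0", "pSI0", "uPri", "u_pi", "eta",
                                        "w0", "wHI", "wSI"}
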