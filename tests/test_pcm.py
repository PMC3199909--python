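import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import norm

from psychocat import (
    estimate_person_locations,
    fit_pcm,
    generate_item_bank,
    generate_population,
    generate_responses,
    outfit,
    pcm_category_probs,
    person_separation_index,
)
from psychocat.data import ItemBank, ResponseMatrix
from psychocat.pcm import expected_score, filter_items, score_variance


def naive_pcm_probs(theta, thresholds):
    """Independent oracle: direct evaluation of the closed form."""
    terms = [1.0]
    for h in range(1, len(thresholds) + 1):
        terms.append(math.exp(sum(theta - d for d in thresholds[:h])))
    total = sum(terms)
    return np.array([t / total for t in terms])


class TestCategoryProbs:
    def test_dichotomous_at_threshold(self):
        np.testing.assert_allclose(pcm_category_probs(0.7, [0.7]), [0.5, 0.5])

    def test_hand_case(self):
        # closed form: (1/(2+e), e/(2+e), 1/(2+e))
        e = math.e
        expected = np.array([1 / (2 + e), e / (2 + e), 1 / (2 + e)])
        got = pcm_category_probs(0.0, [-1.0, 1.0])
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(got, [0.2119, 0.5761, 0.2119], atol=5e-5)

    def test_extreme_theta_no_overflow(self):
        thr = np.array([-1.0, 0.5, 2.0])
        p = pcm_category_probs(thr.mean() + 50, thr)
        assert np.all(np.isfinite(p))
        assert p[-1] > 1 - 1e-12

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(1, 5)
            thr = rng.normal(0, 1.5, m)
            theta = rng.normal(0, 2)
            np.testing.assert_allclose(
                pcm_category_probs(theta, thr), naive_pcm_probs(theta, thr), atol=1e-12
            )

    @given(
        theta=st.floats(-8, 8),
        thr=st.lists(st.floats(-4, 4), min_size=1, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_property(self, theta, thr):
        p = pcm_category_probs(theta, np.array(thr))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pcm_category_probs(np.nan, [0.0])


class TestInformationIdentity:
    def test_variance_equals_derivative_of_expected_score(self):
        # Richardson-extrapolated central difference of E[X|theta]
        rng = np.random.default_rng(1)
        for _ in range(100):
            m = rng.integers(1, 4)
            thr = rng.normal(0, 1.5, m)
            theta = rng.normal(0, 2)
            h = 1e-2
            d1 = (expected_score(theta + h, thr) - expected_score(theta - h, thr)) / (2 * h)
            d2 = (expected_score(theta + h / 2, thr) - expected_score(theta - h / 2, thr)) / h
            deriv = (4 * d2 - d1) / 3
            assert abs(score_variance(theta, thr) - deriv) < 1e-9


def grid_search_marginal_ll(resp, nodes, log_prior, thr_grid):
    """Exhaustive oracle: max marginal loglik over a threshold grid for
    dichotomous items (one threshold each), latent fixed at the prior."""
    n_items = resp.shape[1]
    # A[j][t, n, q] = log P(x_nj | node q, threshold t)
    A = []
    for j in range(n_items):
        lp = np.empty((len(thr_grid), resp.shape[0], len(nodes)))
        for ti, t in enumerate(thr_grid):
            logits = np.stack([np.zeros_like(nodes), nodes - t])
            lognorm_ = logsumexp(logits, axis=0)
            for n in range(resp.shape[0]):
                lp[ti, n] = logits[resp[n, j]] - lognorm_
        A.append(lp)
    best = -np.inf
    if n_items == 2:
        for t1 in range(len(thr_grid)):
            joint = A[0][t1][None] + A[1]  # (T, N, Q)
            ll = logsumexp(joint + log_prior[None, None, :], axis=2).sum(axis=1)
            best = max(best, ll.max())
    else:
        raise NotImplementedError
    return best


class TestFitPcm:
    def test_identical_items_get_equal_estimates(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(0, 1, 400)
        p = 1 / (1 + np.exp(-(theta - 0.3)))
        col = (rng.random(400) < p).astype(float)
        values = np.column_stack([col, col, (rng.random(400) < 0.5).astype(float)])
        resp = ResponseMatrix(values, np.arange(400), [0, 1, 2])
        res = fit_pcm(resp)
        assert res.bank.thresholds[0][0] == pytest.approx(
            res.bank.thresholds[1][0], abs=1e-6
        )

    def test_beats_exhaustive_grid_search(self):
        # 6 persons x 2 dichotomous items, enumerated fixture
        values = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [1, 1], [0, 1]], dtype=float
        )
        resp = ResponseMatrix(values, np.arange(6), [0, 1])
        res = fit_pcm(resp, quadrature_nodes=61)
        nodes = np.linspace(-6, 6, 61)
        log_prior = norm.logpdf(nodes)
        log_prior -= logsumexp(log_prior)
        thr_grid = np.arange(-3, 3 + 1e-9, 0.05)
        oracle_best = grid_search_marginal_ll(
            values.astype(int), nodes, log_prior, thr_grid
        )
        assert res.loglik >= oracle_best - 1e-6

    def test_em_monotone_loglik(self, core_bank, calibrated_cohort):
        _, responses = calibrated_cohort
        res = fit_pcm(responses, core_bank)
        diffs = np.diff(res.ll_path)
        assert np.all(diffs >= -1e-8 * np.abs(res.ll_path[:-1]))

    def test_identification_constraint(self, core_bank, calibrated_cohort):
        _, responses = calibrated_cohort
        res = fit_pcm(responses, core_bank)
        assert abs(res.bank.locations.mean()) < 1e-8

    def test_parameter_recovery(self, core_bank):
        persons = generate_population(
            n_persons=2000, theta_shift=0.0, lognorm_mu=0.0, lognorm_sigma=0.6, seed=31
        )
        responses = generate_responses(core_bank, persons, design="complete", seed=32)
        res = fit_pcm(responses, core_bank)
        true_loc = core_bank.locations - core_bank.locations.mean()
        est = res.bank.locations
        assert np.sqrt(np.mean((est - true_loc) ** 2)) < 0.15
        assert np.corrcoef(est, true_loc)[0, 1] > 0.98

    def test_recovery_improves_with_n(self, core_bank):
        rmse = {}
        for n in (500, 4000):
            persons = generate_population(
                n_persons=n, theta_shift=0.0, lognorm_mu=0.0, lognorm_sigma=0.6,
                seed=100,
            )
            responses = generate_responses(
                core_bank, persons, design="complete", seed=101
            )
            res = fit_pcm(responses, core_bank)
            true_loc = core_bank.locations - core_bank.locations.mean()
            rmse[n] = np.sqrt(np.mean((res.bank.locations - true_loc) ** 2))
        assert rmse[4000] < rmse[500]

    def test_unobserved_interior_category_collapsed(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 2, 200).astype(float) * 2  # only categories 0 and 2
        other = rng.integers(0, 3, 200).astype(float)
        resp = ResponseMatrix(np.column_stack([col, other]), np.arange(200), [0, 1])
        bank = ItemBank(
            ids=[0, 1],
            labels=["a", "b"],
            blocks=np.array(["A", "A"], object),
            thresholds=[np.zeros(2), np.zeros(2)],
            retained=[True, True],
        )
        with pytest.warns(UserWarning, match="collapsing"):
            res = fit_pcm(resp, bank)
        assert res.bank.thresholds[0].size == 1  # collapsed to dichotomous
        assert 0 in res.category_maps

    def test_single_category_item_rejected(self):
        resp = ResponseMatrix(
            np.column_stack([np.ones(50), np.arange(50) % 2]).astype(float),
            np.arange(50),
            [0, 1],
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_pcm(resp)


class TestPersonLocations:
    def test_eap_matches_fine_grid_oracle(self, core_bank, calibrated_cohort):
        _, responses = calibrated_cohort
        sub = responses.subset_persons(responses.person_ids[:20])
        theta, se = estimate_person_locations(sub, core_bank, method="eap")
        # oracle: 4001-node numeric integration of the same posterior
        nodes = np.linspace(-6, 6, 4001)
        lp = norm.logpdf(nodes)
        lp -= logsumexp(lp)
        for n in range(20):
            ll = lp.copy()
            for j in np.flatnonzero(sub.observed[n]):
                probs = pcm_category_probs(nodes, core_bank.thresholds[j])
                ll += np.log(probs[np.arange(4001), int(sub.values[n, j])])
            w = np.exp(ll - logsumexp(ll))
            mean = w @ nodes
            sd = np.sqrt(w @ nodes**2 - mean**2)
            assert abs(theta[n] - mean) < 1e-3
            assert abs(se[n] - sd) < 1e-3

    def test_wle_extreme_score_finite_and_low(self, core_bank):
        values = np.zeros((1, len(core_bank)))
        resp = ResponseMatrix(values, [0], core_bank.ids)
        theta, se = estimate_person_locations(resp, core_bank, method="wle")
        assert np.isfinite(theta[0])
        assert theta[0] < core_bank.locations.min()
        assert se[0] > 0

    def test_zero_response_person_named(self, core_bank):
        values = np.full((2, len(core_bank)), np.nan)
        values[0, 0] = 1.0
        resp = ResponseMatrix(values, [7, 8], core_bank.ids)
        with pytest.raises(ValueError, match="8"):
            estimate_person_locations(resp, core_bank, method="eap")


class TestOutfit:
    def test_hand_case_unit_outfit(self):
        bank = ItemBank(
            ids=[0], labels=["x"], blocks=np.array(["A"], object),
            thresholds=[np.array([0.0])], retained=[True],
        )
        resp = ResponseMatrix(np.array([[1.0], [0.0]]), [0, 1], [0])
        got = outfit(resp, bank, np.array([0.0, 0.0]))
        assert got[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_case_gross_misfit(self):
        # p(correct)=1/(1+e^-6); z^2 for a 0-response = p/(1-p) = e^6
        bank = ItemBank(
            ids=[0], labels=["x"], blocks=np.array(["A"], object),
            thresholds=[np.array([-3.0])], retained=[True],
        )
        resp = ResponseMatrix(np.array([[0.0]]), [0], [0])
        got = outfit(resp, bank, np.array([3.0]))
        assert got[0] == pytest.approx(np.exp(6.0), rel=1e-10)

    def test_model_consistent_data_mean_near_one(self, core_bank, calibrated_cohort):
        _, responses = calibrated_cohort
        res = fit_pcm(responses, core_bank)
        fit_vals = outfit(responses, res.bank, res.person_theta)
        assert 0.9 <= np.nanmean(fit_vals) <= 1.1


class TestFilterItems:
    def test_no_misfit_no_removal(self, core_bank, calibrated_cohort):
        _, responses = calibrated_cohort
        res = fit_pcm(responses, core_bank)
        res.outfit = outfit(responses, res.bank, res.person_theta)
        if np.nanmax(res.outfit) < 1.7:
            filt = filter_items(res, responses=responses)
            assert filt.removed == []
            assert filt.bank.retained.all()

    def test_noise_item_removed(self):
        # wide trait spread so independence from theta registers as misfit
        bank = generate_item_bank(
            n_core=30, n_short=1, n_categories=3, location_low=-2,
            location_high=2, spread=1.0, seed=5,
        )
        bank = bank.subset(np.asarray(bank.blocks) == "A")
        persons = generate_population(
            n_persons=2000, theta_shift=-2.4, lognorm_mu=0.75,
            lognorm_sigma=0.55, seed=55,
        )
        responses = generate_responses(bank, persons, design="complete", seed=56)
        rng = np.random.default_rng(57)
        responses.values[:, 4] = rng.integers(0, 3, 2000)  # uniform noise item
        res = fit_pcm(responses, bank)
        res.outfit = outfit(responses, res.bank, res.person_theta)
        assert res.outfit[4] >= 1.7
        filt = filter_items(res, responses=responses)
        assert int(bank.ids[4]) in [i for i, _ in filt.removed]
        assert not filt.bank.retained[4]
        # refit excludes the noise item
        assert int(bank.ids[4]) not in filt.calibration.bank.ids

    def test_threshold_must_be_positive(self, core_bank, calibrated_cohort):
        _, responses = calibrated_cohort
        res = fit_pcm(responses, core_bank)
        res.outfit = outfit(responses, res.bank, res.person_theta)
        with pytest.raises(ValueError):
            filter_items(res, threshold=0.0)


class TestPersonSeparationIndex:
    def test_zero_se_gives_one(self):
        assert person_separation_index([0.0, 1.0, 2.0], [0, 0, 0]) == 1.0

    def test_direct_substitution(self):
        # Var = 1, mean SE^2 = 0.07 -> PSI = 0.93
        theta = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.0)  # sample var exactly 1
        se = np.full(3, np.sqrt(0.07))
        assert person_separation_index(theta, se) == pytest.approx(0.93)

    def test_zero_when_se_matches_variance(self):
        theta = np.array([-1.0, 0.0, 1.0])
        se = np.full(3, 1.0)  # mean SE^2 = Var(theta) = 1
        assert person_separation_index(theta, se) == pytest.approx(0.0)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            person_separation_index([1.0, 1.0], [0.1, 0.1])
        with pytest.raises(ValueError):
            person_separation_index([1.0], [0.1])
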