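"""Logit transforms, the message function F, and the nested predictors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circinfer import (
    F,
    GenerativeChain,
    ModelParams,
    TaskTrial,
    exact_posterior_oracle,
    inv_logit,
    likelihood_logit,
    logit,
    predict_circular,
    predict_simple,
    predict_weighted,
    prior_logit,
)

finite_logits = st.floats(min_value=-8.0, max_value=8.0, allow_nan=False)
weights = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestLogitTransforms:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 0.0), (0.8, math.log(4)), (0.2, -math.log(4))],
    )
    def test_logit_closed_form(self, p, expected):
        assert logit(p) == pytest.approx(expected, abs=1e-12)

    def test_inverse_identity(self):
        for p in (0.31, 0.5, 0.999, 1e-4):
            assert inv_logit(logit(p)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_logit_domain_error(self, p):
        with pytest.raises(ValueError):
            logit(p)

    @pytest.mark.parametrize(
        "s_r, s_l, expected",
        [(2, 1, math.log(2)), (3, 3, 0.0), (1, 2, -math.log(2)), (8, 2, math.log(4))],
    )
    def test_prior_logit(self, s_r, s_l, expected):
        assert prior_logit(s_r, s_l) == pytest.approx(expected, abs=1e-12)

    def test_prior_logit_rejects_nonpositive_sizes(self):
        with pytest.raises(ValueError):
            prior_logit(0.0, 1.0)
        with pytest.raises(ValueError):
            prior_logit(2.0, -1.0)

    def test_likelihood_logit_values_and_boundaries(self):
        assert likelihood_logit(0.8) == pytest.approx(math.log(4), abs=1e-12)
        assert likelihood_logit(0.5) == 0.0
        assert likelihood_logit(1.0) == math.inf
        assert likelihood_logit(0.0) == -math.inf
        with pytest.raises(ValueError):
            likelihood_logit(1.5)


class TestTaskTrial:
    def test_derived_fields_and_ambiguity_flag(self):
        trial = TaskTrial(basket_left=2, basket_right=8, p_red_right=0.8)
        assert trial.prior_logit == pytest.approx(math.log(4))
        assert trial.likelihood_logit == pytest.approx(math.log(4))
        assert trial.is_ambiguous

        extreme = TaskTrial(basket_left=5, basket_right=5, p_red_right=1.0)
        assert not extreme.is_ambiguous
        assert extreme.likelihood_logit is None

    def test_mirror_negates_logits(self):
        trial = TaskTrial(basket_left=3, basket_right=7, p_red_right=0.3)
        mirror = trial.mirrored()
        assert mirror.prior_logit == pytest.approx(-trial.prior_logit)
        assert mirror.likelihood_logit == pytest.approx(-trial.likelihood_logit)


class TestMessageFunctionF:
    def test_anchor_points(self):
        assert F(0.0, 0.7) == 0.0
        assert F(2.0, 1.0) == pytest.approx(2.0, abs=1e-12)
        assert F(3.1, 0.5) == pytest.approx(0.0, abs=1e-12)
        expected = math.log((0.8 * math.e**2 + 0.2) / (0.2 * math.e**2 + 0.8))
        assert F(2.0, 0.8) == pytest.approx(expected, abs=1e-14)

    @settings(derandomize=True, max_examples=200)
    @given(L=finite_logits, w=weights)
    def test_odd_and_saturating(self, L, w):
        assert F(-L, w) == pytest.approx(-F(L, w), abs=1e-10)
        assert abs(F(L, w)) <= abs(L) + 1e-12
        if 0.0 < w < 1.0:
            assert abs(F(L, w)) <= abs(logit(w)) + 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(
        L1=finite_logits,
        L2=finite_logits,
        w=st.floats(min_value=0.5, max_value=1.0),
    )
    def test_monotone_for_trusting_weights(self, L1, L2, w):
        lo, hi = sorted((L1, L2))
        assert F(lo, w) <= F(hi, w) + 1e-12

    def test_stable_for_large_loop_arguments(self):
        # alpha * L can reach ~100; the transform must not overflow
        val = F(10.0 * 11.5, 0.9)
        assert np.isfinite(val)
        assert val == pytest.approx(logit(0.9), abs=1e-10)

    def test_rejects_non_finite_logit(self):
        with pytest.raises(ValueError):
            F(math.inf, 0.8)


class TestNestedPredictors:
    def test_simple_is_additive(self):
        assert predict_simple(math.log(4), math.log(4)) == pytest.approx(2 * math.log(4))
        assert predict_simple(1.2, -1.2) == pytest.approx(0.0)
        assert predict_simple(0.0, 0.5) == pytest.approx(0.5)

    def test_weighted_reduces_to_simple_at_unit_weights(self, logit_grid):
        LS, LP = logit_grid
        params = ModelParams.weighted(1.0, 1.0)
        np.testing.assert_allclose(predict_weighted(LS, LP, params), predict_simple(LS, LP), atol=1e-12)

    def test_weighted_is_zero_at_uninformative_weights(self, logit_grid):
        LS, LP = logit_grid
        params = ModelParams.weighted(0.5, 0.5)
        np.testing.assert_allclose(predict_weighted(LS, LP, params), 0.0, atol=1e-12)

    def test_circular_reduces_to_weighted_at_zero_loops(self, logit_grid):
        LS, LP = logit_grid
        for w_s, w_p in [(0.9, 0.75), (0.6, 0.95), (1.0, 1.0)]:
            circ = ModelParams.circular(w_s, w_p, 0.0, 0.0)
            wght = ModelParams.weighted(w_s, w_p)
            np.testing.assert_allclose(
                predict_circular(LS, LP, circ), predict_weighted(LS, LP, wght), atol=1e-12
            )

    def test_all_predictors_odd_under_mirror(self, logit_grid):
        LS, LP = logit_grid
        params = ModelParams.circular(0.85, 0.7, 1.5, 0.8)
        np.testing.assert_allclose(
            predict_circular(-LS, -LP, params), -predict_circular(LS, LP, params), atol=1e-10
        )
        wparams = ModelParams.weighted(0.8, 0.9)
        np.testing.assert_allclose(
            predict_weighted(-LS, -LP, wparams), -predict_weighted(LS, LP, wparams), atol=1e-10
        )

    def test_monotone_in_each_logit(self):
        params = ModelParams.circular(0.9, 0.8, 2.0, 1.0)
        ls = np.linspace(-2.2, 2.2, 200)
        for lp in (-1.5, 0.0, 1.5):
            vals = predict_circular(ls, np.full_like(ls, lp), params)
            assert np.all(np.diff(vals) >= -1e-10)
            vals_p = predict_circular(np.full_like(ls, lp), ls, params)
            assert np.all(np.diff(vals_p) >= -1e-10)

    def test_origin_is_fixed_point(self):
        for params in (
            ModelParams.simple(),
            ModelParams.weighted(0.7, 0.9),
            ModelParams.circular(0.9, 0.6, 3.0, 2.0),
        ):
            if params.variant == "simple":
                assert predict_simple(0.0, 0.0) == 0.0
            else:
                assert predict_circular(0.0, 0.0, params) == pytest.approx(0.0, abs=1e-14)

    def test_ascending_loops_steepen_slope_beyond_unity(self):
        # over-counting signature: local d L_c / d L_s at the origin exceeds 1
        params = ModelParams.circular(w_s=0.9, w_p=0.75, alpha_s=1.8, alpha_p=0.0)
        h = 1e-6
        slope = (predict_circular(h, 0.0, params) - predict_circular(-h, 0.0, params)) / (2 * h)
        assert slope > 1.0
        # while maximal trust without loops caps the slope at exactly 1
        flat = ModelParams.weighted(1.0, 1.0)
        slope_w = (predict_weighted(h, 0.0, flat) - predict_weighted(-h, 0.0, flat)) / (2 * h)
        assert slope_w == pytest.approx(1.0, abs=1e-6)


class TestEnumerationOracle:
    def test_uninformative_chain_gives_zero(self):
        chain = GenerativeChain(prior_prob_right=0.5, w_p=0.5, w_s=0.5)
        assert exact_posterior_oracle(chain, 1.7) == pytest.approx(0.0, abs=1e-14)

    def test_deterministic_chain_adds_logits(self):
        chain = GenerativeChain(prior_prob_right=0.7, w_p=1.0, w_s=1.0)
        got = exact_posterior_oracle(chain, 1.3)
        assert got == pytest.approx(1.3 + logit(0.7), abs=1e-12)

    def test_uninformative_link_with_one_hot_evidence_returns_prior_term(self):
        chain = GenerativeChain(prior_prob_right=0.7, w_p=0.9, w_s=0.5)
        got = exact_posterior_oracle(chain, math.inf)
        assert got == pytest.approx(F(logit(0.7), 0.9), abs=1e-12)

    def test_matches_weighted_prediction_on_random_chains(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            w_s = rng.uniform(0.0, 1.0)
            w_p = rng.uniform(0.0, 1.0)
            prior = rng.uniform(0.01, 0.99)
            L_s = rng.uniform(-6, 6)
            chain = GenerativeChain(prior_prob_right=prior, w_p=w_p, w_s=w_s)
            oracle = exact_posterior_oracle(chain, L_s)
            closed = F(L_s, w_s) + F(logit(prior), w_p)
            worst = max(worst, abs(oracle - closed))
        assert worst <= 1e-12


class TestModelParams:
    def test_variant_constraints(self):
        with pytest.raises(ValueError):
            ModelParams(w_s=0.9, variant="simple")
        with pytest.raises(ValueError):
            ModelParams(alpha_s=1.0, variant="weighted")
        with pytest.raises(ValueError):
            ModelParams(w_s=0.4)
        with pytest.raises(ValueError):
            ModelParams(alpha_p=-0.5)

    def test_free_parameter_counts(self):
        assert ModelParams.simple().k == 0
        assert ModelParams.weighted(0.8, 0.8).k == 2
        assert ModelParams.circular(0.8, 0.8, 1.0, 1.0).k == 4

    def test_vector_round_trip(self):
        p = ModelParams.circular(0.8, 0.7, 2.5, 0.3)
        assert ModelParams.from_vector(p.to_vector(), "circular") == p
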