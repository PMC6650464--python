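"""Incidence family, vector field, equilibria and threshold quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import switchsir as sw
from switchsir.model_core import RegimeParameters

positive = st.floats(min_value=1e-3, max_value=1e3)
state = st.floats(min_value=0.0, max_value=1e3)
exponent = st.floats(min_value=1e-3, max_value=4.0)


def params(**kw):
    base = dict(Lambda=0.3, mu=0.1, beta=0.8, alpha=0.2, gamma=0.3,
                epsilon=0.1, sigma2=0.4)
    base.update(kw)
    return RegimeParameters(**base)


class TestIncidence:
    @pytest.mark.parametrize("args, expected", [
        ((1.0, 1.0, 1.0, 1.0, 1.0), 0.5),          # standard incidence
        ((3.0, 0.0, 0.8, 0.2, 0.002), 0.0),        # no infecteds
        ((0.0, 0.5, 0.8, 0.2, 0.002), 0.0),        # boundary limit
        # frozen against a 40-digit evaluation of the formula
        ((0.3, 0.2, 0.8, 0.2, 0.002), 0.1333513491339652),
    ])
    def test_values(self, args, expected):
        assert sw.ratio_dependent_incidence(*args) == pytest.approx(
            expected, rel=1e-12, abs=1e-15)

    @given(S=state, I=state, beta=positive, alpha=positive, h=exponent)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounded_by_beta_I(self, S, I, beta, alpha, h):
        g = sw.ratio_dependent_incidence(S, I, beta, alpha, h)
        assert 0.0 <= g <= beta * I * (1 + 1e-12)

    @given(S=state, I=state, beta=positive, alpha=positive, h=exponent)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_general_reduces_at_l_1(self, S, I, beta, alpha, h):
        left = sw.general_incidence(S, I, beta, alpha, h, l=1.0)
        right = sw.ratio_dependent_incidence(S, I, beta, alpha, h)
        assert left == pytest.approx(right, rel=1e-12, abs=1e-300)

    def test_standard_incidence_special_case(self):
        # alpha = h = l = 1 is the frequency-dependent rate beta*S*I/(S+I)
        assert sw.general_incidence(2.0, 2.0, 1.0, 1.0, 1.0, 1.0) == 1.0
        assert sw.general_incidence(5.0, 0.0, 1.0, 1.0, 1.0, 1.0) == 0.0

    @pytest.mark.parametrize("bad", [
        dict(S=-1.0, I=1.0), dict(S=1.0, I=-0.5), dict(beta=0.0),
        dict(alpha=-1.0), dict(h=0.0),
    ])
    def test_domain_errors(self, bad):
        kw = dict(S=1.0, I=1.0, beta=1.0, alpha=1.0, h=1.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            sw.ratio_dependent_incidence(**kw)


class TestVectorField:
    def test_disease_free_point_is_fixed(self):
        # division Lambda/mu exact here, so the drift is exactly zero
        p = params(Lambda=1.0, mu=0.5)
        assert sw.drift(p.Lambda / p.mu, 0.0, p, 0.002) == (0.0, 0.0)

    def test_drift_example_regime1(self, regime1):
        aS, aI = sw.drift(0.3, 0.2, regime1, 0.002)
        # incidence oracle minus removal 0.5 * 0.2
        assert aI == pytest.approx(0.03335134913396516, rel=1e-12)

    @given(S=state, I=state, h=exponent)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sum_identity(self, S, I, h):
        p = params()
        aS, aI = sw.drift(S, I, p, h)
        expected = p.Lambda - p.mu * (S + I) - (p.gamma + p.epsilon) * I
        assert aS + aI == pytest.approx(expected, rel=1e-10, abs=1e-10)

    @given(S=state, I=state, h=exponent)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_diffusion_degenerate(self, S, I, h):
        p = params()
        bS, bI = sw.diffusion(S, I, p, h)
        cS, cI = sw.diffusion_gradient_product(S, I, p, h)
        assert bS + bI == 0.0
        assert cS + cI == 0.0
        assert bS <= 0.0

    def test_diffusion_vanishes_on_axes_and_without_noise(self, regime1):
        assert sw.diffusion(3.0, 0.0, regime1, 0.002) == (0.0, 0.0)
        p0 = params(sigma2=0.0)
        assert sw.diffusion(0.3, 0.2, p0, 0.002) == (0.0, 0.0)
        assert sw.diffusion_gradient_product(0.3, 0.2, p0, 0.002) == (0.0, 0.0)
        assert sw.diffusion_gradient_product(0.0, 0.2, regime1, 0.002) == (0.0, 0.0)

    def test_correction_matches_finite_differences(self, regime1):
        S, I, h = 0.3, 0.2, 0.002
        eps = 1e-7
        dbS_dS = (sw.diffusion(S + eps, I, regime1, h)[0]
                  - sw.diffusion(S - eps, I, regime1, h)[0]) / (2 * eps)
        dbS_dI = (sw.diffusion(S, I + eps, regime1, h)[0]
                  - sw.diffusion(S, I - eps, regime1, h)[0]) / (2 * eps)
        bS, bI = sw.diffusion(S, I, regime1, h)
        expected = bS * dbS_dS + bI * dbS_dI
        cS, _ = sw.diffusion_gradient_product(S, I, regime1, h)
        assert cS == pytest.approx(expected, rel=1e-6)


class TestEquilibria:
    def test_deterministic_R0(self, regime1, regime2):
        assert sw.deterministic_R0(regime1) == pytest.approx(1.6)
        assert sw.deterministic_R0(regime2) == pytest.approx(1.0)
        p = params(beta=0.5, mu=0.1, gamma=0.3, epsilon=0.1)
        assert sw.deterministic_R0(p) == 1.0

    def test_disease_free_always_present(self, regime1):
        eq = sw.equilibria(regime1, 0.002)
        assert eq.disease_free == pytest.approx((3.0, 0.0))

    def test_endemic_point_h1(self, regime1):
        eq = sw.equilibria(regime1, 1.0)
        # frozen from numerical root-finding on the drift field
        assert eq.endemic == pytest.approx((0.1875, 0.5625), rel=1e-12)
        residual = sw.drift(*eq.endemic, regime1, 1.0)
        assert max(abs(r) for r in residual) < 1e-10

    def test_absent_when_subcritical(self):
        p = params(beta=0.4)  # R0 = 0.8
        eq = sw.equilibria(p, 1.0)
        assert eq.endemic is None
        assert eq.note is None

    def test_overflow_reported_not_raised(self, regime1):
        # (R0-1)/alpha = 3, and 3^(1/h) overflows doubles for h = 0.001
        eq = sw.equilibria(regime1, 0.001)
        assert eq.endemic is None
        assert "not representable" in eq.note


class TestThresholds:
    def test_R0S_case_a(self, model_a):
        assert sw.stochastic_R0S(model_a) == pytest.approx(76 / 70, rel=1e-12)
        assert round(sw.stochastic_R0S(model_a), 3) == 1.086

    def test_R0S_reduces_to_R0_without_noise(self):
        p = params(sigma2=0.0)
        m = sw.SwitchingModel([p], [[0.0]], h=1.0)
        assert sw.stochastic_R0S(m) == sw.deterministic_R0(p)

    def test_R0S_case_c_formula_value(self, model_c):
        # direct evaluation of the threshold formula gives 19/18 here
        assert sw.stochastic_R0S(model_c) == pytest.approx(19 / 18, rel=1e-12)

    def test_R0S_rejects_bad_pi(self, model_a):
        with pytest.raises(ValueError):
            sw.stochastic_R0S(model_a, pi=[0.7, 0.2])
        with pytest.raises(ValueError):
            sw.stochastic_R0S(model_a, pi=[1.0])

    def test_Rbar_case_b(self, model_b):
        assert sw.extinction_index_Rbar(model_b) == pytest.approx(
            0.38 / 0.52, rel=1e-12)
        assert round(sw.extinction_index_Rbar(model_b), 3) == 0.731

    def test_Rbar_case_a(self, model_a):
        assert sw.extinction_index_Rbar(model_a) == pytest.approx(
            0.82 / 0.52, rel=1e-12)

    def test_Rbar_single_regime_and_undefined(self):
        p = params(sigma2=0.4)
        m = sw.SwitchingModel([p], [[0.0]], h=1.0)
        expected = p.beta ** 2 / (2 * p.sigma2 * p.removal_rate)
        assert sw.extinction_index_Rbar(m) == pytest.approx(expected)
        m0 = sw.SwitchingModel([params(sigma2=0.0)], [[0.0]], h=1.0)
        with pytest.raises(ValueError, match="sigma2 = 0"):
            sw.extinction_index_Rbar(m0)


class TestClassification:
    def test_reference_cases(self, model_a, model_b, model_c):
        assert sw.classify_dynamics(model_a).classification == "persistent"
        assert sw.classify_dynamics(model_b).classification == "extinct_i"
        # the threshold formula itself puts case c above 1
        assert sw.classify_dynamics(model_c).classification == "persistent"

    def test_small_noise_extinction(self, model_a):
        # halving every beta drops R0S below 1 with sigma_i^2 <= beta_i, but
        # it also drops Rbar below 1, so condition (i) takes precedence
        halved = [RegimeParameters(Lambda=p.Lambda, mu=p.mu, beta=p.beta / 2,
                                   alpha=p.alpha, gamma=p.gamma,
                                   epsilon=p.epsilon, sigma2=p.sigma2)
                  for p in model_a.regimes]
        m = sw.SwitchingModel(halved, model_a.generator, h=model_a.h)
        rep = sw.classify_dynamics(m)
        assert rep.R0S < 1
        assert rep.noise_dominance.all()
        assert rep.Rbar < 1
        assert rep.classification == "extinct_i"
        # extinct_ii proper requires Rbar >= 1: small noise, modest beta
        p = params(Lambda=0.5, mu=0.2, beta=0.5, alpha=0.2, gamma=0.2,
                   epsilon=0.2, sigma2=0.1)
        rep2 = sw.classify_dynamics(sw.SwitchingModel([p], [[0.0]], h=1.0))
        assert rep2.R0S < 1 and rep2.Rbar >= 1
        assert rep2.noise_dominance.all()
        assert rep2.classification == "extinct_ii"

    def test_indeterminate_gap(self):
        # R0S < 1 but sigma^2 > beta and Rbar >= 1: no sufficient condition applies
        p = params(Lambda=0.5, mu=0.02, beta=0.5, alpha=0.2, gamma=0.02,
                   epsilon=0.01, sigma2=1.0)
        m = sw.SwitchingModel([p], [[0.0]], h=1.0)
        rep = sw.classify_dynamics(m)
        assert rep.R0S < 1
        assert rep.Rbar >= 1
        assert not rep.noise_dominance.all()
        assert rep.classification == "indeterminate"

    def test_pure_function(self, model_a):
        r1 = sw.classify_dynamics(model_a)
        r2 = sw.classify_dynamics(model_a)
        assert np.array_equal(r1.pi, r2.pi)
        assert r1.R0S == r2.R0S and r1.Rbar == r2.Rbar
        assert r1.classification == r2.classification

    def test_extinct_i_precedence(self, model_b):
        # case b satisfies both extinction conditions; (i) wins
        rep = sw.classify_dynamics(model_b)
        assert rep.R0S < 1 and rep.noise_dominance.all()
        assert rep.Rbar < 1
        assert rep.classification == "extinct_i"


class TestValidation:
    def test_regime_parameters_reject_nonpositive(self):
        with pytest.raises(ValueError):
            params(mu=0.0)
        with pytest.raises(ValueError):
            params(sigma2=-0.1)

    def test_model_requires_irreducible_generator(self):
        p = params()
        with pytest.raises(ValueError, match="irreducible"):
            sw.SwitchingModel([p, p], [[0.0, 0.0], [1.0, -1.0]], h=1.0)

    def test_model_warns_on_small_h(self):
        p = params()
        with pytest.warns(UserWarning, match="h=0.002"):
            sw.SwitchingModel([p], [[0.0]], h=0.002)
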