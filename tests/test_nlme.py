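"""Priors, likelihood components and the Laplace marginal."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from camkin.forward_model import EquilibriumPoint, Recording, SolutionComposition
from camkin.nlme import (
    FixedEffects,
    NLMEProblem,
    Prior,
    conditional_loglik,
    default_priors,
    gaussian_loglik,
    laplace_marginal_1d,
    log_prior,
    map_objective,
    parameter_model,
    theta_param_names,
)
from camkin.schemes import BufferParams, build_scheme, load_rate_set
from camkin.synthetic import GroundTruth, generate_equilibrium_dataset, generate_uncaging_dataset

LOG_2PI = math.log(2 * math.pi)


@pytest.fixture(scope="module")
def s1_setup():
    spec = build_scheme("S1")
    rates = load_rate_set("S1", "our_fits")
    priors = default_priors(spec)
    fixed = FixedEffects(rates=rates, mu=0.0, omega=1.0,
                         sigma_dyn=0.05, sigma_eq=0.1)
    return spec, rates, priors, fixed


class TestPriors:
    def test_forward_rate_outside_support_is_minus_inf(self, s1_setup):
        spec, rates, priors, fixed = s1_setup
        bad = FixedEffects(
            rates=type(rates)(scheme_id="S1",
                              log10_forward={"k1": 10.0, "k3": 4.0},
                              log10_kd=dict(rates.log10_kd)),
            mu=0.0, omega=1.0)
        assert log_prior(bad, priors, spec) == -math.inf

    def test_normal_prior_mode_density(self):
        p = Prior("normal", -5.0, 1.0)
        assert p.logpdf(-5.0) == pytest.approx(-0.5 * LOG_2PI)

    def test_flat_interior_independent_of_position(self, s1_setup):
        spec, rates, priors, _ = s1_setup
        vals = []
        for k1 in (3.0, 5.0, 8.5):
            fx = FixedEffects(
                rates=type(rates)("S1", {"k1": k1, "k3": 4.0},
                                  dict(rates.log10_kd)),
                mu=0.0, omega=1.0)
            vals.append(log_prior(fx, priors, spec))
        assert np.isfinite(vals).all()
        assert max(vals) - min(vals) == pytest.approx(0.0, abs=1e-12)

    def test_mu_box_and_omega_restriction(self, s1_setup):
        spec, rates, priors, _ = s1_setup
        out_mu = FixedEffects(rates=rates, mu=6.0, omega=1.5)
        assert log_prior(out_mu, priors, spec) == -math.inf
        below = FixedEffects(rates=rates, mu=0.0, omega=0.5)
        assert log_prior(below, priors, spec) == -math.inf

    def test_unrestricted_omega_mle_can_fall_below_one(self):
        """The over-fitting rationale for the omega >= 1 restriction: with
        tightly clustered random effects the unrestricted ML estimate of
        omega collapses below 1, while the restriction clamps it at 1."""
        etas = np.array([0.1, -0.05, 0.12, 0.02, -0.08])
        mu = etas.mean()

        def profile(omega):
            return float(np.sum(norm.logpdf(etas, mu, omega)))

        grid = np.linspace(0.01, 3.0, 500)
        omega_hat = grid[np.argmax([profile(w) for w in grid])]
        assert omega_hat < 1.0
        restricted = grid[grid >= 1.0]
        omega_res = restricted[np.argmax([profile(w) for w in restricted])]
        assert omega_res == pytest.approx(1.0, abs=0.01)


class TestParameterModel:
    def test_determinism_and_sole_eta_usage(self, s1_setup, buffers):
        spec, rates, priors, fixed = s1_setup
        comp = SolutionComposition(10e-6, 1e-3, 50e-6, 1e-4)
        p1 = parameter_model(fixed, comp, 0.3, buffers, spec)
        p2 = parameter_model(fixed, comp, 0.3, buffers, spec)
        assert p1["uncaging_fraction"] == p2["uncaging_fraction"]
        assert p1["linear_rate_pairs"] == p2["linear_rate_pairs"]
        p3 = parameter_model(fixed, comp, 0.9, buffers, spec)
        assert p3["linear_rate_pairs"] == p1["linear_rate_pairs"]
        assert p3["uncaging_fraction"] != p1["uncaging_fraction"]

    def test_rates_are_exponentiated(self, buffers):
        spec = build_scheme("S1")
        rates = type(load_rate_set("S1", "our_fits"))(
            "S1", {"k1": 3.0, "k3": 4.0}, {"KD1": -6.0, "KD2": -6.0})
        fixed = FixedEffects(rates=rates)
        comp = SolutionComposition(10e-6, 1e-3, 50e-6, 1e-4)
        p = parameter_model(fixed, comp, 0.0, buffers, spec)
        assert p["linear_rate_pairs"][0][0] == pytest.approx(1000.0)


class TestConditionalLoglik:
    def test_empty_data_is_zero(self, s1_setup, buffers):
        spec, rates, priors, fixed = s1_setup
        assert conditional_loglik(fixed, {}, [], [], spec, buffers) == 0.0

    def test_zero_residuals_value(self, s1_setup, buffers):
        """Noiseless synthetic data evaluated at truth: residuals vanish and
        the log-likelihood is the Gaussian normalization alone."""
        spec = build_scheme("S1")
        truth = GroundTruth.default("S1", seed=5, sigma_dyn=0.0, sigma_eq=0.0)
        recs, truth = generate_uncaging_dataset(truth, 2, 2)
        eq = generate_equilibrium_dataset(truth, n_points=10)
        fixed = FixedEffects(rates=truth.rates, mu=truth.mu,
                             omega=truth.omega, sigma_dyn=0.05, sigma_eq=0.1)
        ll = conditional_loglik(fixed, truth.eta, recs, eq, spec, truth.buffers)
        m_dyn = sum(r.times.size for r in recs)
        expected = (m_dyn * (-math.log(0.05) - 0.5 * LOG_2PI)
                    + 10 * (-math.log(0.1) - 0.5 * LOG_2PI))
        assert ll == pytest.approx(expected, abs=1e-3)

    def test_sigma_doubling_closed_form(self):
        res = np.array([0.1, -0.2, 0.05])
        a = gaussian_loglik(res, 0.1)
        b = gaussian_loglik(res, 0.2)
        ss = float(np.sum(res ** 2))
        expected = (-0.5 * ss * (1 / 0.04 - 1 / 0.01)
                    - res.size * math.log(2.0))
        assert b - a == pytest.approx(expected, rel=1e-12)


class TestMapObjective:
    def test_no_data_reduces_to_priors(self, s1_setup, buffers):
        spec, rates, priors, fixed = s1_setup
        etas = {"a": 0.3, "b": -0.2}
        recs = []
        val = map_objective(fixed, etas, recs, [], spec, buffers, priors)
        eta_term = sum(norm.logpdf(e, fixed.mu, fixed.omega)
                       for e in etas.values())
        assert val == pytest.approx(log_prior(fixed, priors, spec) + eta_term)

    def test_eta_at_mu_prior_term(self, s1_setup, buffers):
        spec, rates, priors, fixed = s1_setup
        n = 4
        etas = {f"r{i}": fixed.mu for i in range(n)}
        val = map_objective(fixed, etas, [], [], spec, buffers, priors)
        expected_eta = -n * (math.log(fixed.omega) + 0.5 * LOG_2PI)
        assert val - log_prior(fixed, priors, spec) == pytest.approx(expected_eta)

    def test_objective_drops_away_from_eta_optimum(self, s1_setup, buffers):
        spec, rates, priors, fixed = s1_setup
        base = map_objective(fixed, {"a": fixed.mu}, [], [], spec, buffers,
                             priors)
        for d in (-0.5, 0.5):
            perturbed = map_objective(fixed, {"a": fixed.mu + d}, [], [],
                                      spec, buffers, priors)
            assert perturbed < base

    def test_invariant_to_recording_order(self, buffers):
        truth = GroundTruth.default("S1", seed=9)
        recs, truth = generate_uncaging_dataset(truth, 2, 2)
        eq = generate_equilibrium_dataset(truth, n_points=8)
        spec = truth.spec
        priors = default_priors(spec)
        fixed = FixedEffects(rates=truth.rates, mu=0.5, omega=1.0,
                             sigma_dyn=0.05, sigma_eq=0.1)
        a = map_objective(fixed, truth.eta, recs, eq, spec, truth.buffers, priors)
        b = map_objective(fixed, truth.eta, recs[::-1], eq, spec,
                          truth.buffers, priors)
        assert a == pytest.approx(b, rel=1e-12)


class TestLaplace:
    def conjugate_case(self, rng):
        mu = rng.uniform(-1, 1)
        omega = rng.uniform(0.3, 2.0)
        sigma = rng.uniform(0.05, 1.0)
        y = rng.uniform(-2, 2)

        def joint(eta):
            return (norm.logpdf(y, eta, sigma) + norm.logpdf(eta, mu, omega))

        exact = norm.logpdf(y, mu, math.sqrt(omega ** 2 + sigma ** 2))
        return joint, mu, omega, exact

    def test_matches_conjugate_marginal(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            joint, mu, omega, exact = self.conjugate_case(rng)
            approx = laplace_marginal_1d(joint, mu, omega)
            assert approx == pytest.approx(exact, abs=1e-6)

    def test_degenerate_prior_limit(self):
        # omega -> 0: marginal -> conditional likelihood at eta = mu
        y, sigma, mu = 0.7, 0.3, 0.2
        for omega in (1e-3, 1e-4):
            def joint(eta):
                return norm.logpdf(y, eta, sigma) + norm.logpdf(eta, mu, omega)

            val = laplace_marginal_1d(joint, mu, omega, h=omega * 1e-2)
            assert val == pytest.approx(norm.logpdf(y, mu, sigma), abs=1e-3)

    def test_laplace_identity_bound(self):
        rng = np.random.default_rng(7)
        joint, mu, omega, _ = self.conjugate_case(rng)
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda e: -joint(e))
        g_max = joint(res.x)
        val = laplace_marginal_1d(joint, mu, omega)
        # marginal = conditional max + 0.5 log(2 pi / H) by construction
        assert val <= g_max + 10.0
        h = 1e-4
        curv = -(joint(res.x + h) - 2 * g_max + joint(res.x - h)) / h ** 2
        assert val == pytest.approx(g_max + 0.5 * math.log(2 * math.pi / curv),
                                    abs=1e-5)

    def test_nonpositive_curvature_reported(self):
        with pytest.raises(RuntimeError, match="rec7"):
            laplace_marginal_1d(lambda e: 0.1 * e, 0.0, 1.0, label="rec7")


def test_theta_param_ordering_matches_slots():
    spec = build_scheme("S6")
    names = theta_param_names(spec)
    assert len(names) == 16
    assert names[:8] == spec.forward_slots
    assert names[8:] == spec.kd_names
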