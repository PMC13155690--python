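import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avci.shapes import (
    LOG_INCREMENT_FLOOR,
    PIVOTS,
    ContextParams,
    NoiseModel,
    PivotGrid,
    PriorModel,
    apply_prior_exponent,
    apply_recalibration,
    build_semiparametric_noise,
    build_semiparametric_prior,
    flat_noise_theta,
    flat_prior_theta,
    noise_sigma,
)

GRID = np.linspace(-45.0, 45.0, 721)
# independent refined grid for unit-mass checks (cusp-aware, half steps)
FINE = PriorModel.make_norm_grid(refine=2)


class TestParametricPriors:
    def test_single_gaussian_normalizes(self):
        p = PriorModel("SingleGaussian", {"sigma_s": 8.0})
        assert np.trapezoid(p.pdf(GRID), GRID) == pytest.approx(1.0, rel=1e-6)

    def test_gaussian_laplace_closed_form_at_zero(self):
        sig, b, om = 6.0, 2.0, 0.4
        p = PriorModel("GaussianLaplace", {"sigma_s": sig, "b": b, "omega": om})
        expected = (1 - om) / (sig * np.sqrt(2 * np.pi)) + om / (2 * b)
        assert p.pdf(0.0) == pytest.approx(expected, rel=1e-4)

    def test_two_gaussians_degenerate_mixture(self):
        a = PriorModel("TwoGaussians", {"sigma_s": 5.0, "sigma_delta": 7.0, "omega": 0.0})
        b = PriorModel("SingleGaussian", {"sigma_s": 5.0})
        assert np.allclose(a.pdf(GRID), b.pdf(GRID))

    @pytest.mark.parametrize("family,params", [
        ("SingleGaussian", {"sigma_s": 3.0}),
        ("TwoGaussians", {"sigma_s": 3.0, "sigma_delta": 8.0, "omega": 0.3}),
        ("GaussianLaplace", {"sigma_s": 6.0, "b": 1.5, "omega": 0.6}),
    ])
    def test_symmetry_nonnegativity_mass(self, family, params):
        p = PriorModel(family, params)
        d = p.pdf(GRID)
        assert np.all(d >= 0)
        assert np.allclose(d, d[::-1])
        assert np.trapezoid(p.pdf(FINE), FINE) == pytest.approx(1.0, rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PriorModel("SingleGaussian", {"sigma_s": -1.0})
        with pytest.raises(ValueError):
            PriorModel("GaussianLaplace", {"sigma_s": 1.0, "b": 1.0, "omega": 1.5})


class TestNoiseModels:
    def test_exp_at_zero_and_asymptote(self):
        n = NoiseModel("Exp", {"sigma0": 1.5, "k1": 4.0, "k2": 0.5}, "V")
        assert n.sigma(0.0) == pytest.approx(1.5)
        assert n.sigma(1e3 / 0.5) == pytest.approx(5.5, rel=1e-9)

    def test_exp_with_k1_zero_equals_const(self):
        e = NoiseModel("Exp", {"sigma0": 2.0, "k1": 0.0, "k2": 1.0}, "V")
        c = NoiseModel("Const", {"sigma0": 2.0}, "V")
        s = np.linspace(-45, 45, 101)
        assert np.allclose(e.sigma(s), c.sigma(s))

    def test_scaling_contract(self):
        c = NoiseModel("Const", {"sigma0": 2.0}, "V")
        ctx = ContextParams(alpha_med=1.5, alpha_low=3.0, beta_V=1.2, beta_A=1.6)
        got = noise_sigma(c, 7.0, "low", ctx, bisensory=True)
        assert got == pytest.approx(2.0 * 3.0 * 1.2)

    def test_reliability_rejected_for_audition(self):
        a = NoiseModel("Const", {"sigma0": 2.0}, "A")
        with pytest.raises(ValueError):
            noise_sigma(a, 0.0, "med", ContextParams())

    def test_monotone_nondecreasing_in_eccentricity(self):
        n = NoiseModel("Exp", {"sigma0": 0.5, "k1": 5.0, "k2": 0.2}, "V")
        s = np.arange(0.0, 45.0 + 1e-9, 0.1)
        assert np.all(np.diff(n.sigma(s)) >= -1e-12)


class TestSemiparametricBuilders:
    def test_noise_cumulative_sum(self):
        theta = np.zeros(12)  # log(1) everywhere
        n = build_semiparametric_noise(theta)
        for j, loc in enumerate(PIVOTS):
            assert n.sigma(loc) == pytest.approx(1.0 + j, abs=1e-12)

    def test_flat_noise(self):
        n = build_semiparametric_noise(flat_noise_theta(2.0))
        s = np.linspace(0, 45, 200)
        assert np.allclose(n.sigma(s), 2.0, atol=1e-4)

    def test_noise_knots_exact_and_monotone(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(-1, 1, 12)
        n = build_semiparametric_noise(theta)
        knots = np.cumsum(np.exp(theta))
        assert np.allclose([n.sigma(p) for p in PIVOTS], knots, rtol=1e-12)
        s = np.arange(0.0, 45.0 + 1e-9, 0.1)
        assert np.all(np.diff(n.sigma(s)) >= -1e-12)

    def test_prior_uniform_at_floor(self):
        p = build_semiparametric_prior(flat_prior_theta())
        d = p.pdf(np.linspace(-45, 45, 500))
        assert np.allclose(d, 1.0 / 90.0, rtol=1e-3)

    def test_prior_normalized_and_monotone(self):
        rng = np.random.default_rng(1)
        theta = rng.normal(-1.5, 1.0, 11)
        p = build_semiparametric_prior(theta)
        assert np.trapezoid(p.pdf(FINE), FINE) == pytest.approx(1.0, rel=1e-6)
        vals = p.pdf(PIVOTS)
        assert np.all(np.diff(vals) <= 1e-15)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            build_semiparametric_noise(np.zeros(11))
        with pytest.raises(ValueError):
            build_semiparametric_prior(np.zeros(12))


class TestRecalibrationAndExponent:
    def test_recalibration_values(self):
        assert apply_recalibration(9.0, 4.0 / 3.0) == pytest.approx(12.0)
        assert apply_recalibration(0.0, 1.7) == 0.0
        x = np.array([-3.0, 5.0])
        assert np.allclose(apply_recalibration(x, 1.0), x)

    def test_gamma_one_is_identity(self):
        p = PriorModel("SingleGaussian", {"sigma_s": 5.0})
        assert apply_prior_exponent(p, 1.0) is p

    def test_gamma_zero_is_uniform(self):
        p = PriorModel("GaussianLaplace", {"sigma_s": 5.0, "b": 2.0, "omega": 0.5})
        q = apply_prior_exponent(p, 0.0)
        d = q.pdf(np.linspace(-44, 44, 100))
        assert np.allclose(d, 1.0 / 90.0, rtol=1e-9)

    def test_gamma_two_on_gaussian_narrows_by_sqrt2(self):
        # N(0, s^2)^2 is proportional to N(0, s^2/2)
        p = PriorModel("SingleGaussian", {"sigma_s": 6.0})
        q = apply_prior_exponent(p, 2.0)
        ref = PriorModel("SingleGaussian", {"sigma_s": 6.0 / np.sqrt(2)})
        s = np.linspace(-30, 30, 301)
        assert np.allclose(q.pdf(s), ref.pdf(s), rtol=1e-6)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(theta0=st.floats(-1.0, 2.0),
       incr=st.lists(st.floats(LOG_INCREMENT_FLOOR, 2.0), min_size=11, max_size=11))
def test_semiparametric_noise_properties(theta0, incr):
    """Positivity, symmetry, and monotone growth for arbitrary pivot values."""
    n = build_semiparametric_noise(np.array([theta0] + incr))
    s = np.linspace(0, 45, 451)
    vals = n.sigma(s)
    assert np.all(vals > 0)
    assert np.allclose(n.sigma(-s), vals)
    assert np.all(np.diff(vals) >= -1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(theta=st.lists(st.floats(LOG_INCREMENT_FLOOR, 1.5), min_size=11, max_size=11))
def test_semiparametric_prior_properties(theta):
    """Unit mass, symmetry, monotone decay for arbitrary pivot decrements."""
    p = build_semiparametric_prior(np.array(theta))
    d = p.pdf(GRID)
    assert np.all(d >= 0)
    assert np.allclose(d, d[::-1])
    assert np.trapezoid(p.pdf(FINE), FINE) == pytest.approx(1.0, rel=1e-6)
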