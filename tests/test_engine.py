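import numpy as np
import pytest
from scipy.stats import norm

from avci.engine import GridSpec, ObserverModel
from avci.shapes import ContextParams, NoiseModel, PriorModel

from conftest import make_vanilla


def conjugate_weight(sigma0, sigma_s):
    return sigma_s**2 / (sigma_s**2 + sigma0**2)


class TestUnisensory:
    def test_posterior_mean_symmetry_point(self, vanilla_model):
        assert vanilla_model.posterior_mean_unisensory(0.0, "V") == pytest.approx(0.0, abs=1e-9)

    def test_conjugate_shrinkage_half(self):
        m = make_vanilla(sigma_V=10.0, sigma_s=10.0)
        assert m.posterior_mean_unisensory(10.0, "V") == pytest.approx(5.0, abs=1e-3)

    def test_conjugate_shrinkage_general(self):
        m = make_vanilla(sigma_V=3.0, sigma_s=7.0)
        w = conjugate_weight(3.0, 7.0)
        x = np.linspace(-20, 20, 21)
        got = m.posterior_mean_unisensory(x, "V")
        assert np.max(np.abs(got - w * x)) < 1e-3

    def test_pure_lapse_density_is_uniform(self):
        m = make_vanilla(lapse=1.0)
        s = np.zeros(5)
        r = np.array([-44.0, -10.0, 0.0, 22.0, 44.9])
        d = m.unisensory_response_density(s, "high", "UV", r)
        assert np.allclose(d, 1.0 / 90.0)
        out = m.unisensory_response_density(np.zeros(1), "high", "UV", np.array([46.0]))
        assert out[0] == 0.0

    def test_vanilla_closed_form_density(self):
        sigma0, sigma_s, sigma_m = 2.0, 10.0, 0.8
        m = make_vanilla(sigma_V=sigma0, sigma_s=sigma_s, sigma_motor=sigma_m)
        w = conjugate_weight(sigma0, sigma_s)
        sd = np.sqrt(w**2 * sigma0**2 + sigma_m**2)
        for s in (-15.0, -5.0, 0.0, 10.0, 15.0):
            r = np.linspace(s - 10, s + 10, 41)
            got = m.unisensory_response_density(np.full_like(r, s), "high", "UV", r)
            assert np.max(np.abs(got - norm.pdf(r, w * s, sd))) < 1e-4

    def test_density_mean_matches_shrunk_stimulus(self):
        sigma0, sigma_s = 2.0, 10.0
        m = make_vanilla(sigma_V=sigma0, sigma_s=sigma_s)
        w = conjugate_weight(sigma0, sigma_s)
        r = np.linspace(-30, 30, 1201)
        d = m.unisensory_density_grid(8.0, "high", "UV", r)
        mean = np.trapezoid(r * d, r) / np.trapezoid(d, r)
        assert mean == pytest.approx(w * 8.0, abs=1e-2)

    def test_ua_recalibration_shifts_mean(self):
        rho = 4.0 / 3.0
        m = make_vanilla(sigma_A=3.0, sigma_s=50.0, rho_A=rho, sigma_motor=0.5)
        r = np.linspace(-40, 40, 2001)
        d = m.unisensory_density_grid(9.0, None, "UA", r)
        mean = np.trapezoid(r * d, r) / np.trapezoid(d, r)
        w = conjugate_weight(3.0, 50.0)
        assert mean == pytest.approx(w * rho * 9.0, abs=0.1)

    def test_localization_density_normalizes(self, rich_model):
        r = np.linspace(-60, 60, 2401)
        for task, s, rel in (("UV", 12.0, "low"), ("UA", -10.0, None)):
            d = rich_model.unisensory_density_grid(s, rel, task, r)
            assert np.trapezoid(d, r) == pytest.approx(1.0, abs=1e-3)

    def test_invalid_task_reliability(self, vanilla_model):
        with pytest.raises(ValueError):
            vanilla_model.unisensory_response_density(np.zeros(1), "med", "UA", np.zeros(1))
        with pytest.raises(ValueError):
            vanilla_model.unisensory_response_density(np.zeros(1), "high", "BC", np.zeros(1))


class TestCausalPosterior:
    def closed_form(self, xv, xa, sv2, sa2, ss2, psame):
        mu_c = (xv / sv2 + xa / sa2) / (1 / sv2 + 1 / sa2)
        var_c = 1.0 / (1 / sv2 + 1 / sa2)
        L1 = norm.pdf(xv - xa, 0, np.sqrt(sv2 + sa2)) * norm.pdf(mu_c, 0, np.sqrt(ss2 + var_c))
        L2 = norm.pdf(xv, 0, np.sqrt(sv2 + ss2)) * norm.pdf(xa, 0, np.sqrt(sa2 + ss2))
        return psame * L1 / (psame * L1 + (1 - psame) * L2)

    def test_degenerate_prior_probabilities(self):
        for psame, expected in ((1.0, 1.0), (0.0, 0.0)):
            m = make_vanilla(p_same=psame)
            for xv, xa in ((-10.0, 3.0), (0.0, 0.0), (7.0, 7.0)):
                assert m.causal_posterior_at(xv, xa, "high") == pytest.approx(expected)

    def test_matches_conjugate_closed_form(self):
        m = make_vanilla(sigma_V=2.0, sigma_A=4.0, sigma_s=10.0, p_same=0.55)
        xs = np.linspace(-14, 14, 8)
        for xv in xs:
            for xa in xs:
                want = self.closed_form(xv, xa, 4.0, 16.0, 100.0, 0.55)
                assert m.causal_posterior_at(xv, xa, "high") == pytest.approx(want, abs=1e-4)

    def test_bisensory_estimates_closed_form(self):
        m = make_vanilla(sigma_V=2.0, sigma_A=4.0, sigma_s=10.0)
        xv, xa = 6.0, -3.0
        fused, single = m.posterior_means_bisensory(xv, xa, "V", "high")
        prec = 1 / 4.0 + 1 / 16.0 + 1 / 100.0
        want_f = (xv / 4.0 + xa / 16.0) / prec
        assert fused == pytest.approx(want_f, abs=1e-3)
        assert single == pytest.approx(xv * 100.0 / 104.0, abs=1e-3)

    def test_single_cue_estimate_ignores_other_measurement(self, vanilla_model):
        _, s1 = vanilla_model.posterior_means_bisensory(5.0, -12.0, "V", "high")
        _, s2 = vanilla_model.posterior_means_bisensory(5.0, 9.0, "V", "high")
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_symmetric_measurements_at_zero(self, vanilla_model):
        fused, single = vanilla_model.posterior_means_bisensory(0.0, 0.0, "V", "high")
        assert fused == pytest.approx(0.0, abs=1e-9)
        assert single == pytest.approx(0.0, abs=1e-9)


class TestBisensoryLikelihoods:
    def test_bc_pure_lapse(self):
        for strat in ("MS", "PM"):
            m = make_vanilla(lapse=1.0, strategy=strat)
            p = m.bc_response_probability(np.array([3.0]), np.array([-9.0]), "high")
            assert p[0] == pytest.approx(0.5)

    def test_bc_degenerate_common_cause(self):
        for strat in ("MS", "MA", "PM"):
            m = make_vanilla(p_same=1.0, strategy=strat)
            p = m.bc_response_probability(np.array([0.0]), np.array([12.0]), "high")
            assert p[0] == pytest.approx(1.0, abs=1e-9)

    def test_bc_probabilities_sum_to_one(self, rich_model):
        p1 = rich_model.bc_response_probability(np.array([5.0]), np.array([-5.0]), "med")
        assert 0.0 <= p1[0] <= 1.0  # complement defined as 1 - p1 exactly

    def test_bv_pure_lapse(self):
        m = make_vanilla(lapse=1.0)
        d = m.bisensory_localization_density(np.array([3.0]), np.array([6.0]),
                                             "high", "V", np.array([11.0]))
        assert d[0] == pytest.approx(1.0 / 90.0)

    def test_psame_zero_reduces_to_single_cue(self):
        """With p(C=1) = 0 every strategy collapses to the target modality's
        unisensory response density with beta-scaled bisensory noise."""
        beta_V = 1.3
        for strat in ("MS", "MA", "PM"):
            m = make_vanilla(sigma_V=2.0, sigma_s=10.0, p_same=0.0,
                             strategy=strat, beta_V=beta_V)
            r = np.linspace(-10, 14, 13)
            got = m.bisensory_localization_density(np.full(13, 4.0), np.full(13, -8.0),
                                                   "high", "V", r)
            sig_eff = 2.0 * beta_V
            w = conjugate_weight(sig_eff, 10.0)
            sd = np.sqrt(w**2 * sig_eff**2 + m.context.sigma_motor**2)
            want = norm.pdf(r, w * 4.0, sd)
            assert np.max(np.abs(got - want)) < 1e-4

    def test_strategy_collapse_under_degenerate_posterior(self):
        """MS, MA, PM coincide when the causal posterior is 0 or 1."""
        r = np.linspace(-12, 12, 9)
        for psame in (0.0, 1.0):
            dens = []
            for strat in ("MS", "MA", "PM"):
                m = make_vanilla(p_same=psame, strategy=strat)
                dens.append(m.bisensory_localization_density(
                    np.full(9, 2.0), np.full(9, -2.0), "high", "A", r))
            assert np.allclose(dens[0], dens[1], atol=1e-10)
            assert np.allclose(dens[0], dens[2], atol=1e-10)

    def test_bv_density_normalizes(self, rich_model):
        r = np.linspace(-60, 60, 1201)
        d = rich_model.bisensory_localization_density(
            np.full(r.shape, 6.0), np.full(r.shape, -4.0), "low", "V", r)
        assert np.trapezoid(d, r) == pytest.approx(1.0, abs=1e-3)


class TestGridConvergence:
    def test_halved_grids_change_probabilities_below_tolerance(self, rich_model):
        import dataclasses
        fine = dataclasses.replace(rich_model, grids=rich_model.grids.halved())
        r = np.array([-6.0, 0.0, 4.5])
        s_v = np.full(3, 5.0)
        s_a = np.full(3, -5.0)
        pairs = [
            (rich_model.unisensory_response_density(np.full(3, 8.0), "med", "UV", r),
             fine.unisensory_response_density(np.full(3, 8.0), "med", "UV", r)),
            (rich_model.unisensory_response_density(np.full(3, -10.0), None, "UA", r),
             fine.unisensory_response_density(np.full(3, -10.0), None, "UA", r)),
            (rich_model.bc_response_probability(s_v, s_a, "high"),
             fine.bc_response_probability(s_v, s_a, "high")),
            (rich_model.bisensory_localization_density(s_v, s_a, "low", "A", r),
             fine.bisensory_localization_density(s_v, s_a, "low", "A", r)),
        ]
        for coarse_v, fine_v in pairs:
            assert np.max(np.abs(coarse_v - fine_v)) < 1e-3
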