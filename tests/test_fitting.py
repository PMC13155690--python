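import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from avci.design import ExperimentDesign
from avci.fitting import (
    Param,
    fit_mle,
    lift_semiparametric,
    negative_log_likelihood,
)
from avci.recovery import RECOVERY_GRIDS
from avci.simulate import make_simulated_group, simulate_responses
from avci.zoo import build_model


@pytest.fixture(scope="module")
def toy_data():
    design = ExperimentDesign(n_participants=1,
                              trials_per_task={"UV": 60, "UA": 60, "B": 40, "BC": 40})
    return make_simulated_group("Const-SingleGaussian-PM", {}, design, seed=21)


class TestNLL:
    def test_pure_lapse_localization(self):
        design = ExperimentDesign(n_participants=1, trials_per_task={"UV": 50, "UA": 30})
        grp = make_simulated_group("Const-SingleGaussian_1", {"lapse": 0.5}, design, seed=2)
        params = dict(grp.params[0], lapse=1.0)
        nll = negative_log_likelihood(params, "Const-SingleGaussian_1", grp.trials,
                                      grids=RECOVERY_GRIDS)
        assert nll == pytest.approx(80 * np.log(90.0), rel=1e-12)

    def test_additive_over_data_partition(self, toy_data):
        spec = build_model("Const-SingleGaussian-PM")
        p = toy_data.params[0]
        t = toy_data.trials
        a, b = t.iloc[:100], t.iloc[100:]
        total = negative_log_likelihood(p, spec, t, grids=RECOVERY_GRIDS)
        parts = (negative_log_likelihood(p, spec, a, grids=RECOVERY_GRIDS)
                 + negative_log_likelihood(p, spec, b, grids=RECOVERY_GRIDS))
        assert total == pytest.approx(parts, rel=1e-12)

    def test_invariant_to_trial_order(self, toy_data):
        spec = build_model("Const-SingleGaussian-PM")
        p = toy_data.params[0]
        t = toy_data.trials
        shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert negative_log_likelihood(p, spec, t, grids=RECOVERY_GRIDS) == pytest.approx(
            negative_log_likelihood(p, spec, shuffled, grids=RECOVERY_GRIDS), rel=1e-12)

    def test_matches_trial_by_trial_reevaluation(self, toy_data):
        """Brute-force oracle: evaluate each trial alone through a fresh model,
        bypassing all per-call caching and vectorized grouping."""
        spec = build_model("Const-SingleGaussian-PM")
        p = toy_data.params[0]
        t = toy_data.trials
        total = negative_log_likelihood(p, spec, t, grids=RECOVERY_GRIDS)
        brute = 0.0
        for i in range(len(t)):
            one = t.iloc[[i]].reset_index(drop=True)
            model = spec.make_model(p, grids=RECOVERY_GRIDS)  # fresh caches
            brute += float(-np.log(model.trial_likelihoods(one)[0]))
        assert total == pytest.approx(brute, rel=1e-8)

    def test_rejects_nonfinite_params(self, toy_data):
        p = dict(toy_data.params[0], sigma0_V=np.nan)
        with pytest.raises(ValueError):
            negative_log_likelihood(p, "Const-SingleGaussian-PM", toy_data.trials)

    def test_task_restriction(self, toy_data):
        spec = build_model("Const-SingleGaussian-PM")
        p = toy_data.params[0]
        uni = negative_log_likelihood(p, spec, toy_data.trials, tasks=("UV", "UA"),
                                      grids=RECOVERY_GRIDS)
        sub = toy_data.trials[toy_data.trials["task"].isin(("UV", "UA"))]
        assert uni == pytest.approx(
            negative_log_likelihood(p, spec, sub, grids=RECOVERY_GRIDS), rel=1e-12)


class TestTransforms:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(u=st.floats(0.01, 0.99))
    def test_roundtrip_log(self, u):
        p = Param("sigma", 0.05, 30.0, "log")
        x = p.from_unit(u)
        assert p.from_internal(p.to_internal(x)) == pytest.approx(x, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(u=st.floats(0.01, 0.99))
    def test_roundtrip_linear_and_logit(self, u):
        for tr in ("linear", "logit"):
            p = Param("q", 0.0 if tr == "linear" else 1e-4,
                      5.0 if tr == "linear" else 1 - 1e-4, tr)
            x = p.from_unit(u)
            assert p.from_internal(p.to_internal(x)) == pytest.approx(x, rel=1e-9, abs=1e-12)


class TestFitMLE:
    def test_warm_start_contract(self, toy_data):
        """The returned optimum is never worse than a supplied warm start."""
        spec = build_model("Const-SingleGaussian-PM")
        truth = toy_data.params[0]
        nll_truth = negative_log_likelihood(truth, spec, toy_data.trials,
                                            grids=RECOVERY_GRIDS)
        fit = fit_mle(spec, toy_data.trials, n_starts=0, seed=0, grids=RECOVERY_GRIDS,
                      warm_starts=[truth], budget=120)
        assert fit.nll <= nll_truth + 1e-9
        assert fit.n_trials == len(toy_data.trials)

    def test_smoke_fit_small_table(self):
        design = ExperimentDesign(n_participants=1, trials_per_task={"UA": 50})
        grp = make_simulated_group("Const-SingleGaussian_1", {}, design, seed=8)
        fit = fit_mle("Const-SingleGaussian_1", grp.trials, n_starts=1, seed=0,
                      grids=RECOVERY_GRIDS, budget=250)
        assert np.isfinite(fit.nll)
        assert set(fit.params) == set(build_model("Const-SingleGaussian_1").parameter_spec.names)
        assert len(fit.restarts) == 1

    def test_semiparametric_smoke_fit_uses_flat_starts(self):
        """The 40-parameter semiparametric model fits (budget-capped) from
        flat-function initializations without error."""
        design = ExperimentDesign(n_participants=1, trials_per_task={"UV": 40, "UA": 40})
        grp = make_simulated_group("Const-SingleGaussian_1", {}, design, seed=17)
        fit = fit_mle("Semiparam", grp.trials, n_starts=2, seed=0,
                      grids=RECOVERY_GRIDS, budget=250)
        assert np.isfinite(fit.nll)
        assert fit.n_params == 40
        # at least one restart explores a flat sigma/prior shape start
        assert any(r["start"]["theta_V_1"] == pytest.approx(float(np.log(1e-6)), rel=1e-6)
                   for r in fit.restarts)

    def test_nested_model_never_worse(self, toy_data):
        """Exp noise nests Const (k1 -> 0): warm-starting the larger model at
        the embedded point keeps its NLL at or below the smaller model's."""
        small = build_model("Const-SingleGaussian-PM")
        large = build_model("Exp-SingleGaussian-PM")
        p_small = toy_data.params[0]
        nll_small = negative_log_likelihood(p_small, small, toy_data.trials,
                                            grids=RECOVERY_GRIDS)
        embed = dict(p_small)
        for mod in ("V", "A"):
            embed[f"k1_{mod}"] = 1e-3
            embed[f"k2_{mod}"] = 1e-3
        fit = fit_mle(large, toy_data.trials, n_starts=0, seed=0, grids=RECOVERY_GRIDS,
                      warm_starts=[embed], budget=150)
        assert fit.nll <= nll_small + 0.01


class TestLifting:
    @pytest.fixture(scope="class")
    def lifted_setup(self):
        rng = np.random.default_rng(0)
        frozen = {
            "theta_V": np.concatenate([[np.log(1.0)], np.full(11, np.log(0.3))]),
            "theta_A": np.concatenate([[np.log(2.5)], np.full(11, np.log(0.3))]),
            "theta_prior": np.full(11, np.log(0.25)),
        }
        design = ExperimentDesign(n_participants=1,
                                  trials_per_task={"UV": 40, "UA": 40, "B": 40, "BC": 40})
        spec = build_model("LiftedSemiparam-PM", frozen_shapes=frozen)
        ctx = {"alpha_med": 1.6, "alpha_low": 2.8, "lapse": 0.04, "sigma_motor": 1.0,
               "rho_A": 1.25, "p_same": 0.5, "beta_V": 1.1, "beta_A": 1.5, "gamma": 1.0}
        grp = make_simulated_group(spec, [ctx], design, seed=13)
        return frozen, grp

    def test_lifted_free_parameter_count(self, lifted_setup):
        frozen, _ = lifted_setup
        spec = build_model("LiftedSemiparam-PM", frozen_shapes=frozen)
        assert spec.n_free_params == 9
        assert set(spec.parameter_spec.names) == {
            "alpha_med", "alpha_low", "lapse", "sigma_motor", "rho_A",
            "p_same", "beta_V", "beta_A", "gamma"}

    def test_lift_requires_semiparametric_upstream(self, toy_data):
        from avci.fitting import FitResult
        bogus = FitResult("Const-SingleGaussian", toy_data.params[0], 0.0, 7, 10)
        with pytest.raises(ValueError, match="semiparametric"):
            lift_semiparametric(bogus, toy_data.trials, "PM")

    def test_lifted_fit_runs_and_reproduces_unisensory_nll(self, lifted_setup):
        """gamma = 1 + unisensory context reproduces the unisensory NLL on the
        unisensory subset (identical model on identical data)."""
        frozen, grp = lifted_setup
        spec = build_model("LiftedSemiparam-PM", frozen_shapes=frozen)
        params = grp.params[0]
        uni = grp.trials[grp.trials["task"].isin(("UV", "UA"))]
        nll_direct = negative_log_likelihood(params, spec, uni, grids=RECOVERY_GRIDS)
        uni_spec = build_model("Semiparam")
        uni_params = {f"theta_V_{j}": frozen["theta_V"][j] for j in range(12)}
        uni_params.update({f"theta_A_{j}": frozen["theta_A"][j] for j in range(12)})
        uni_params.update({f"theta_prior_{j}": frozen["theta_prior"][j - 1]
                           for j in range(1, 12)})
        uni_params.update({k: params[k] for k in
                           ("alpha_med", "alpha_low", "lapse", "sigma_motor", "rho_A")})
        nll_uni = negative_log_likelihood(uni_params, uni_spec, uni, grids=RECOVERY_GRIDS)
        assert nll_direct == pytest.approx(nll_uni, rel=1e-10)
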