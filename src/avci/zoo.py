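"""Model registry, naming, free-parameter accounting, and AIC/BIC comparison.

Model names follow the ``noise-prior-strategy[_recalib]`` convention, e.g.
``Exp-GaussianLaplace-PM`` (all-tasks scope) or ``Const-SingleGaussian_1``
(unisensory scope, recalibration gain fixed at 1).  The recalibration suffix
is ``_1`` (no recalibration), ``_4/3`` (full remapping of the auditory range
onto the visual range), or absent (free rho_A).  ``Semiparam`` names the
40-parameter unisensory semiparametric model and ``LiftedSemiparam-<strategy>``
its 9-free-parameter lift to all tasks (shape parameters frozen from the
unisensory fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from avci.engine import GridSpec, ObserverModel
from avci.fitting import FitResult, Param, ParameterSpec
from avci.shapes import (
    LOG_INCREMENT_FLOOR,
    ContextParams,
    NoiseModel,
    PriorModel,
    build_semiparametric_noise,
    build_semiparametric_prior,
    flat_noise_theta,
    flat_prior_theta,
)

NOISE_FAMILIES = {"Const": 1, "Exp": 3, "Semiparam": 12}
PRIOR_FAMILIES = {"SingleGaussian": 1, "TwoGaussians": 3, "GaussianLaplace": 3,
                  "Semiparam": 11}
STRATEGIES = ("MS", "MA", "PM")

#: Frozen shape parameters of a lifted fit: theta_V (12) + theta_A (12) + theta_prior (11)
N_FROZEN_SHAPE_PARAMS = 35

_BOUNDS = {
    "sigma0": (0.05, 30.0, "log"),
    "k1": (1e-3, 40.0, "log"),
    "k2": (1e-3, 5.0, "log"),
    "sigma_s": (0.25, 60.0, "log"),
    "sigma_delta": (0.25, 60.0, "log"),
    "b": (0.25, 60.0, "log"),
    "omega": (1e-4, 1 - 1e-4, "logit"),
    "lapse": (1e-4, 1 - 1e-4, "logit"),
    "p_same": (1e-4, 1 - 1e-4, "logit"),
    "sigma_motor": (0.05, 30.0, "log"),
    "alpha": (0.2, 10.0, "log"),
    "beta": (0.2, 10.0, "log"),
    "rho_A": (0.5, 2.0, "log"),
    "gamma": (0.0, 5.0, "linear"),
    "theta": (LOG_INCREMENT_FLOOR, np.log(40.0), "linear"),
}

_DEFAULT_START = {
    "sigma0_V": 1.0, "k1_V": 3.0, "k2_V": 0.3,
    "sigma0_A": 3.0, "k1_A": 4.0, "k2_A": 0.2,
    "sigma_s": 8.0, "sigma_delta": 8.0, "b": 2.0, "omega": 0.5,
    "alpha_med": 1.8, "alpha_low": 3.0, "lapse": 0.03, "sigma_motor": 1.0,
    "rho_A": 1.15, "p_same": 0.5, "beta_V": 1.15, "beta_A": 1.5, "gamma": 1.0,
}


def _param(name: str, kind: str) -> Param:
    lo, hi, tr = _BOUNDS[kind]
    return Param(name, lo, hi, tr)


def _noise_params(family: str, modality: str) -> list:
    if family == "Const":
        return [_param(f"sigma0_{modality}", "sigma0")]
    if family == "Exp":
        return [_param(f"sigma0_{modality}", "sigma0"),
                _param(f"k1_{modality}", "k1"),
                _param(f"k2_{modality}", "k2")]
    return [_param(f"theta_{modality}_{j}", "theta") for j in range(12)]


def _prior_params(family: str) -> list:
    if family == "SingleGaussian":
        return [_param("sigma_s", "sigma_s")]
    if family == "TwoGaussians":
        return [_param("sigma_s", "sigma_s"), _param("sigma_delta", "sigma_delta"),
                _param("omega", "omega")]
    if family == "GaussianLaplace":
        return [_param("sigma_s", "sigma_s"), _param("b", "b"), _param("omega", "omega")]
    return [_param(f"theta_prior_{j}", "theta") for j in range(1, 12)]


@dataclass(frozen=True)
class ModelSpec:
    """A parsed model name: component families, task scope, frozen set."""

    name: str
    noise_family: str
    prior_family: str
    strategy: str | None  # None for unisensory scope
    recalib: str | float  # "free", 1.0, or 4/3
    frozen_shapes: dict | None = None  # lifted models: theta_V/theta_A/theta_prior

    @property
    def task_scope(self) -> str:
        return "all" if self.strategy is not None else "unisensory"

    @property
    def lifted(self) -> bool:
        return self.frozen_shapes is not None or self.name.startswith("LiftedSemiparam")

    @property
    def parameter_spec(self) -> ParameterSpec:
        params = []
        if not self.lifted:
            params += _noise_params(self.noise_family, "V")
            params += _noise_params(self.noise_family, "A")
            params += _prior_params(self.prior_family)
        params += [_param("alpha_med", "alpha"), _param("alpha_low", "alpha"),
                   _param("lapse", "lapse"), _param("sigma_motor", "sigma_motor")]
        if self.recalib == "free":
            params.append(_param("rho_A", "rho_A"))
        if self.strategy is not None:
            params += [_param("p_same", "p_same"), _param("beta_V", "beta"),
                       _param("beta_A", "beta")]
        if self.lifted:
            params.append(_param("gamma", "gamma"))
        return ParameterSpec(tuple(params))

    @property
    def n_free_params(self) -> int:
        return len(self.parameter_spec)

    def default_start(self) -> dict:
        start = {}
        for name in self.parameter_spec.names:
            if name in _DEFAULT_START:
                start[name] = _DEFAULT_START[name]
            elif name.startswith("theta_prior"):
                j = int(name.rsplit("_", 1)[1])
                # gently decaying prior start
                start[name] = np.log(0.3)
            elif name.startswith("theta_V"):
                j = int(name.rsplit("_", 1)[1])
                start[name] = np.log(1.0) if j == 0 else np.log(0.3)
            elif name.startswith("theta_A"):
                j = int(name.rsplit("_", 1)[1])
                start[name] = np.log(3.0) if j == 0 else np.log(0.3)
            else:  # pragma: no cover - every name should be covered above
                raise KeyError(name)
        return start

    def flat_shape_starts(self, levels=(1.0, 3.0, 8.0)) -> list:
        """Flat-function initializations for semiparametric shapes: sigma flat
        at a fixed level, prior flat across the range."""
        if self.noise_family != "Semiparam" and self.prior_family != "Semiparam":
            return []
        starts = []
        for lv in levels:
            s = self.default_start()
            if self.noise_family == "Semiparam":
                for j, v in enumerate(flat_noise_theta(lv)):
                    s[f"theta_V_{j}"] = float(v)
                for j, v in enumerate(flat_noise_theta(2.0 * lv)):
                    s[f"theta_A_{j}"] = float(v)
            if self.prior_family == "Semiparam":
                for j, v in enumerate(flat_prior_theta(), start=1):
                    s[f"theta_prior_{j}"] = float(v)
            starts.append(s)
        return starts

    # ---------------- assembly ----------------

    def _make_noise(self, params: dict, modality: str) -> NoiseModel:
        if self.lifted:
            return build_semiparametric_noise(self.frozen_shapes[f"theta_{modality}"],
                                              modality=modality)
        fam = self.noise_family
        if fam == "Const":
            return NoiseModel("Const", {"sigma0": params[f"sigma0_{modality}"]}, modality)
        if fam == "Exp":
            return NoiseModel("Exp", {"sigma0": params[f"sigma0_{modality}"],
                                      "k1": params[f"k1_{modality}"],
                                      "k2": params[f"k2_{modality}"]}, modality)
        theta = np.array([params[f"theta_{modality}_{j}"] for j in range(12)])
        return build_semiparametric_noise(theta, modality=modality)

    def _make_prior(self, params: dict) -> PriorModel:
        if self.lifted:
            return build_semiparametric_prior(self.frozen_shapes["theta_prior"])
        fam = self.prior_family
        if fam == "SingleGaussian":
            return PriorModel("SingleGaussian", {"sigma_s": params["sigma_s"]})
        if fam == "TwoGaussians":
            return PriorModel("TwoGaussians", {k: params[k] for k in
                                               ("sigma_s", "sigma_delta", "omega")})
        if fam == "GaussianLaplace":
            return PriorModel("GaussianLaplace", {k: params[k] for k in
                                                  ("sigma_s", "b", "omega")})
        theta = np.array([params[f"theta_prior_{j}"] for j in range(1, 12)])
        return build_semiparametric_prior(theta)

    def make_model(self, params: dict, grids: GridSpec | None = None) -> ObserverModel:
        rho = params.get("rho_A", self.recalib if self.recalib != "free" else 1.0)
        context = ContextParams(
            alpha_med=params["alpha_med"],
            alpha_low=params["alpha_low"],
            beta_V=params.get("beta_V", 1.0),
            beta_A=params.get("beta_A", 1.0),
            rho_A=float(rho),
            p_same=params.get("p_same", 0.5),
            lapse=params["lapse"],
            sigma_motor=params["sigma_motor"],
            gamma=params.get("gamma", 1.0),
        )
        return ObserverModel(
            prior=self._make_prior(params),
            noise_V=self._make_noise(params, "V"),
            noise_A=self._make_noise(params, "A"),
            strategy=self.strategy or "PM",
            context=context,
            grids=grids or GridSpec(),
        )


def parse_model_name(name: str, frozen_shapes: dict | None = None) -> ModelSpec:
    recalib: str | float = "free"
    base = name
    if "_" in name:
        base, suffix = name.rsplit("_", 1)
        if suffix == "1":
            recalib = 1.0
        elif suffix == "4/3":
            recalib = 4.0 / 3.0
        else:
            raise ValueError(f"unknown recalibration suffix {suffix!r} in {name!r}")
    parts = base.split("-")
    if parts[0] == "Semiparam":
        if len(parts) != 1:
            raise ValueError("the semiparametric model is unisensory only")
        return ModelSpec(name, "Semiparam", "Semiparam", None, recalib)
    if parts[0] == "LiftedSemiparam":
        if len(parts) != 2 or parts[1] not in STRATEGIES:
            raise ValueError(f"malformed lifted model name {name!r}")
        return ModelSpec(name, "Semiparam", "Semiparam", parts[1], recalib,
                         frozen_shapes=frozen_shapes)
    if len(parts) == 2:
        noise, prior = parts
        strategy = None
    elif len(parts) == 3:
        noise, prior, strategy = parts
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown causal strategy {strategy!r}")
    else:
        raise ValueError(f"malformed model name {name!r}")
    if noise not in ("Const", "Exp") or prior not in ("SingleGaussian", "TwoGaussians",
                                                      "GaussianLaplace"):
        raise ValueError(f"unknown component family in {name!r}")
    return ModelSpec(name, noise, prior, strategy, recalib)


def build_model(name, frozen_shapes: dict | None = None) -> ModelSpec:
    """Parse a model name into a :class:`ModelSpec` (registry entry)."""
    if isinstance(name, ModelSpec):
        return name
    return parse_model_name(name, frozen_shapes=frozen_shapes)


def embed_params(sub: ModelSpec, sub_params: dict, sup: ModelSpec) -> dict | None:
    """Embed a fitted nested sub-model's optimum into a larger model's space.

    Const noise embeds into Exp (k1 at its lower bound), SingleGaussian into
    the two mixture priors (omega at its lower bound), and a fixed
    recalibration gain into a free one.  Returns None when ``sub`` is not
    nested in ``sup`` (different scopes, semiparametric shapes, incompatible
    families).
    """
    if sub.lifted or sup.lifted or "Semiparam" in (sub.noise_family, sup.noise_family,
                                                   sub.prior_family, sup.prior_family):
        return None
    if sub.strategy != sup.strategy:
        return None
    out = dict(sub_params)
    if sub.noise_family != sup.noise_family:
        if (sub.noise_family, sup.noise_family) != ("Const", "Exp"):
            return None
        for mod in ("V", "A"):
            out[f"k1_{mod}"] = _BOUNDS["k1"][0]
            out[f"k2_{mod}"] = 0.3
    if sub.prior_family != sup.prior_family:
        if sub.prior_family != "SingleGaussian" or sup.prior_family not in (
                "GaussianLaplace", "TwoGaussians"):
            return None
        out["omega"] = _BOUNDS["omega"][0]
        if sup.prior_family == "GaussianLaplace":
            out["b"] = 2.0
        else:
            out["sigma_delta"] = 8.0
    if sup.recalib == "free" and "rho_A" not in out:
        out["rho_A"] = float(sub.recalib) if sub.recalib != "free" else 1.0
    names = set(sup.parameter_spec.names)
    if not names <= set(out):
        return None
    return {k: out[k] for k in names}


# ---------------- comparison metrics ----------------


def aic_bic(nll: float, n_params: int, n_trials: int) -> tuple:
    """AIC = 2 NLL + 2 k;  BIC = 2 NLL + ln(N) k."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return 2.0 * nll + 2.0 * n_params, 2.0 * nll + np.log(n_trials) * n_params


def lifted_complexity(fit: FitResult, mode: str = "exclude_frozen") -> tuple:
    """AIC/BIC of a lifted fit, counting or not the 35 frozen shape parameters.

    A lifted fit inherits 12 + 12 + 11 shape parameters fitted upstream on the
    unisensory data; ``include_frozen`` charges them to model complexity.
    """
    if not fit.frozen:
        raise ValueError("lifted_complexity requires a lifted fit with a frozen set")
    k = fit.n_params
    if mode == "include_frozen":
        k += N_FROZEN_SHAPE_PARAMS
    elif mode != "exclude_frozen":
        raise ValueError("mode must be include_frozen or exclude_frozen")
    return aic_bic(fit.nll, k, fit.n_trials)


METRICS = ("nll", "aic", "bic")


def _fit_row(fit: FitResult) -> dict:
    aic, bic = aic_bic(fit.nll, fit.n_params, fit.n_trials)
    return {"nll": fit.nll, "aic": aic, "bic": bic,
            "n_params": fit.n_params, "n_trials": fit.n_trials}


def group_comparison(fits: dict, n_boot: int = 10_000, seed: int = 0,
                     metric_best: str = "bic") -> pd.DataFrame:
    """Group-level comparison table from per-participant fits.

    ``fits`` maps model name -> {participant -> FitResult}.  Returns one row
    per model with group-summed NLL/AIC/BIC, the difference of each metric to
    the best model (per metric), and participant-level bootstrap 95% intervals
    of the deltas (resampling participants with replacement).
    """
    models = list(fits)
    participants = sorted(next(iter(fits.values())).keys())
    for m in models:
        if sorted(fits[m].keys()) != participants:
            raise ValueError(f"model {m!r} is missing participant fits")
    per = {m: pd.DataFrame([_fit_row(fits[m][p]) for p in participants],
                           index=participants) for m in models}
    rows = []
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, len(participants), size=(n_boot, len(participants)))
    for m in models:
        row = {"model": m}
        for metric in METRICS:
            row[metric] = per[m][metric].sum()
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")
    for metric in METRICS:
        best = table[metric].idxmin()
        table[f"d{metric}"] = table[metric] - table.loc[best, metric]
        deltas = np.stack([per[m][metric].to_numpy() - per[best][metric].to_numpy()
                           for m in models])  # (models, participants)
        boot = deltas[:, boot_idx].sum(axis=2)  # (models, n_boot)
        table[f"d{metric}_lo"] = np.percentile(boot, 2.5, axis=1)
        table[f"d{metric}_hi"] = np.percentile(boot, 97.5, axis=1)
    return table


def parametric_best(fits: dict) -> dict:
    """ParametricBest aggregation: per participant, per metric, take the best
    model's metric value; sum across participants.  Returns
    {metric: {"total": float, "selected": {participant: model}}}."""
    models = list(fits)
    if not models:
        raise ValueError("empty model family set")
    participants = sorted(next(iter(fits.values())).keys())
    out = {}
    for metric in METRICS:
        total = 0.0
        selected = {}
        for p in participants:
            vals = {m: _fit_row(fits[m][p])[metric] for m in models}
            best = min(vals, key=vals.get)
            selected[p] = best
            total += vals[best]
        out[metric] = {"total": total, "selected": selected}
    return out
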