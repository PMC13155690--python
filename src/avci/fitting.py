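"""Maximum-likelihood fitting: NLL objective, parameter transforms, multi-start
derivative-free optimization.

The objective is the summed negative log likelihood over trials (per-trial
densities floored at 1e-300 before the log).  Every bounded parameter is
mapped to an unconstrained internal coordinate through a sigmoid warp — on a
log axis for scale-like parameters, linear for the rest — so any unconstrained
derivative-free optimizer can be plugged in.  The default optimizer is scipy's
Powell; restarts combine a heuristic default start, Latin-hypercube draws
within bounds, and (for semiparametric shapes) flat-function starts at several
fixed levels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

DENSITY_FLOOR = 1e-300


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(u):
    return np.log(u) - np.log1p(-u)


@dataclass(frozen=True)
class Param:
    """One named, bounded model parameter.

    ``transform`` is 'log' (sigmoid warp on the log axis; scale parameters),
    'logit' (probabilities), or 'linear'.
    """

    name: str
    lo: float
    hi: float
    transform: str = "log"

    def to_internal(self, x: float) -> float:
        if self.transform == "log":
            u = (np.log(x) - np.log(self.lo)) / (np.log(self.hi) - np.log(self.lo))
        else:
            u = (x - self.lo) / (self.hi - self.lo)
        return float(_logit(np.clip(u, 1e-12, 1 - 1e-12)))

    def from_internal(self, z: float) -> float:
        u = _sigmoid(z)
        if self.transform == "log":
            return float(np.exp(np.log(self.lo) + u * (np.log(self.hi) - np.log(self.lo))))
        return float(self.lo + u * (self.hi - self.lo))

    def from_unit(self, u: float) -> float:
        """Map a [0, 1] coordinate to the parameter range (for LHS starts)."""
        u = float(np.clip(u, 1e-9, 1 - 1e-9))
        if self.transform == "log":
            return float(np.exp(np.log(self.lo) + u * (np.log(self.hi) - np.log(self.lo))))
        return float(self.lo + u * (self.hi - self.lo))


@dataclass(frozen=True)
class ParameterSpec:
    """Ordered free parameters of a model; frozen parameters never appear here."""

    params: tuple

    @property
    def names(self) -> list:
        return [p.name for p in self.params]

    def __len__(self) -> int:
        return len(self.params)

    def to_internal(self, values: dict) -> np.ndarray:
        return np.array([p.to_internal(values[p.name]) for p in self.params])

    def from_internal(self, z: np.ndarray) -> dict:
        return {p.name: p.from_internal(zi) for p, zi in zip(self.params, z)}

    def clip_to_bounds(self, values: dict) -> dict:
        out = dict(values)
        for p in self.params:
            eps = 1e-9 * (p.hi - p.lo)
            out[p.name] = float(np.clip(values[p.name], p.lo + eps, p.hi - eps))
        return out


@dataclass
class FitResult:
    """Outcome of a multi-start MLE fit."""

    model_name: str
    params: dict
    nll: float
    n_params: int
    n_trials: int
    restarts: list = field(default_factory=list)
    seed: int = 0
    data_digest: str = ""
    frozen: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": {k: float(v) for k, v in self.params.items()},
            "nll": float(self.nll),
            "n_params": self.n_params,
            "n_trials": self.n_trials,
            "seed": self.seed,
            "data_digest": self.data_digest,
            "restarts": self.restarts,
            "frozen": {k: np.asarray(v).tolist() for k, v in self.frozen.items()},
        }


def data_digest(table: pd.DataFrame) -> str:
    h = hashlib.sha1(pd.util.hash_pandas_object(table, index=False).values.tobytes())
    return h.hexdigest()[:16]


def _restrict_tasks(data: pd.DataFrame, tasks) -> pd.DataFrame:
    if tasks is None:
        return data
    return data[data["task"].isin(tasks)].reset_index(drop=True)


def negative_log_likelihood(params: dict, model, data: pd.DataFrame,
                            tasks=None, grids=None) -> float:
    """Summed NLL of a trial table under a named model (or ModelSpec).

    Trial order does not matter; densities below the floor are clamped so the
    objective stays finite under pathological parameters.
    """
    from avci.zoo import ModelSpec, build_model

    spec = model if isinstance(model, ModelSpec) else build_model(model)
    for v in params.values():
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite parameter value")
    observer = spec.make_model(params, grids=grids)
    table = _restrict_tasks(data, tasks)
    lik = observer.trial_likelihoods(table)
    return float(-np.sum(np.log(np.maximum(lik, DENSITY_FLOOR))))


def powell_optimizer(fun, z0: np.ndarray, budget: int | None = None):
    """Default derivative-free local search in the unconstrained internal space.

    A short second Powell pass from the first optimum resets the direction set,
    which reliably un-sticks the occasional stalled line search at low cost.
    """
    options = {"xtol": 1e-3, "ftol": 1e-5}
    if budget is not None:
        options["maxfev"] = budget
    res = minimize(fun, z0, method="Powell", options=options)
    x, f, nfev = res.x, float(res.fun), int(res.nfev)
    if budget is None or budget >= 400:  # skip for deliberately tiny budgets
        polish = minimize(fun, x, method="Powell",
                          options={"xtol": 1e-3, "ftol": 1e-5, "maxfev": 600})
        if polish.fun < f:
            x, f = polish.x, float(polish.fun)
        nfev += int(polish.nfev)
    return x, f, nfev


def moment_start(spec, table: pd.DataFrame) -> dict:
    """Data-driven initialization from regression/variance moments.

    Unisensory response slopes approximate the shrinkage weight (times rho_A
    for audition); residual SDs around the per-condition regression line seed
    the noise scales and the reliability multipliers.  All values are crude by
    design — they only place the optimizer in the right basin — and are
    clipped into bounds by the caller.
    """
    start = spec.default_start()
    names = set(spec.parameter_spec.names)

    def slope_and_center_sd(sub, s_col):
        s = sub[s_col].to_numpy(dtype=float)
        r = sub["response_loc"].to_numpy(dtype=float)
        ok = np.isfinite(r)
        s, r = s[ok], r[ok]
        if len(s) < 20 or np.var(s) < 1e-9:
            return None, None, None
        a = float(np.cov(s, r)[0, 1] / np.var(s))
        resid = r - a * s
        core = np.abs(resid) < 4 * max(np.std(resid), 1.0)  # trim lapses
        center = np.abs(s) <= 6.0
        sd_c = float(np.std(resid[core & center])) if (core & center).sum() > 10 else None
        sd_p = float(np.std(resid[core & (np.abs(s) > 10)])) if (core & (np.abs(s) > 10)).sum() > 10 else None
        return a, sd_c, sd_p

    ua = table[table["task"] == "UA"]
    a_A = sd0_A = None
    if len(ua):
        a_A, sd0_A, sdp_A = slope_and_center_sd(ua, "s_A")
    uv = table[table["task"] == "UV"]
    sd_by_rel = {}
    a_V = sd0_V = sdp_V = None
    for rel in ("high", "med", "low"):
        sub = uv[uv["reliability"] == rel]
        if len(sub):
            a, sd_c, sd_p = slope_and_center_sd(sub, "s_V")
            sd_by_rel[rel] = sd_c
            if rel == "high":
                a_V, sd0_V, sdp_V = a, sd_c, sd_p

    sig_m = start.get("sigma_motor", 1.0)

    def noise_from_sd(sd, gain):
        if sd is None:
            return None
        return float(np.sqrt(max(sd**2 - sig_m**2, 0.09)) / max(gain, 0.3))

    if a_A is not None and "rho_A" in names:
        start["rho_A"] = float(np.clip(a_A / 0.92, 0.6, 1.9))
    if sd0_A is not None and "sigma0_A" in names:
        g = abs(a_A) if a_A else 1.0
        start["sigma0_A"] = float(np.clip(noise_from_sd(sd0_A, g), 0.1, 25.0))
    if sd0_V is not None and "sigma0_V" in names:
        g = abs(a_V) if a_V else 1.0
        start["sigma0_V"] = float(np.clip(noise_from_sd(sd0_V, g), 0.1, 25.0))
    if sd0_V is not None and sdp_V is not None and "k1_V" in names:
        start["k1_V"] = float(np.clip(np.sqrt(max(sdp_V**2 - sd0_V**2, 1e-4)), 0.1, 30.0))
    if sd_by_rel.get("high") and sd_by_rel.get("med") and "alpha_med" in names:
        start["alpha_med"] = float(np.clip(sd_by_rel["med"] / sd_by_rel["high"], 1.0, 8.0))
    if sd_by_rel.get("high") and sd_by_rel.get("low") and "alpha_low" in names:
        start["alpha_low"] = float(np.clip(sd_by_rel["low"] / sd_by_rel["high"], 1.0, 8.0))
    return start


def fit_mle(model, data: pd.DataFrame, tasks=None, n_starts: int = 3, seed: int = 0,
            optimizer=None, grids=None, warm_starts=None, budget: int | None = None,
            extra_candidates=None) -> FitResult:
    """Multi-start maximum-likelihood fit of a model to one participant's trials.

    ``warm_starts`` is an optional list of parameter dicts appended to the
    restart list (e.g. the generating truth in recovery studies); the returned
    optimum is never worse than any warm start.  ``extra_candidates`` are
    additional parameter dicts that join the start-screening pool (e.g.
    embedded optima of nested sub-models); each costs one NLL evaluation and
    is optimized only if it screens among the best ``n_starts``.
    """
    from avci.zoo import ModelSpec, build_model

    spec = model if isinstance(model, ModelSpec) else build_model(model)
    pspec = spec.parameter_spec
    table = _restrict_tasks(data, tasks)
    if len(table) == 0:
        raise ValueError("no trials in the requested task scope")
    optimizer = optimizer or powell_optimizer

    def objective(z):
        return negative_log_likelihood(pspec.from_internal(z), spec, table, grids=grids)

    # candidate pool: data moments, flat-shape initializations (semiparametric
    # specs only), the fixed heuristic, and Latin-hypercube draws; every
    # candidate is screened by its objective value and the best n_starts are
    # optimized (screening costs one NLL evaluation per candidate)
    pool = [moment_start(spec, table)] + spec.flat_shape_starts() + [spec.default_start()]
    pool += [dict(c) for c in extra_candidates or []]
    n_lhs = max(0, 2 * n_starts - len(pool))
    if n_lhs > 0:
        sampler = qmc.LatinHypercube(d=len(pspec), seed=seed)
        for u in sampler.random(n_lhs):
            pool.append({p.name: p.from_unit(ui) for p, ui in zip(pspec.params, u)})
    n_flat = len(spec.flat_shape_starts())
    flat_idx = set(range(1, 1 + n_flat))
    pool = [pspec.clip_to_bounds(p) for p in pool]
    if n_starts > 0:
        scores = [objective(pspec.to_internal(p)) for p in pool]
        order = list(np.argsort(scores))
        chosen = order[:n_starts]
        # semiparametric fits always explore at least one flat-function start
        if n_flat and n_starts >= 2 and not set(chosen) & flat_idx:
            best_flat = min(flat_idx, key=lambda i: scores[i])
            chosen[-1] = best_flat
        starts = [pool[i] for i in chosen]
    else:
        starts = []
    for w in warm_starts or []:
        starts.append(pspec.clip_to_bounds(w))

    restarts = []
    best_z, best_nll = None, np.inf
    for start in starts:
        z0 = pspec.to_internal(start)
        f0 = objective(z0)
        z, nll, nfev = optimizer(objective, z0, budget)
        # optimizer monotonicity contract: never return worse than the start
        if nll > f0:
            z, nll = z0, f0
        restarts.append({"start": {k: float(v) for k, v in start.items()},
                         "nll": float(nll), "nfev": nfev})
        if nll < best_nll:
            best_z, best_nll = z, nll
    return FitResult(
        model_name=spec.name,
        params=pspec.from_internal(best_z),
        nll=best_nll,
        n_params=len(pspec),
        n_trials=len(table),
        restarts=restarts,
        seed=seed,
        data_digest=data_digest(table),
        frozen=dict(spec.frozen_shapes or {}),
    )


def lift_semiparametric(unisensory_fit: FitResult, data: pd.DataFrame, strategy: str,
                        **fit_kwargs) -> FitResult:
    """Lift a unisensory semiparametric fit to all five tasks.

    The fitted shape parameters (theta_V, theta_A, theta_prior) are frozen;
    the nine context parameters (alpha_med, alpha_low, lapse, sigma_motor,
    rho_A, p_same, beta_V, beta_A, gamma) are refit on the full data.
    """
    from avci.zoo import build_model

    p = unisensory_fit.params
    try:
        frozen = {
            "theta_V": np.array([p[f"theta_V_{j}"] for j in range(12)]),
            "theta_A": np.array([p[f"theta_A_{j}"] for j in range(12)]),
            "theta_prior": np.array([p[f"theta_prior_{j}"] for j in range(1, 12)]),
        }
    except KeyError as err:
        raise ValueError("lifting requires an upstream semiparametric fit") from err
    spec = build_model(f"LiftedSemiparam-{strategy}", frozen_shapes=frozen)
    warm = {k: v for k, v in p.items() if k in spec.parameter_spec.names}
    warm["p_same"] = 0.5
    warm["beta_V"] = 1.1
    warm["beta_A"] = 1.4
    warm["gamma"] = 1.0
    fit_kwargs.setdefault("warm_starts", []).append(warm)
    return fit_mle(spec, data, tasks=None, **fit_kwargs)
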