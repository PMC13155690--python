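"""Sampling-path simulator of observer responses.

The simulator is the generative counterpart of the likelihood engine: instead
of integrating over latent measurements on grids, it draws the measurements,
computes the observer's estimates by direct posterior-mean quadrature at the
sampled measurement, applies the causal strategy by explicit sampling (PM draws
the hypothesis; MS/MA are deterministic given the measurements), adds motor
noise, and lapses with probability lambda.  Because the two paths share only
the low-level posterior-mean quadrature, binned agreement between simulated
responses and engine densities is a strong cross-validation of both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from avci.design import ExperimentDesign, sample_experiment, validate_trials
from avci.engine import HALF_RANGE, ObserverModel


def _simulate_unisensory(model: ObserverModel, s, reliability, modality,
                         rng: np.random.Generator) -> np.ndarray:
    ctx = model.context
    sig = model.sigma_eff(s, modality, reliability, False)
    x = rng.normal(s, sig)
    m = ctx.rho_A * x if modality == "A" else x
    shat = model.posterior_mean_unisensory(m, modality, reliability, False)
    r = rng.normal(shat, ctx.sigma_motor)
    lapse = rng.random(len(s)) < ctx.lapse
    r[lapse] = rng.uniform(-HALF_RANGE, HALF_RANGE, int(lapse.sum()))
    return r


def _draw_bisensory_measurements(model, s_V, s_A, reliability, rng):
    sigV = model.sigma_eff(s_V, "V", reliability, True)
    sigA = model.sigma_eff(s_A, "A", None, True)
    x_V = rng.normal(s_V, sigV)
    m_A = model.context.rho_A * rng.normal(s_A, sigA)
    return x_V, m_A


def _simulate_bc(model, s_V, s_A, reliability, rng) -> np.ndarray:
    ctx = model.context
    x_V, m_A = _draw_bisensory_measurements(model, s_V, s_A, reliability, rng)
    p1 = model.causal_posterior_at(x_V, m_A, reliability)
    if model.strategy in ("MS", "MA"):
        c = np.where(p1 >= 0.5, 1, 2)
    else:  # PM
        c = np.where(rng.random(len(s_V)) < p1, 1, 2)
    lapse = rng.random(len(s_V)) < ctx.lapse
    c[lapse] = rng.integers(1, 3, int(lapse.sum()))
    return c.astype(float)


def _simulate_bloc(model, s_V, s_A, reliability, target, rng) -> np.ndarray:
    ctx = model.context
    x_V, m_A = _draw_bisensory_measurements(model, s_V, s_A, reliability, rng)
    p1 = model.causal_posterior_at(x_V, m_A, reliability)
    fused, single = model.posterior_means_bisensory(x_V, m_A, target, reliability)
    if model.strategy == "MS":
        est = np.where(p1 >= 0.5, fused, single)
    elif model.strategy == "MA":
        est = p1 * fused + (1.0 - p1) * single
    else:  # PM draws the hypothesis per trial
        est = np.where(rng.random(len(s_V)) < p1, fused, single)
    r = rng.normal(est, ctx.sigma_motor)
    lapse = rng.random(len(s_V)) < ctx.lapse
    r[lapse] = rng.uniform(-HALF_RANGE, HALF_RANGE, int(lapse.sum()))
    return r


def simulate_responses(trials: pd.DataFrame, model: ObserverModel, seed: int,
                       chunk: int = 20000) -> pd.DataFrame:
    """Respond to every trial of a stimuli-only table; reproducible under seed."""
    validate_trials(trials)
    out = trials.copy()
    rng = np.random.default_rng(seed)
    task = out["task"].to_numpy()
    rel = out["reliability"].to_numpy(dtype=object)
    r_loc = np.full(len(out), np.nan)
    r_cat = np.full(len(out), np.nan)
    # fixed group iteration order keeps the random stream reproducible
    groups = [("UA", None)] + [(t, lv) for t in ("UV", "BC", "BV", "BA")
                               for lv in ("high", "med", "low")]
    for tname, level in groups:
        sel = task == tname if level is None else (task == tname) & (rel == level)
        idx = np.flatnonzero(sel)
        for lo in range(0, idx.size, chunk):
            ii = idx[lo:lo + chunk]
            sV = out["s_V"].to_numpy(dtype=float)[ii]
            sA = out["s_A"].to_numpy(dtype=float)[ii]
            if tname == "UV":
                r_loc[ii] = _simulate_unisensory(model, sV, level, "V", rng)
            elif tname == "UA":
                r_loc[ii] = _simulate_unisensory(model, sA, None, "A", rng)
            elif tname == "BC":
                r_cat[ii] = _simulate_bc(model, sV, sA, level, rng)
            else:
                r_loc[ii] = _simulate_bloc(model, sV, sA, level,
                                           "V" if tname == "BV" else "A", rng)
    out["response_loc"] = r_loc
    out["response_cat"] = r_cat
    return out


@dataclass
class SimulatedGroup:
    """A responded synthetic group with full provenance."""

    model_name: str
    params: list  # per-participant parameter dicts, exactly as used
    design: ExperimentDesign
    seed: int
    trials: pd.DataFrame

    def provenance(self) -> str:
        return json.dumps(
            {
                "model": self.model_name,
                "seed": self.seed,
                "n_participants": self.design.n_participants,
                "params": self.params,
            },
            indent=2,
            default=float,
        )


#: Generator parameter ranges for synthetic groups, motivated by the fitted
#: group summaries of the experiment (e.g. rho_A near 4/3, beta_A > beta_V > 1,
#: visual noise dipping well below auditory noise at the center).  These are
#: repository defaults for synthetic data, not per-participant estimates.
DEFAULT_PARAM_RANGES = {
    "sigma0_V": (0.4, 1.6),
    "k1_V": (2.0, 6.0),
    "k2_V": (0.15, 0.6),
    "sigma0_A": (1.5, 4.0),
    "k1_A": (3.0, 8.0),
    "k2_A": (0.1, 0.45),
    "sigma_s": (4.0, 12.0),
    "sigma_delta": (4.0, 12.0),
    "b": (1.0, 4.0),
    "omega": (0.3, 0.7),
    "alpha_med": (1.5, 2.6),
    "alpha_low": (2.8, 4.5),
    "beta_V": (1.05, 1.3),
    "beta_A": (1.3, 1.8),
    "rho_A": (1.1, 1.5),
    "p_same": (0.4, 0.7),
    "lapse": (0.02, 0.10),
    "sigma_motor": (0.6, 1.6),
    "gamma": (0.8, 1.2),
}


def spread_group_params(param_names, n_participants: int, seed: int,
                        ranges: dict | None = None, overrides: dict | None = None) -> list:
    """Per-participant generator values spaced evenly across each range.

    Each parameter takes ``n_participants`` evenly spaced values across its
    range, independently permuted across participants (seeded), so every
    parameter has spread at the group level — mimicking the between-subject
    variability of the fitted cohort.  ``overrides`` pins a parameter to one
    value for all participants.
    """
    ranges = {**DEFAULT_PARAM_RANGES, **(ranges or {})}
    overrides = overrides or {}
    rng = np.random.default_rng(seed)
    values = {}
    for name in param_names:
        if name in overrides:
            values[name] = np.full(n_participants, float(overrides[name]))
            continue
        lo, hi = ranges[name]
        grid = np.linspace(lo, hi, n_participants) if n_participants > 1 else np.array(
            [(lo + hi) / 2.0])
        values[name] = rng.permutation(grid)
    return [{k: float(v[i]) for k, v in values.items()} for i in range(n_participants)]


def make_simulated_group(model_name: str, params_source, design: ExperimentDesign,
                         seed: int) -> SimulatedGroup:
    """Sample a full experiment per participant and respond with the named model.

    ``params_source`` is either a list of per-participant parameter dicts or a
    dict of overrides handed to :func:`spread_group_params`.
    """
    from avci.zoo import build_model  # deferred: zoo depends on shapes/engine

    spec = build_model(model_name)
    if isinstance(params_source, dict):
        params = spread_group_params(spec.parameter_spec.names, design.n_participants,
                                     seed, overrides=params_source)
    else:
        params = [dict(p) for p in params_source]
    if len(params) != design.n_participants:
        raise ValueError("one parameter dict per participant is required")
    stimuli = sample_experiment(design, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51D]))
    pieces = []
    for p in range(design.n_participants):
        model = spec.make_model(params[p])
        sub = stimuli[stimuli["participant"] == p]
        pieces.append(simulate_responses(sub, model, int(rng.integers(2**31))))
    table = pd.concat(pieces, ignore_index=True)
    return SimulatedGroup(model_name=spec.name, params=params, design=design,
                          seed=seed, trials=table)
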