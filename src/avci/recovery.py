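"""Model-recovery and parameter-recovery harnesses.

Model recovery: simulate a synthetic group from each candidate model, refit
every candidate to every simulated participant, and tabulate group-summed
NLL/AIC/BIC differences to the generating model (rows).  Successful recovery
means every off-diagonal AIC/BIC cell is positive.

Parameter recovery: simulate from one model, refit the same model, and pair
ground-truth with recovered values per parameter (median absolute relative
error and Spearman rank correlation across simulated participants).

Defaults are scaled down for routine runs (few participants, reduced restart
budget, coarser fitting grids); the experiment-scale run is the same code with
a 15-participant design and a larger budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from avci.design import ExperimentDesign
from avci.engine import GridSpec
from avci.fitting import fit_mle
from avci.simulate import make_simulated_group
from avci.zoo import METRICS, aic_bic, build_model

#: Coarser grids used during recovery fits (validated by grid-convergence tests
#: at default resolution; recovery tolerances are far looser than the grid error).
RECOVERY_GRIDS = GridSpec(s_points=361, n_x=101, x_table_step=0.5, m_table_step=1.0,
                          n_x_bisensory=41)

#: Unisensory candidate subset interpolating between the vanilla model and the
#: best-fitting distilled model.
DEFAULT_CANDIDATES = ("Const-SingleGaussian_1", "Const-GaussianLaplace",
                      "Exp-SingleGaussian", "Exp-GaussianLaplace")


def _unisensory_design(n_participants: int, trials_per_task: int) -> ExperimentDesign:
    return ExperimentDesign(
        n_participants=n_participants,
        trials_per_task={"UV": trials_per_task, "UA": trials_per_task},
    )


@dataclass
class RecoveryMatrix:
    """Generator x fitted-model grids of group-summed metric differences."""

    candidates: tuple
    nll: pd.DataFrame
    aic: pd.DataFrame
    bic: pd.DataFrame
    seed: int
    provenance: dict = field(default_factory=dict)

    def diagonal_is_best(self, metric: str = "bic") -> bool:
        """True when every generator is recovered (all off-diagonal cells > 0)."""
        m = getattr(self, metric).to_numpy()
        off = m[~np.eye(len(m), dtype=bool)]
        return bool(np.all(off > 0.0))


@dataclass
class RecoveryScatter:
    """Paired (true, recovered) parameter values across simulated participants."""

    model_name: str
    true: pd.DataFrame       # participants x parameters
    recovered: pd.DataFrame
    seed: int

    def rank_correlation(self, name: str) -> float:
        rho = spearmanr(self.true[name], self.recovered[name]).statistic
        return float(rho)

    def median_abs_relative_error(self, name: str) -> float:
        t = self.true[name].to_numpy()
        r = self.recovered[name].to_numpy()
        return float(np.median(np.abs(r - t) / np.maximum(np.abs(t), 1e-12)))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.true.columns:
            rows.append({"parameter": name,
                         "rank_correlation": self.rank_correlation(name),
                         "median_abs_rel_error": self.median_abs_relative_error(name)})
        return pd.DataFrame(rows).set_index("parameter")


def _fit_group(model_name, group, tasks, n_starts, seed, grids, budget):
    fits = {}
    spec = build_model(model_name)
    for p in range(group.design.n_participants):
        data = group.trials[group.trials["participant"] == p].reset_index(drop=True)
        fits[p] = fit_mle(spec, data, tasks=tasks, n_starts=n_starts,
                          seed=seed + 131 * p, grids=grids, budget=budget)
    return fits


def _fit_all_candidates(candidates, group, tasks, n_starts, seed, grids, budget):
    """Fit every candidate to every participant, simplest models first.

    Each fit's start screening additionally considers the embedded optima of
    already-fitted nested sub-models, which enforces the nesting inequality
    (a larger model never fits its own data worse than a model it contains)
    at the cost of one NLL evaluation per embedding.
    """
    from avci.zoo import embed_params

    specs = {name: build_model(name) for name in candidates}
    order = sorted(candidates, key=lambda n: specs[n].n_free_params)
    fits = {name: {} for name in candidates}
    for p in range(group.design.n_participants):
        data = group.trials[group.trials["participant"] == p].reset_index(drop=True)
        done = []
        for name in order:
            extra = []
            for prev in done:
                emb = embed_params(specs[prev], fits[prev][p].params, specs[name])
                if emb is not None:
                    extra.append(emb)
            fits[name][p] = fit_mle(specs[name], data, tasks=tasks, n_starts=n_starts,
                                    seed=seed + 131 * p, grids=grids, budget=budget,
                                    extra_candidates=extra)
            done.append(name)
    return fits


def run_model_recovery(candidates=DEFAULT_CANDIDATES, params_source=None,
                       design: ExperimentDesign | None = None, seed: int = 0,
                       n_starts: int = 2, grids: GridSpec | None = None,
                       budget: int | None = None, tasks=("UV", "UA")) -> RecoveryMatrix:
    """Simulate a group per candidate, refit all candidates, difference metrics.

    ``params_source`` maps candidate name -> per-participant parameter dicts or
    override dict (see :func:`avci.simulate.spread_group_params`); defaults to
    the package's generator ranges.
    """
    candidates = tuple(candidates)
    design = design or _unisensory_design(5, 500)
    grids = grids or RECOVERY_GRIDS
    params_source = params_source or {}
    sums = {metric: pd.DataFrame(np.nan, index=candidates, columns=candidates)
            for metric in METRICS}
    provenance = {"design_trials": dict(design.trials_per_task),
                  "n_participants": design.n_participants,
                  "n_starts": n_starts, "seed": seed}
    for gi, gen in enumerate(candidates):
        group = make_simulated_group(gen, params_source.get(gen, {}), design,
                                     seed=seed + 977 * gi)
        all_fits = _fit_all_candidates(candidates, group, tasks, n_starts,
                                       seed + 7 * gi, grids, budget)
        for fitted in candidates:
            metric_sum = dict.fromkeys(METRICS, 0.0)
            for f in all_fits[fitted].values():
                aic, bic = aic_bic(f.nll, f.n_params, f.n_trials)
                metric_sum["nll"] += f.nll
                metric_sum["aic"] += aic
                metric_sum["bic"] += bic
            for metric in METRICS:
                sums[metric].loc[gen, fitted] = metric_sum[metric]
    diffs = {metric: sums[metric].sub(np.diag(sums[metric].to_numpy()), axis=0)
             for metric in METRICS}
    return RecoveryMatrix(candidates=candidates, nll=diffs["nll"], aic=diffs["aic"],
                          bic=diffs["bic"], seed=seed, provenance=provenance)


def run_parameter_recovery(model_name: str, true_params: list,
                           design: ExperimentDesign | None = None, seed: int = 0,
                           n_starts: int = 2, grids: GridSpec | None = None,
                           budget: int | None = None, tasks=("UV", "UA"),
                           warm_start_truth: bool = False) -> RecoveryScatter:
    """Simulate from ``model_name`` at ``true_params`` (one dict per
    participant), refit the same model, and pair true/recovered values."""
    design = design or _unisensory_design(len(true_params), 500)
    if design.n_participants != len(true_params):
        raise ValueError("one parameter dict per participant is required")
    grids = grids or RECOVERY_GRIDS
    group = make_simulated_group(model_name, true_params, design, seed=seed)
    spec = build_model(model_name)
    recovered = []
    for p in range(design.n_participants):
        data = group.trials[group.trials["participant"] == p].reset_index(drop=True)
        warm = [true_params[p]] if warm_start_truth else None
        fit = fit_mle(spec, data, tasks=tasks, n_starts=n_starts, seed=seed + 131 * p,
                      grids=grids, budget=budget, warm_starts=warm)
        recovered.append(fit.params)
    names = spec.parameter_spec.names
    return RecoveryScatter(
        model_name=model_name,
        true=pd.DataFrame([{k: tp[k] for k in names} for tp in true_params]),
        recovered=pd.DataFrame([{k: rp[k] for k in names} for rp in recovered]),
        seed=seed,
    )
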