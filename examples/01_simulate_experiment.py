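"""Simulate the five-task audiovisual experiment for a synthetic group.

Builds the standard design (here shrunk to 2 participants for speed), samples
stimuli, generates responses from a heteroskedastic-noise, mixture-prior
observer with probability-matching causal inference, and writes the trial
table to CSV.
"""

from avci import ExperimentDesign, filter_valid_responses, make_simulated_group, write_trials

design = ExperimentDesign(
    n_participants=2,
    trials_per_task={"UV": 100, "UA": 100, "B": 100, "BC": 100},
)
group = make_simulated_group("Exp-GaussianLaplace-PM", {}, design, seed=7)
table, n_discarded = filter_valid_responses(group.trials)

print(f"simulated {len(table)} trials ({n_discarded} out-of-range discarded)")
print(table.groupby("task").size().to_string())
print("\nfirst trials:")
print(table.head(5).to_string(index=False))
write_trials(table, "scratch_trials.csv")
print("\nwrote scratch_trials.csv; per-participant generating parameters:")
for i, p in enumerate(group.params):
    print(f"  participant {i}: rho_A={p['rho_A']:.2f}  lapse={p['lapse']:.3f}  "
          f"sigma0_V={p['sigma0_V']:.2f}")
# Each row is one trial; localization tasks fill response_loc (degrees),
# the causal task fills response_cat (1 = "same source", 2 = "different").
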