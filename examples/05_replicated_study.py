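"""Small replicated evaluation study.

Loops simulate -> detect -> solve -> calibrate -> score over a grid of
conditions and aggregates the five evaluation criteria: objective before /
after, nuisance-trait correlation, item-parameter MSE, Fisher information,
and between-group SS bias.
"""

from difreduce import SimulationConfig, run_study

grid = [
    SimulationConfig(link="identity", n_respondents=1000, n_items=10, n_dif_items=3),
    SimulationConfig(link="logit", n_respondents=1000, n_items=10, n_dif_items=3),
]
report = run_study(grid, n_replications=3, seed=1)
cols = ["link", "n", "n_dif", "q_before", "q_after", "nuisance_corr",
        "fi_before", "fi_after", "ss_bias_uncorrected", "ss_bias_corrected"]
print(report.table[cols].round(3).to_string(index=False))
# q_after near zero and ss_bias_corrected well below ss_bias_uncorrected
# are the method working as intended; for the identity link the closed form
# reaches an exact zero of the objective.
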