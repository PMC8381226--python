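"""Estimation and significance statistics on a simulated experiment.

Simulates a small population measured under control, Mec and Mec+MLA,
averages the five puffs per cell and condition, then runs the paired
estimation statistics (BCa bootstrap) and the balanced
repeated-measures model, exactly as the full pipeline would.
"""

from puffquant import effects, infer
from puffquant.io import RunConfig, quantify_sweeps, simulate_experiment

cfg = RunConfig(
    seed=4,
    rate=25_000.0,
    n_cells=5,
    n_puffs=5,
    conditions=("control", "Mec", "Mec+MLA"),
)
sweeps = simulate_experiment(cfg)
_, summaries = quantify_sweeps(sweeps, cfg.quantify)

dataset = effects.PairedDataset.from_tidy(summaries, value="mean_area")
summary = effects.estimation_summary(dataset, n_boot=10_000, seed=cfg.seed)
print("paired mean differences (area, mV*ms), 95% BCa intervals:")
for eff in summary["effects"]:
    print(f"  {eff}")

fit = infer.fit_repeated_measures(dataset)
print()
print(
    f"repeated-measures model: F({fit.df1},{fit.df2}) = "
    f"{fit.f_statistic:.2f}, p = {fit.p_value:.2g}"
)
for c in fit.contrasts:
    print(f"  control vs {c.treatment}: t_{c.df} = {c.t:.2f}, p = {c.p_value:.2g}")
print()
print("Each cell is its own control (random intercept); the F statistic")
print("tests the overall drug effect and the t contrasts each drug vs")
print("control, with (k-1)(n-1) denominator degrees of freedom.")
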