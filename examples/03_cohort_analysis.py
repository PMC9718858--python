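"""Full pipeline on a SOM cohort: per-animal rates and the genotype comparison.

Mirrors the study design: 8 wild-type vs 8 APP animals, one value per
animal (mean over its neurons), normality-gated two-group test.
"""

from calcohort import SimulationConfig, run_pipeline, simulate_cohort

config = SimulationConfig(
    cell_types=("SOM",),
    n_animals_per_group=8,
    n_fov_per_animal=1,
    n_neurons_per_fov=6,
    duration_s=120.0,
    seed=3,
)
cohort, truth = simulate_cohort(config)
result = run_pipeline(cohort)

rc = result.report["SOM"]["rate_comparison"]
print(result.per_animal.to_string(index=False))
print()
print(f"WT mean rate:   {rc['mean_wt_hz']:.4f} Hz")
print(f"APP mean rate:  {rc['mean_app_hz']:.4f} Hz")
print(f"fold change:    {rc['fold_change']:.2f}  (generator configured 2.7)")
print(f"{rc['test']}: statistic={rc['statistic']:.3g}, p={rc['p']:.2e} "
      f"(n={rc['n_wt']} vs {rc['n_app']} animals)")
print()
print(
    "A fold change near 2.7 with a small p shows the pipeline recovering "
    "the simulated SOM hyperactivity from raw fluorescence alone."
)
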