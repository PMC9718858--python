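"""Plaque-distance analysis: rates vs distance to the amyloid plaque center.

APP fields of view carry a single plaque; SOM rates are modulated as
rate = base * (1 + A exp(-d / l)) with A = 2 and l = 40 um, so activity
is highest near the plaque.  The pipeline should recover a negative
Spearman correlation and a hot near-plaque (<60 um) bin.
"""

import pandas as pd

from calcohort import SimulationConfig, run_pipeline, simulate_cohort

config = SimulationConfig(
    cell_types=("SOM",),
    n_animals_per_group=8,
    n_fov_per_animal=2,
    n_neurons_per_fov=8,
    duration_s=150.0,
    plaque_modulation_amplitude=2.0,
    plaque_modulation_length_um=40.0,
    seed=100,
)
cohort, _ = simulate_cohort(config)
result = run_pipeline(cohort)
entry = result.report["SOM"]

sp = entry["plaque_distance_spearman"]
print(f"Spearman rate-vs-distance: r={sp['r']:.3f}, p={sp['p']:.2e}, n={sp['n']} neurons")
print()
print(pd.DataFrame(entry["plaque_distance_bins"]).to_string(index=False))
kw = entry["plaque_distance_kruskal"]
print(f"\nKruskal-Wallis across bins: H={kw['H']:.2f}, p={kw['p']:.2e}")
print("Dunn pairwise (Holm-adjusted):")
print(pd.DataFrame(kw["dunn"]).to_string(index=False))
print()
print(
    "The negative r and the <60 um bin's elevated mean rate reproduce the "
    "plaque-proximity hyperactivity the generator planted."
)
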