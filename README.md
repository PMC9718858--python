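# calcohort

Simulation and analysis of two-photon calcium-imaging cohorts, built for
studies of cell-type-specific cortical activity changes in amyloidosis
(APP/PS1) mouse models.

Two-photon recordings of GCaMP-expressing neurons yield, per region of
interest (ROI), a somatic and a surrounding-neuropil fluorescence series.
Turning those into interpretable biology — "SOM interneurons near amyloid
plaques are hyperactive", "PV interneurons are hypoactive" — requires a
chain of analysis steps, each with conventions that matter. `calcohort`
implements that chain as a tested, reusable library, together with a
synthetic cohort generator with known ground truth so every step can be
validated without any external recordings.

## The analysis chain

1. **Normalization.** The neuropil signal is subtracted from the soma with
   weight 0.7; the baseline F₀ is a rolling quantile over a 250-frame
   (50 s at 5 Hz) centered window, with the quantile chosen per neuron
   between the median (quiet cells) and the 10th percentile (active
   cells); ΔF/F = (F − F₀)/F₀.
2. **Event inference.** ΔF/F is deconvolved under a first-order
   autoregressive calcium model, c_t = γ·c_{t−1} + s_t with
   γ = exp(−1/(f·τ)), τ = 1.25 s, f = 5 Hz, minimizing ‖c − ΔF/F‖² subject
   to s_t ∈ {0} ∪ [s_min, ∞) where s_min = 2.5 × the noise level σ
   (estimated per neuron from the high-band power spectral density) and
   the sparsity penalty λ = 0. The solver is a greedy pool-merging scheme
   (OASIS family) with back-tracking; an exhaustive brute-force oracle is
   included for validating it on short traces. A peak-counting
   cross-check (local maxima above 3σ) is computed alongside.
3. **Activity metrics.** Event rate = deconvolved event count / duration;
   a neuron is *active* iff its rate exceeds 0.01 Hz; inactive fractions
   are computed per animal.
4. **Plaque-distance statistics.** In fields of view with exactly one
   amyloid plaque (and none within 100 µm in x, y, z), Euclidean
   ROI-to-plaque distances feed a Spearman rate-vs-distance correlation
   and a three-bin (<60, 60–120, >120 µm) Kruskal–Wallis + Dunn analysis.
5. **Synchrony.** Event trains of active neurons are binarized, corrected
   for within-frame line-scan timing by linear interpolation, and
   correlated pairwise (Pearson ρ) within each field of view; ρ is pooled
   by pairwise distance and by geometric-mean event rate.
6. **Group statistics.** Main comparisons use one value per animal, gated
   by Shapiro–Wilk normality (Student's t vs Mann–Whitney U, exact for
   small tie-free groups); pooled neuron-level rates are compared with a
   two-sample KS test; binned pair correlations with a two-way ANOVA
   (type-II).

The synthetic generator inverts this chain: Poisson event trains at the
cell-type rates (wild-type SOM 0.032 Hz, PV 0.18 Hz), genotype fold
changes (SOM ×2.7 up, PV ×1.8 down, excitatory ×1.6 down), optional
plaque-distance rate modulation `rate = base·(1 + A·e^{−d/ℓ})`,
distance-dependent shared-event co-activation, AR1 kernels, noise and a
shared neuropil component.

## Worked example

```python
from calcohort import SimulationConfig, simulate_cohort, run_pipeline

config = SimulationConfig(cell_types=("SOM",), n_animals_per_group=8,
                          n_fov_per_animal=1, n_neurons_per_fov=6,
                          duration_s=120.0, seed=3)
cohort, truth = simulate_cohort(config)
result = run_pipeline(cohort)
rc = result.report["SOM"]["rate_comparison"]
print(rc["mean_wt_hz"], rc["mean_app_hz"], rc["fold_change"], rc["p"])
```

prints

```
0.0411 Hz   0.0993 Hz   fold 2.41   p = 2.94e-06
```

— the pipeline recovers, from raw fluorescence alone, wild-type SOM rates
near the configured 0.032 Hz (plus shared-event co-activation), an
APP/WT fold change near the configured 2.7, and a decisive animal-level
group difference (8 vs 8 animals). The `examples/` directory has one
short script per capability (simulation, single-trace deconvolution,
cohort analysis, plaque-distance statistics, synchrony pooling); each
prints its numbers with a line on what they mean. A thin CLI wraps the
same calls: `calcohort simulate | analyze | report`.

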