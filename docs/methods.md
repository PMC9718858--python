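# Methods

This note records the models, conventions and design decisions behind
`calcohort`, in the spirit of a methods section: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Preprocessing

Per ROI the raw somatic series F and neuropil series N (arbitrary
fluorescence units) are combined as `corrected = F − 0.7·N`. Negative
corrected values are tolerated; only a non-positive baseline is fatal
(`DegenerateBaselineError`), because ΔF/F = (corrected − F₀)/F₀ is
undefined there.

F₀ is a rolling quantile over a 250-frame window (50 s at 5 Hz). Two
conventions were open and are fixed as follows:

* **Window placement** — centered, truncated at the edges; a trace
  shorter than the window uses one global quantile. Centering avoids a
  phase lag between baseline and signal.
* **Activity-adaptive quantile** — the quantile must range from the
  median (quiet cells) to the 10th percentile (active cells), but the
  mapping from "how active" to "which quantile" is open. We use the
  activity index a = fraction of frames exceeding median + 2·MAD of the
  corrected trace, and q = 0.5 − 0.4·min(a/0.2, 1): a neuron with no
  suprathreshold frames gets the median; one whose transients occupy
  ≥20% of frames gets the 10th percentile. The chosen quantile is
  recorded per neuron (`quantile_used`).

No smoothing is applied after the quantile filter: whether the original
"moving average baselining" convention smooths further is unknown, and
we deliberately do not guess.

The chain is scale-invariant (multiplying both channels by k > 0 leaves
ΔF/F unchanged) and maps noiseless, eventless traces to identically zero
ΔF/F; both properties are tested to float tolerance.

## Noise level

σ is estimated per neuron (not per field of view) as the square root of
the mean Welch power spectral density over [0.25, 0.5] × frame rate,
converted to an equivalent white-noise standard deviation. Calcium
transients with a 1.25 s decay contribute little power in that band, but
transient onsets do leak slightly: on synthetic traces with 1.0 ΔF/F
events over σ = 0.1 noise the estimate runs ~10% high on average, a
conservative bias (it raises the event threshold). Constant traces give
σ = 0.

## Thresholded AR1 deconvolution

Calcium dynamics are modelled as c_t = γ·c_{t−1} + s_t, γ = exp(−Δt/τ)
with τ = 1.25 s (γ ≈ 0.852 at 5 Hz). Deconvolution minimizes
‖c − ΔF/F‖² subject to c ≥ 0 and the hard threshold
s_t ∈ {0} ∪ [s_min, ∞), s_min = 2.5σ, with sparsity penalty λ = 0.
Conventions fixed here:

* The threshold is applied to the event amplitudes s, not to the
  denoised trace c (the constraint could be read either way; s is the
  quantity counted as events).
* The initial condition is treated uniformly: s₀ := c₀ and the threshold
  applies to frame 0 like any other, so the greedy solver and the
  brute-force oracle optimize the identical feasible set.
* One event per frame with s_t > 0; simultaneous events merge.

The solver is a greedy pool-merging scheme: each frame starts as a pool
(value v, weight w, length l) and adjacent pools merge while the event
implied at their boundary, v_next − γ^l·v_prev, falls below s_min.
Within a pool the denoised trace decays geometrically from the pool
value. After the forward pass the first pool is clamped onto
{0} ∪ [s_min, ∞) (choosing whichever admissible value fits its frames
better) and any boundary violation the clamp introduces is resolved by
re-merging. A back-tracking refinement then screens the residual for
events the merge pass absorbed into a neighbouring pool: the
unconstrained amplitude of an extra event at frame u is z_u/‖K_u‖² with
z_u the backward-filtered residual, and candidates whose amplitude lands
*strictly inside* [s_min, ∞) are refit by constrained least squares and
accepted when they lower the objective.

**Why the refinement rejects boundary-pinned additions.** The exact
global minimizer of this objective routinely glues events at exactly
s_min onto pure noise — most often in the last frames of a trace, where
the kernel norm is small: the probability that a final-frame event of
amplitude s_min lowers the squared error is P(N(0,1) > s_min/2σ) ≈ 10.6%
at the 2.5σ threshold, a scale-free constant. Reproducing that behavior
would add spurious events at ~1% of frames and corrupt every rate-based
analysis downstream. The solver therefore deliberately remains a
conservative heuristic: the included exhaustive oracle
(`brute_force_oracle`, support enumeration + bound-constrained least
squares, refusing traces longer than 20 frames) always weakly dominates
it on objective value, and their event supports coincide on roughly
two-thirds of short noisy traces — the remaining third being exactly the
instances where the global optimum absorbs noise at the threshold
boundary. On clean, well-separated transients the two agree exactly, and
exact event-count recovery for isolated 10σ spikes exceeds 95%.

Every output satisfies the reconstruction identity c_t = γ·c_{t−1} + s_t
to 1e−9 and contains no amplitude in (0, s_min); both are enforced
structurally and tested.

## Activity metrics

Rate = event count / duration (Hz). *Active* means rate strictly greater
than 0.01 Hz; *inactive* is its complement under the same threshold (no
separate definition exists, so one shared, configurable gate is used).
Peak counting — local ΔF/F maxima above k·σ with maxima closer than a
minimum separation merged to the larger — uses k = 3 and 1.0 s by
default; the published convention cites prior work without parameters,
so both are exposed in the analysis config. On noiseless well-separated
transients peak counts and deconvolved event counts agree exactly.

## Plaque-distance analysis

Distances are in-plane Euclidean distances from ROI centroid to plaque
center; the 100 µm x/y/z exclusion criterion applies to field-of-view
eligibility (exactly one plaque, none nearby), not to the distance
itself. The three pooling bins are <60, 60–120 and >120 µm; the printed
bin labels leave 60 and 120 ambiguous, and we assign both boundaries to
the middle bin ([60, 120]). Rate-vs-distance association uses Spearman
rank correlation with midranks; constant inputs yield NA rather than an
exception. Bin comparisons use tie-corrected Kruskal–Wallis followed by
Dunn's pairwise z-tests with Holm adjustment (the multiplicity
correction was unspecified; Holm is uniformly more powerful than
Bonferroni at the same family-wise error).

## Synchrony

Event trains of active neurons are binarized to {0, 1}. Because a
raster-scanned frame acquires its rows sequentially, an ROI's true
sample times lag the frame clock by (centroid row / frame height) ×
frame period; each train is shifted by that offset and linearly
interpolated back onto the common grid, spreading an event over at most
two frames with weights in [0, 1]. Pearson ρ is computed on these
interpolated (continuous) trains — they are not re-binarized — for every
unordered pair within a field of view; pairs never span fields of view
(no shared clock). Zero-variance members yield ρ = NA. Pooling uses 6
distance bins spanning the FOV diagonal and 7 log-spaced
geometric-mean-rate bins by default (bin counts chosen to match the
degrees of freedom of the corresponding published ANOVA designs);
per-animal mean ρ averages over all of an animal's pairs, weighting
pairs (not neurons) equally.

## Group statistics

Main comparisons use animals as units: one mean per animal over all its
neurons, pooled equally across fields of view (an alternative —
mean-of-FOV-means — is not used; the choice is documented here and the
aggregation is a single function that could be swapped). The test family
is gated by Shapiro–Wilk at α = 0.05 on every group; groups with n < 3
or zero variance force the nonparametric branch with a warning.
Mann–Whitney U uses the exact null distribution for tie-free groups of
at most 10 (the 5–9 animals-per-group regime), the tie-corrected normal
approximation otherwise. Pooled neuron-level rate distributions use the
two-sample KS test. Binned pair correlations use a two-way ANOVA
(bin × genotype) with type-II sums of squares; empty cells and saturated
designs raise errors rather than producing silently unbalanced fits.

## Synthetic cohort generator

The generator emulates the study design: per cell type (SOM, PV, EX) and
genotype (WT, APP), `n_animals_per_group` animals with
`n_fov_per_animal` fields of view (160 × 100 µm at 1 px/µm, 5 Hz,
≥100 s) of `n_neurons_per_fov` ROIs each. Defaults are the study
conditions: WT-SOM 0.032 Hz, WT-PV 0.18 Hz, fold changes ×2.7 (SOM up),
÷1.8 (PV), ÷1.6 (EX), τ = 1.25 s, 8 animals per group, ~26 neurons per
animal, 120 s recordings. The WT-EX absolute rate is not published and
defaults to 0.10 Hz, intermediate between the interneuron classes.

* **Event trains** are homogeneous Poisson, discretized to frames
  (same-frame events sum their amplitudes when rendered).
* **Plaque modulation**: only a monotone negative rate-distance
  association is established empirically, not a functional form; we use
  rate = base·(1 + A·e^{−d/ℓ}) for its monotonicity and two
  interpretable parameters, applied to SOM neurons in plaque-bearing
  (APP) fields of view. The default is A = 0 so that the configured
  genotype fold change is exactly the expected group ratio;
  plaque-distance studies set A (e.g. 2) and ℓ (40 µm) explicitly. Every
  APP field of view carries exactly one plaque, satisfying the
  eligibility rule by construction.
* **Co-activation**: a pair at distance d shares events at Poisson rate
  p·e^{−d/ℓs}·√(r_i·r_j) (default p = 0.1, ℓs = 50 µm — giving modest
  mean pairwise ρ of a few hundredths, comparable to spontaneous
  cortical activity). Each neuron's independent train is thinned by its
  total expected shared rate, so realized per-neuron rates converge to
  the configured ones (verified at 5% with ≥500 neurons). The coupling
  probability p is rate-independent; the observed increase of mean ρ
  across rate bins arises from finite-sample attenuation of the sample
  correlation at low event counts, fading as event density grows.
* **Rendering**: soma = B·(1 + amplitude·c + σ·ε) + w·shared, with B a
  100 a.u. baseline, c the AR1 response, amplitude 1.0 ΔF/F, σ = 0.1
  (transient SNR 10), ε white Gaussian noise, and `shared` one low-pass
  (~2 s correlation time) series per field of view mixed into every soma
  with the true contamination weight w = 0.7 — the value the analysis
  subtracts, emulating surround-based neuropil estimation. The neuropil
  channel is its own baseline plus the shared series plus independent
  noise. Both channels are clipped at a small positive floor.

The generator is bit-reproducible for a fixed seed and config.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: motion artifacts and registration
errors, photobleaching, ROI segmentation errors and spike-shaped
neuropil transients, indicator nonlinearity (saturation, rise time),
bursting and non-Poisson firing statistics, and plaque geometry beyond a
point center. Recovery results here validate the analysis chain's
correctness, not its robustness to those real-world effects.

## Validation studies and problem sizes

`calcohort.validation` regenerates each study from a seed:
greedy-vs-oracle agreement (200 length-12 traces), exact spike recovery
(100 neurons, 60 s traces, 5 isolated 10σ spikes), fold-change recovery
and Mann–Whitney power (50 seeds × 8 vs 8 animals × 6 neurons × 120 s,
for SOM and PV), plaque-distance recovery (20 seeds × 128 neurons with
distances, A = 2 vs A = 0), synchrony orderings (one strongly coupled
cohort, p = 0.5), and type-I calibration (1000 spike-level replicates of
8 vs 8 animals × 15 neurons). These sizes keep a full validation run in
the low minutes on one CPU while leaving Monte-Carlo margins comfortably
inside the asserted tolerances.

## Known limitations

* The deconvolution solver is a heuristic; its objective can exceed the
  global optimum on traces where that optimum absorbs noise at the
  threshold boundary (see above). This is by design.
* AR2 kernels (explicit rise time), λ > 0 path optimization by residual
  matching, and event-morphology metrics are out of scope.
* The two-way ANOVA requires a fully crossed design; unbalanced designs
  with empty cells are rejected, not approximated.
* Whether the published inactive-cell fractions used the 0.01 Hz gate or
  zero events is unknown; this package uses the single 0.01 Hz gate for
  both, configurable.
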