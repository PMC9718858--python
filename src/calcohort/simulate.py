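"""Synthetic multi-animal calcium-imaging cohorts with known ground truth.

Emulates a two-photon study of spontaneous cortical activity in two
genotypes (wild-type ``WT`` and amyloidosis ``APP``) and three cell
types: SOM and PV inhibitory interneurons and excitatory (``EX``)
neurons.  Each animal contributes several fields of view (FOV,
160 x 100 um at 1 px/um, 5 Hz, >= 100 s); each FOV holds a handful of
ROIs with somatic and surrounding-neuropil fluorescence.

The forward model inverts the analysis chain the package implements:

* homogeneous Poisson event trains at cell-type rates (WT-SOM 0.032 Hz,
  WT-PV 0.18 Hz) scaled by genotype fold changes (SOM x2.7 up, PV /1.8,
  EX /1.6);
* in amyloid-bearing (APP) animals each eligible FOV carries a single
  plaque, and SOM event rates are modulated by plaque distance as
  ``rate = base * (1 + A * exp(-d / l))``;
* pairwise synchrony by shared-event insertion: a pair of neurons at
  distance d co-fires at rate
  ``p * exp(-d / l_sync) * sqrt(rate_i * rate_j)``, and each neuron's
  independent train is thinned by its total expected shared rate so the
  realized per-neuron rate still converges to the configured one;
* an AR1 calcium kernel (decay 1.25 s), multiplicative event amplitude,
  additive Gaussian noise and one shared low-pass neuropil series per
  FOV mixed into every soma with a true contamination weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "SimulationConfig",
    "RoiTrace",
    "FovRecording",
    "Cohort",
    "SyntheticGroundTruth",
    "simulate_spike_train",
    "plaque_modulated_rate",
    "render_trace",
    "simulate_cohort",
]

CELL_TYPES = ("SOM", "PV", "EX")
GENOTYPES = ("WT", "APP")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of a synthetic cohort.

    Rates are events/s; distances and FOV sizes are micrometres; the
    kernel decay is seconds.  Defaults reproduce the study conditions:
    WT-SOM 0.032 Hz and WT-PV 0.18 Hz event rates, SOM rates 2.7-fold
    higher under APP, PV 1.8-fold and EX 1.6-fold lower, a 1.25 s decay
    kernel sampled at 5 Hz, and recordings of at least 100 s.  The WT-EX
    absolute rate is a free parameter (0.10 Hz default, intermediate
    between the two interneuron classes).
    """

    baseline_rate_per_type: dict[str, float] = field(
        default_factory=lambda: {"SOM": 0.032, "PV": 0.18, "EX": 0.10}
    )
    genotype_fold_change: dict[str, float] = field(
        default_factory=lambda: {"SOM": 2.7, "PV": 1 / 1.8, "EX": 1 / 1.6}
    )
    cell_types: tuple[str, ...] = CELL_TYPES
    plaque_modulation_amplitude: float = 0.0
    plaque_modulation_length_um: float = 40.0
    plaque_modulated_types: tuple[str, ...] = ("SOM",)
    kernel_decay_s: float = 1.25
    event_amplitude: float = 1.0
    noise_sigma: float = 0.1
    neuropil_weight_true: float = 0.7
    neuropil_sigma: float = 0.05
    shared_coactivation_prob: float = 0.1
    synchrony_length_scale_um: float = 50.0
    n_animals_per_group: int = 8
    n_fov_per_animal: int = 2
    n_neurons_per_fov: int = 13
    duration_s: float = 120.0
    frame_rate_hz: float = 5.0
    fov_size_um: tuple[float, float] = (160.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for ct in self.cell_types:
            if self.baseline_rate_per_type.get(ct, 0.0) <= 0:
                raise InvalidParameterError(f"baseline rate for {ct} must be > 0")
            if self.genotype_fold_change.get(ct, 0.0) <= 0:
                raise InvalidParameterError(f"fold change for {ct} must be > 0")
        if not 0.0 <= self.shared_coactivation_prob <= 1.0:
            raise InvalidParameterError("shared_coactivation_prob must be in [0, 1]")
        if self.plaque_modulation_length_um <= 0:
            raise InvalidParameterError("plaque_modulation_length_um must be > 0")
        if self.synchrony_length_scale_um <= 0:
            raise InvalidParameterError("synchrony_length_scale_um must be > 0")
        if min(self.n_animals_per_group, self.n_fov_per_animal,
               self.n_neurons_per_fov) < 1:
            raise InvalidParameterError("cohort counts must all be >= 1")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise InvalidParameterError("duration and frame rate must be > 0")
        n_frames = self.duration_s * self.frame_rate_hz
        if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 2:
            raise InvalidParameterError(
                "duration_s * frame_rate_hz must be an integer >= 2"
            )
        if self.noise_sigma < 0 or self.event_amplitude <= 0:
            raise InvalidParameterError("noise_sigma >= 0, event_amplitude > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy of this config with fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RoiTrace:
    """Raw somatic and neuropil fluorescence of one ROI."""

    roi_id: str
    soma_f: np.ndarray
    neuropil_f: np.ndarray
    centroid_xy: tuple[float, float]
    fov_id: str
    frame_rate_hz: float


@dataclass(frozen=True)
class FovRecording:
    """One field of view: its ROIs, optional plaque, and provenance tags."""

    fov_id: str
    animal_id: str
    genotype: str
    cell_type: str
    rois: list[RoiTrace]
    plaque_xy: tuple[float, float] | None
    fov_size_um: tuple[float, float]
    frame_rate_hz: float


@dataclass(frozen=True)
class Cohort:
    """A collection of FOV recordings across animals and genotypes."""

    fovs: list[FovRecording]
    frame_rate_hz: float

    def iter_rois(self):
        for fov in self.fovs:
            for roi in fov.rois:
                yield fov, roi

    @property
    def n_neurons(self) -> int:
        return sum(len(f.rois) for f in self.fovs)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "fov_id": f.fov_id,
                "animal_id": f.animal_id,
                "genotype": f.genotype,
                "cell_type": f.cell_type,
                "n_rois": len(f.rois),
                "has_plaque": f.plaque_xy is not None,
            }
            for f in self.fovs
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover.

    ``neurons`` has one row per ROI with true realized rate (spike count
    over duration, shared events included), the intended rate the train
    was drawn at, and plaque distance where a plaque exists.
    ``spikes`` maps (fov_id, roi_id) to spike frame indices (repeats
    allowed: same-frame spikes sum their amplitudes when rendered).
    ``coactivation`` maps ROI pairs to their shared-event counts.
    """

    neurons: pd.DataFrame
    spikes: dict[tuple[str, str], np.ndarray]
    coactivation: dict[tuple[str, str, str], int]
    modulation_amplitude: float
    modulation_length_um: float
    seed: int


def simulate_spike_train(
    rate_hz: float,
    duration_s: float,
    frame_rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homogeneous Poisson event train discretized to frame indices.

    Returns sorted frame indices; multiple events may land in one frame.
    """
    if rate_hz < 0:
        raise InvalidParameterError(f"rate must be >= 0, got {rate_hz}")
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise InvalidParameterError("duration and frame rate must be > 0")
    n = rng.poisson(rate_hz * duration_s)
    times = rng.uniform(0.0, duration_s, size=n)
    frames = np.floor(times * frame_rate_hz).astype(np.int64)
    n_frames = int(round(duration_s * frame_rate_hz))
    return np.sort(np.minimum(frames, n_frames - 1))


def plaque_modulated_rate(
    base_rate_hz: float, distance_um: float, amplitude: float, length_um: float
) -> float:
    """Event rate near an amyloid plaque: base * (1 + A * exp(-d / l)).

    For A > 0 the rate is highest at the plaque and decays to the base
    rate far away, matching the observed negative rate-vs-distance
    correlation of SOM interneurons in amyloid-bearing cortex.
    """
    if length_um <= 0:
        raise InvalidParameterError(f"length scale must be > 0, got {length_um}")
    if distance_um < 0:
        raise InvalidParameterError(f"distance must be >= 0, got {distance_um}")
    return base_rate_hz * (1.0 + amplitude * np.exp(-distance_um / length_um))


def _ar1_convolve(spike_frames: np.ndarray, n_frames: int, gamma: float) -> np.ndarray:
    """Unit-amplitude AR1 calcium response to a spike train."""
    drive = np.zeros(n_frames)
    if spike_frames.size:
        np.add.at(drive, spike_frames, 1.0)
    c = np.empty(n_frames)
    acc = 0.0
    for t in range(n_frames):
        acc = gamma * acc + drive[t]
        c[t] = acc
    return c


def render_trace(
    spike_frames: np.ndarray,
    n_frames: int,
    kernel_decay_s: float,
    amplitude: float,
    baseline_fluorescence: float,
    noise_sigma: float,
    shared_neuropil_series: np.ndarray | None,
    frame_rate_hz: float,
    rng: np.random.Generator,
    *,
    roi_id: str = "roi",
    fov_id: str = "fov",
    centroid_xy: tuple[float, float] = (0.0, 0.0),
    neuropil_weight_true: float = 0.0,
    neuropil_baseline: float | None = None,
) -> RoiTrace:
    """Forward-render somatic and neuropil fluorescence from a spike train.

    soma = B * (1 + amplitude * c + noise) + w_true * shared, where c is
    the AR1 response (``gamma = exp(-1/(frame_rate * decay))``), noise is
    white Gaussian with sd ``noise_sigma`` in dF/F units, and the shared
    neuropil series contaminates the soma with weight ``w_true``.  The
    neuropil channel is its own baseline plus the shared series plus
    independent noise.  Both channels are clipped at a small positive
    floor so fluorescence stays physical.
    """
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if amplitude <= 0 or baseline_fluorescence <= 0:
        raise InvalidParameterError("amplitude and baseline must be > 0")
    spike_frames = np.asarray(spike_frames, dtype=np.int64)
    if spike_frames.size and (spike_frames.min() < 0 or spike_frames.max() >= n_frames):
        raise InvalidParameterError("spike frames outside the recording")
    gamma = np.exp(-1.0 / (frame_rate_hz * kernel_decay_s))
    c = _ar1_convolve(spike_frames, n_frames, gamma)
    shared = (
        np.zeros(n_frames)
        if shared_neuropil_series is None
        else np.asarray(shared_neuropil_series, dtype=float)
    )
    npil_base = (
        0.3 * baseline_fluorescence if neuropil_baseline is None else neuropil_baseline
    )
    B = baseline_fluorescence
    soma = B * (1.0 + amplitude * c + noise_sigma * rng.standard_normal(n_frames))
    soma = soma + neuropil_weight_true * shared
    npil = npil_base + shared + B * noise_sigma * rng.standard_normal(n_frames)
    floor = 1e-3 * B
    return RoiTrace(
        roi_id=roi_id,
        soma_f=np.maximum(soma, floor),
        neuropil_f=np.maximum(npil, floor),
        centroid_xy=centroid_xy,
        fov_id=fov_id,
        frame_rate_hz=frame_rate_hz,
    )


def _shared_neuropil(n_frames: int, sigma_au: float, frame_rate_hz: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered Gaussian series emulating FOV-wide neuropil drift."""
    rho = float(np.exp(-1.0 / (frame_rate_hz * 2.0)))  # ~2 s correlation time
    x = np.empty(n_frames)
    acc = 0.0
    innov = rng.standard_normal(n_frames) * np.sqrt(1 - rho**2)
    for t in range(n_frames):
        acc = rho * acc + innov[t]
        x[t] = acc
    return sigma_au * x


def _place_rois(n: int, fov: tuple[float, float], rng: np.random.Generator,
                min_sep: float = 8.0) -> np.ndarray:
    """Uniform ROI centroids with a minimum separation (soma diameter)."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        p = rng.uniform((0, 0), fov)
        attempts += 1
        if attempts > 2000 or all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SyntheticGroundTruth]:
    """Generate a full multi-animal cohort and its ground truth.

    For each cell type in ``config.cell_types`` and each genotype,
    ``n_animals_per_group`` animals are simulated.  Every FOV of an APP
    animal carries exactly one plaque (so each satisfies the
    single-plaque eligibility rule by construction); SOM rates in APP
    animals are plaque-distance modulated.  Bit-reproducible for a fixed
    seed and config.
    """
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    fovs: list[FovRecording] = []
    rows: list[dict] = []
    spikes: dict[tuple[str, str], np.ndarray] = {}
    coactivation: dict[tuple[str, str, str], int] = {}

    for cell_type in config.cell_types:
        base_wt = config.baseline_rate_per_type[cell_type]
        fold = config.genotype_fold_change[cell_type]
        for genotype in GENOTYPES:
            base = base_wt * (fold if genotype == "APP" else 1.0)
            for a in range(config.n_animals_per_group):
                animal_id = f"{genotype}-{cell_type}-{a:02d}"
                for f in range(config.n_fov_per_animal):
                    fov_id = f"{animal_id}-fov{f}"
                    xy = _place_rois(config.n_neurons_per_fov, config.fov_size_um, rng)
                    plaque = (
                        tuple(rng.uniform((0, 0), config.fov_size_um))
                        if genotype == "APP"
                        else None
                    )
                    # intended per-neuron rates
                    rates = np.full(len(xy), base)
                    dists = np.full(len(xy), np.nan)
                    if plaque is not None:
                        dists = np.linalg.norm(xy - np.asarray(plaque), axis=1)
                        if cell_type in config.plaque_modulated_types:
                            rates = np.array(
                                [
                                    plaque_modulated_rate(
                                        base,
                                        d,
                                        config.plaque_modulation_amplitude,
                                        config.plaque_modulation_length_um,
                                    )
                                    for d in dists
                                ]
                            )
                    # distance-dependent co-activation rates per pair; the
                    # independent trains are thinned by each neuron's total
                    # expected shared rate so the realized per-neuron rate
                    # converges to the configured one
                    n_roi = len(xy)
                    lam = np.zeros((n_roi, n_roi))
                    for i in range(n_roi):
                        for j in range(i + 1, n_roi):
                            d_ij = float(np.linalg.norm(xy[i] - xy[j]))
                            lam[i, j] = (
                                config.shared_coactivation_prob
                                * np.exp(-d_ij / config.synchrony_length_scale_um)
                                * np.sqrt(rates[i] * rates[j])
                            )
                    shared_load = lam.sum(axis=1) + lam.sum(axis=0)
                    trains = [
                        simulate_spike_train(
                            max(rates[i] - shared_load[i], 0.0),
                            config.duration_s,
                            config.frame_rate_hz,
                            rng,
                        )
                        for i in range(n_roi)
                    ]
                    for i in range(n_roi):
                        for j in range(i + 1, n_roi):
                            shared_frames = simulate_spike_train(
                                lam[i, j], config.duration_s, config.frame_rate_hz, rng
                            )
                            if shared_frames.size:
                                trains[i] = np.sort(
                                    np.concatenate([trains[i], shared_frames])
                                )
                                trains[j] = np.sort(
                                    np.concatenate([trains[j], shared_frames])
                                )
                            coactivation[(fov_id, f"roi{i:03d}", f"roi{j:03d}")] = int(
                                shared_frames.size
                            )
                    shared_npil = _shared_neuropil(
                        n_frames,
                        config.neuropil_sigma * 100.0,  # a.u. on a baseline of 100
                        config.frame_rate_hz,
                        rng,
                    )
                    rois = []
                    for i, train in enumerate(trains):
                        roi_id = f"roi{i:03d}"
                        roi = render_trace(
                            train,
                            n_frames,
                            config.kernel_decay_s,
                            config.event_amplitude,
                            100.0,
                            config.noise_sigma,
                            shared_npil,
                            config.frame_rate_hz,
                            rng,
                            roi_id=roi_id,
                            fov_id=fov_id,
                            centroid_xy=(float(xy[i, 0]), float(xy[i, 1])),
                            neuropil_weight_true=config.neuropil_weight_true,
                        )
                        rois.append(roi)
                        spikes[(fov_id, roi_id)] = train
                        rows.append(
                            {
                                "fov_id": fov_id,
                                "roi_id": roi_id,
                                "animal_id": animal_id,
                                "genotype": genotype,
                                "cell_type": cell_type,
                                "x_um": float(xy[i, 0]),
                                "y_um": float(xy[i, 1]),
                                "intended_rate_hz": float(rates[i]),
                                "true_rate_hz": train.size / config.duration_s,
                                "distance_to_plaque_um": float(dists[i]),
                            }
                        )
                    fovs.append(
                        FovRecording(
                            fov_id=fov_id,
                            animal_id=animal_id,
                            genotype=genotype,
                            cell_type=cell_type,
                            rois=rois,
                            plaque_xy=plaque,
                            fov_size_um=config.fov_size_um,
                            frame_rate_hz=config.frame_rate_hz,
                        )
                    )

    cohort = Cohort(fovs=fovs, frame_rate_hz=config.frame_rate_hz)
    truth = SyntheticGroundTruth(
        neurons=pd.DataFrame(rows),
        spikes=spikes,
        coactivation=coactivation,
        modulation_amplitude=config.plaque_modulation_amplitude,
        modulation_length_um=config.plaque_modulation_length_um,
        seed=config.seed,
    )
    return cohort, truth
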