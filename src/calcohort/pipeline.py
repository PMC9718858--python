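"""End-to-end orchestration: traces -> dF/F -> events -> spatial/synchrony -> stats.

:func:`run_pipeline` turns a :class:`~calcohort.simulate.Cohort` into a
results bundle of tidy tables (per-neuron summaries, pair correlations,
per-animal aggregates) plus a statistics report keyed by cell type.  The
pipeline is a pure function of its inputs and configuration; it draws no
random numbers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import preprocess, spatial, stats, synchrony
from .deconvolve import Ar1Model, deconvolve_ar1_thresholded
from .exceptions import InvalidParameterError
from .simulate import Cohort

__all__ = ["AnalysisConfig", "PipelineResult", "run_pipeline", "write_results"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable constants of the analysis chain in one place.

    Defaults are the study's published parameters: neuropil weight 0.7,
    250-frame baseline window, 1.25 s indicator decay, event threshold
    2.5x noise, lambda 0, 0.01 Hz active gate, distance bins at 60 and
    120 um, 100 um plaque exclusion radius.
    """

    neuropil_weight: float = preprocess.DEFAULT_NEUROPIL_WEIGHT
    baseline_window_frames: int = preprocess.DEFAULT_WINDOW_FRAMES
    baseline_quantile: float | None = None  # None -> activity-adaptive rule
    decay_time_s: float = 1.25
    s_min_multiplier: float = 2.5
    sparsity_lambda: float = 0.0
    active_threshold_hz: float = ev.ACTIVE_THRESHOLD_HZ
    distance_bin_edges_um: tuple[float, float] = spatial.DISTANCE_BIN_EDGES
    exclusion_radius_um: float = spatial.EXCLUSION_RADIUS_UM
    n_distance_pools: int = synchrony.N_DISTANCE_BINS
    n_rate_pools: int = synchrony.N_RATE_BINS
    peak_k_sd: float = ev.PEAK_K_SD
    peak_min_separation_s: float = ev.PEAK_MIN_SEPARATION_S
    dunn_p_adjust: str = "holm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.active_threshold_hz <= 0 or self.decay_time_s <= 0:
            raise InvalidParameterError("thresholds must be positive")
        if self.s_min_multiplier <= 0 or self.baseline_window_frames < 1:
            raise InvalidParameterError("thresholds must be positive")
        lo, hi = self.distance_bin_edges_um
        if not 0 < lo < hi:
            raise InvalidParameterError("distance bin edges must be increasing")


@dataclass
class PipelineResult:
    """Tables and reports produced by one pipeline run."""

    neurons: pd.DataFrame
    pairs: pd.DataFrame
    per_animal: pd.DataFrame
    report: dict
    config: AnalysisConfig
    manifest: dict = field(default_factory=dict)


def _analyze_roi(roi, cfg: AnalysisConfig):
    dff = preprocess.dff_from_raw(
        roi.soma_f,
        roi.neuropil_f,
        weight=cfg.neuropil_weight,
        window_frames=cfg.baseline_window_frames,
        quantile=cfg.baseline_quantile,
    )
    model = Ar1Model.from_trace(
        dff.dff,
        roi.frame_rate_hz,
        decay_time_s=cfg.decay_time_s,
        s_min_multiplier=cfg.s_min_multiplier,
        sparsity_lambda=cfg.sparsity_lambda,
    )
    train = deconvolve_ar1_thresholded(dff.dff, model)
    peaks = ev.count_peaks(
        dff.dff,
        model.noise_sigma,
        k_sd=cfg.peak_k_sd,
        min_separation_s=cfg.peak_min_separation_s,
        frame_rate_hz=roi.frame_rate_hz,
    )
    return dff, model, train, peaks


def run_pipeline(cohort: Cohort, config: AnalysisConfig | None = None) -> PipelineResult:
    """Run the full analysis on a cohort and assemble the results bundle."""
    cfg = config or AnalysisConfig()
    if not cohort.fovs:
        raise InvalidParameterError("empty cohort")

    rows = []
    all_pairs = []
    for fov in cohort.fovs:
        trains: dict[str, object] = {}
        rates: dict[str, float] = {}
        centroids: dict[str, tuple[float, float]] = {}
        plaque = spatial.PlaqueField.assess(
            fov.fov_id,
            [fov.plaque_xy] if fov.plaque_xy is not None else [],
            exclusion_radius_um=cfg.exclusion_radius_um,
        )
        for roi in fov.rois:
            dff, model, train, peaks = _analyze_roi(roi, cfg)
            rate = ev.event_rate(train)
            dist = (
                spatial.distance_to_plaque(roi.centroid_xy, plaque.plaque_center_xy)
                if plaque.eligible
                else np.nan
            )
            rows.append(
                {
                    "fov_id": fov.fov_id,
                    "roi_id": roi.roi_id,
                    "animal_id": fov.animal_id,
                    "genotype": fov.genotype,
                    "cell_type": fov.cell_type,
                    "x_um": roi.centroid_xy[0],
                    "y_um": roi.centroid_xy[1],
                    "rate_hz": rate,
                    "active": ev.classify_active(rate, cfg.active_threshold_hz),
                    "event_count": train.event_count,
                    "peak_count": peaks,
                    "peak_rate_hz": peaks / train.duration_s,
                    "noise_sigma": model.noise_sigma,
                    "quantile_used": dff.quantile_used,
                    "distance_to_plaque_um": dist,
                }
            )
            trains[roi.roi_id] = train
            rates[roi.roi_id] = rate
            centroids[roi.roi_id] = roi.centroid_xy
        active_series = {
            rid: synchrony.binarize_and_timeshift(
                trains[rid],
                min(max(centroids[rid][1], 0.0), fov.fov_size_um[1]),
                fov.fov_size_um[1],
                fov.frame_rate_hz,
            )
            for rid in trains
            if rates[rid] > cfg.active_threshold_hz
        }
        pairs = synchrony.pairwise_pearson(
            active_series, rates, centroids, fov_id=fov.fov_id
        )
        for p in pairs:
            all_pairs.append(
                {
                    "fov_id": p.fov_id,
                    "animal_id": fov.animal_id,
                    "genotype": fov.genotype,
                    "cell_type": fov.cell_type,
                    "roi_i": p.roi_i,
                    "roi_j": p.roi_j,
                    "rho": p.rho,
                    "pair_distance_um": p.pair_distance_um,
                    "geom_mean_rate_hz": p.geom_mean_rate_hz,
                }
            )

    neurons = pd.DataFrame(rows)
    pairs_df = pd.DataFrame(
        all_pairs,
        columns=[
            "fov_id", "animal_id", "genotype", "cell_type",
            "roi_i", "roi_j", "rho", "pair_distance_um", "geom_mean_rate_hz",
        ],
    )
    per_animal = stats.aggregate_per_animal(neurons, value="rate_hz")
    report = build_report(neurons, pairs_df, cfg)
    manifest = {
        "config": asdict(cfg),
        "n_fovs": len(cohort.fovs),
        "n_neurons": len(neurons),
        "n_pairs": len(pairs_df),
    }
    return PipelineResult(
        neurons=neurons,
        pairs=pairs_df,
        per_animal=per_animal,
        report=report,
        config=cfg,
        manifest=manifest,
    )


def build_report(
    neurons: pd.DataFrame, pairs: pd.DataFrame, cfg: AnalysisConfig
) -> dict:
    """Statistics report keyed by cell type, mirroring the figure battery:

    per-animal WT-vs-APP rate comparison, pooled KS on neuron rates,
    inactive-cell fractions, plaque-distance Spearman and bin tests
    (plaque-bearing FOVs only), and pooled pair-correlation analyses.
    """
    report: dict = {}
    for cell_type, sub in neurons.groupby("cell_type", sort=True):
        entry: dict = {}
        wt = sub[sub["genotype"] == "WT"]
        app = sub[sub["genotype"] == "APP"]
        if len(wt) and len(app):
            wt_means = stats.aggregate_per_animal(wt)["mean_rate_hz"].to_numpy()
            app_means = stats.aggregate_per_animal(app)["mean_rate_hz"].to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_res = stats.compare_group_means(wt_means, app_means)
            entry["rate_comparison"] = {
                "test": cmp_res.test_name,
                "statistic": cmp_res.statistic,
                "p": cmp_res.p_value,
                "n_wt": int(wt_means.size),
                "n_app": int(app_means.size),
                "mean_wt_hz": float(wt_means.mean()),
                "mean_app_hz": float(app_means.mean()),
                "fold_change": float(app_means.mean() / wt_means.mean())
                if wt_means.mean() > 0
                else float("nan"),
            }
            if len(wt) >= 5 and len(app) >= 5:
                ks = stats.compare_rate_distributions(
                    wt["rate_hz"].to_numpy(), app["rate_hz"].to_numpy()
                )
                entry["rate_distribution_ks"] = {
                    "D": ks.statistic,
                    "p": ks.p_value,
                    "n_wt": int(len(wt)),
                    "n_app": int(len(app)),
                }
            inact = (
                sub.groupby("animal_id")
                .apply(lambda g: ev.inactive_fraction(g), include_groups=False)
                .rename("inactive_fraction")
                .reset_index()
                .merge(
                    sub[["animal_id", "genotype"]].drop_duplicates(), on="animal_id"
                )
            )
            entry["inactive_fraction_per_animal"] = inact.to_dict(orient="records")

        withdist = app.dropna(subset=["distance_to_plaque_um"])
        if len(withdist) >= 3:
            r, p, n = spatial.rate_distance_spearman(withdist)
            entry["plaque_distance_spearman"] = {"r": r, "p": p, "n": n}
            bins = spatial.bin_rates_by_distance(withdist)
            entry["plaque_distance_bins"] = bins.to_dict(orient="records")
            groups = {
                label: grp["rate_hz"].to_numpy()
                for label, grp in withdist.assign(
                    b=withdist["distance_to_plaque_um"].map(
                        spatial.assign_distance_bin
                    )
                ).groupby("b")
            }
            if len(groups) == 3 and all(v.size >= 2 for v in groups.values()):
                omni, dunn = stats.compare_distance_bins(
                    groups, p_adjust=cfg.dunn_p_adjust
                )
                entry["plaque_distance_kruskal"] = {
                    "H": omni.statistic,
                    "p": omni.p_value,
                    "dunn": dunn.to_dict(orient="records"),
                }

        ct_pairs = pairs[pairs["cell_type"] == cell_type]
        if len(ct_pairs):
            entry["synchrony"] = _synchrony_report(ct_pairs, cfg)
        report[cell_type] = entry
    return report


def _synchrony_report(ct_pairs: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    out: dict = {}
    by_animal = (
        ct_pairs.dropna(subset=["rho"])
        .groupby("animal_id")
        .agg(mean_rho=("rho", "mean"), genotype=("genotype", "first"))
        .reset_index()
    )
    out["per_animal_mean_rho"] = by_animal.to_dict(orient="records")
    wt_rho = by_animal.loc[by_animal["genotype"] == "WT", "mean_rho"].to_numpy()
    app_rho = by_animal.loc[by_animal["genotype"] == "APP", "mean_rho"].to_numpy()
    if wt_rho.size >= 2 and app_rho.size >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_res = stats.compare_group_means(wt_rho, app_rho)
        out["rho_comparison"] = {
            "test": cmp_res.test_name,
            "statistic": cmp_res.statistic,
            "p": cmp_res.p_value,
        }
    limits = synchrony.default_distance_limits(n_bins=cfg.n_distance_pools)
    edges = synchrony.default_rate_edges(n_bins=cfg.n_rate_pools)
    out["pooled_by_distance"] = synchrony.pool_pairs_by_distance(
        ct_pairs, limits
    ).to_dict(orient="records")
    out["pooled_by_rate"] = synchrony.pool_pairs_by_rate(ct_pairs, edges).to_dict(
        orient="records"
    )
    return out


def write_results(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write the results bundle: CSV tables, JSON report and run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.neurons.to_csv(out / "neurons.csv", index=False)
    result.pairs.to_csv(out / "pairs.csv", index=False)
    result.per_animal.to_csv(out / "per_animal.csv", index=False)
    (out / "report.json").write_text(json.dumps(result.report, indent=2, default=float))
    (out / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=str)
    )
    return out
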