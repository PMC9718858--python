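"""Pairwise synchrony of active neurons.

Deconvolved event trains are binarized, corrected for within-frame
line-scan timing (an ROI lower in a raster-scanned frame is acquired
later by up to one frame period), and correlated pairwise with Pearson's
rho.  Pairs are formed within a field of view only, between neurons
passing the 0.01 Hz active gate.  Two pooling analyses mirror how
synchrony is summarised: mean rho by pairwise distance (6 bins spanning
the FOV diagonal by default) and by geometric-mean event rate (7
log-spaced bins by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolve import EventTrain
from .exceptions import InvalidParameterError

__all__ = [
    "PairCorrelation",
    "binarize_and_timeshift",
    "pairwise_pearson",
    "pool_pairs_by_distance",
    "pool_pairs_by_rate",
    "default_distance_limits",
    "default_rate_edges",
]

N_DISTANCE_BINS = 6
N_RATE_BINS = 7


@dataclass(frozen=True)
class PairCorrelation:
    """Pearson rho for one active-neuron pair with its covariates."""

    fov_id: str
    roi_i: str
    roi_j: str
    rho: float
    pair_distance_um: float
    geom_mean_rate_hz: float


def binarize_and_timeshift(
    train: EventTrain,
    centroid_y_um: float,
    fov_height_um: float,
    frame_rate_hz: float,
) -> np.ndarray:
    """Binarized event train resampled onto the common frame clock.

    The ROI's samples are acquired at ``t_k + (y / H) / frame_rate``;
    linear interpolation back onto the nominal frame times spreads each
    binary event over at most two adjacent frames, with weights in
    [0, 1] summing to 1 in the interior.
    """
    if not 0.0 <= centroid_y_um <= fov_height_um:
        raise InvalidParameterError(
            f"centroid y={centroid_y_um} outside FOV height {fov_height_um}"
        )
    b = (np.asarray(train.event_amplitudes, dtype=float) > 0).astype(float)
    offset = (centroid_y_um / fov_height_um) / frame_rate_hz
    if offset == 0.0:
        return b
    t = np.arange(b.size) / frame_rate_hz
    return np.interp(t, t + offset, b, left=b[0])


def pairwise_pearson(
    series: dict[str, np.ndarray],
    rates_hz: dict[str, float],
    centroids_xy: dict[str, tuple[float, float]],
    fov_id: str = "fov",
) -> list[PairCorrelation]:
    """Pearson rho for every unordered pair of active neurons in one FOV.

    ``series`` maps roi_id to its timing-corrected train; only neurons
    present in ``series`` (i.e. already gated as active) are paired.  A
    pair containing a zero-variance series gets rho = NaN.
    """
    ids = sorted(series)
    if len(ids) < 2:
        return []
    pairs: list[PairCorrelation] = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            x, y = series[i], series[j]
            if x.size != y.size:
                raise InvalidParameterError("paired series must share the frame grid")
            if np.std(x) == 0 or np.std(y) == 0:
                rho = float("nan")
            else:
                rho = float(np.corrcoef(x, y)[0, 1])
            d = float(
                np.linalg.norm(
                    np.asarray(centroids_xy[i]) - np.asarray(centroids_xy[j])
                )
            )
            pairs.append(
                PairCorrelation(
                    fov_id=fov_id,
                    roi_i=i,
                    roi_j=j,
                    rho=rho,
                    pair_distance_um=d,
                    geom_mean_rate_hz=float(np.sqrt(rates_hz[i] * rates_hz[j])),
                )
            )
    return pairs


def pairs_to_frame(pairs: list[PairCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "fov_id": p.fov_id,
                "roi_i": p.roi_i,
                "roi_j": p.roi_j,
                "rho": p.rho,
                "pair_distance_um": p.pair_distance_um,
                "geom_mean_rate_hz": p.geom_mean_rate_hz,
            }
            for p in pairs
        ]
    )


def default_distance_limits(
    fov_size_um: tuple[float, float] = (160.0, 100.0),
    n_bins: int = N_DISTANCE_BINS,
) -> np.ndarray:
    """Upper limits of the distance pools, spanning the FOV diagonal."""
    diag = float(np.hypot(*fov_size_um))
    return np.linspace(diag / n_bins, diag, n_bins)


def default_rate_edges(
    min_rate_hz: float = 0.01, max_rate_hz: float = 1.0, n_bins: int = N_RATE_BINS
) -> np.ndarray:
    """Log-spaced geometric-mean-rate bin edges (n_bins + 1 edges)."""
    return np.geomspace(min_rate_hz, max_rate_hz, n_bins + 1)


def _pool(df: pd.DataFrame, bin_index: np.ndarray, labels: list[str]) -> pd.DataFrame:
    out_rows = []
    for k, label in enumerate(labels):
        sel = df.loc[bin_index == k, "rho"].dropna()
        out_rows.append(
            {
                "bin": label,
                "n_pairs": int(sel.size),
                "mean_rho": float(sel.mean()) if sel.size else float("nan"),
                "sem_rho": float(sel.sem()) if sel.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(out_rows)


def pool_pairs_by_distance(
    pairs: list[PairCorrelation] | pd.DataFrame,
    bin_upper_limits_um: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and s.e.m. of rho per pairwise-distance pool.

    Pools are defined by their upper limits; a pair belongs to the first
    pool whose limit is >= its distance.  Empty pools are reported with
    count 0 and NaN mean.
    """
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    if df.empty:
        raise InvalidParameterError("need at least one pair")
    limits = (
        default_distance_limits()
        if bin_upper_limits_um is None
        else np.asarray(bin_upper_limits_um, dtype=float)
    )
    idx = np.searchsorted(limits, df["pair_distance_um"].to_numpy(), side="left")
    idx = np.minimum(idx, limits.size - 1)  # beyond-last-limit pairs join the top pool
    labels = [f"<= {lim:g}" for lim in limits]
    out = _pool(df, idx, labels)
    out.insert(1, "upper_limit_um", limits)
    return out


def pool_pairs_by_rate(
    pairs: list[PairCorrelation] | pd.DataFrame,
    rate_bin_edges_hz: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean and s.e.m. of rho per geometric-mean-rate bin (log-spaced)."""
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    if df.empty:
        raise InvalidParameterError("need at least one pair")
    edges = (
        default_rate_edges()
        if rate_bin_edges_hz is None
        else np.asarray(rate_bin_edges_hz, dtype=float)
    )
    rates = df["geom_mean_rate_hz"].to_numpy()
    idx = np.searchsorted(edges, rates, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    labels = [f"{edges[k]:.3g}-{edges[k + 1]:.3g}" for k in range(edges.size - 1)]
    out = _pool(df, idx, labels)
    out.insert(1, "rate_bin_low_hz", edges[:-1])
    return out
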