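"""Plaque-distance geometry, binning and rate-vs-distance statistics.

Distances are Euclidean, in micrometres, from ROI centroid to plaque
center in the imaging plane.  A field of view is eligible for
plaque-distance analysis only if it contains exactly one plaque and no
other plaque lies within 100 um in x, y or z.  Neurons are pooled into
three canonical distance bins: <60 um, 60-120 um and >120 um (the 60 and
120 um boundaries belong to the middle bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import InvalidParameterError

__all__ = [
    "PlaqueField",
    "distance_to_plaque",
    "assign_distance_bin",
    "bin_rates_by_distance",
    "rate_distance_spearman",
    "DISTANCE_BIN_LABELS",
]

EXCLUSION_RADIUS_UM = 100.0
DISTANCE_BIN_EDGES = (60.0, 120.0)
DISTANCE_BIN_LABELS = ("<60", "60-120", ">120")


@dataclass(frozen=True)
class PlaqueField:
    """Eligibility record for one FOV's plaque-distance analysis."""

    fov_id: str
    plaque_center_xy: tuple[float, float] | None
    eligible: bool
    exclusion_radius_um: float = EXCLUSION_RADIUS_UM

    @classmethod
    def assess(
        cls,
        fov_id: str,
        plaque_centers: list[tuple[float, float]],
        other_plaques_within_radius: bool = False,
        exclusion_radius_um: float = EXCLUSION_RADIUS_UM,
    ) -> "PlaqueField":
        """Eligible iff exactly one plaque and no neighbour within the radius.

        ``other_plaques_within_radius`` covers plaques outside the FOV
        (including other z planes) that imaging metadata may report.
        """
        eligible = len(plaque_centers) == 1 and not other_plaques_within_radius
        return cls(
            fov_id=fov_id,
            plaque_center_xy=plaque_centers[0] if eligible else None,
            eligible=eligible,
            exclusion_radius_um=exclusion_radius_um,
        )


def distance_to_plaque(
    centroid_xy: tuple[float, float], plaque_center_xy: tuple[float, float]
) -> float:
    """In-plane Euclidean distance from an ROI centroid to the plaque center."""
    a = np.asarray(centroid_xy, dtype=float)
    b = np.asarray(plaque_center_xy, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidParameterError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


def assign_distance_bin(distance_um: float) -> str:
    """Canonical three-bin label: <60, 60-120 (inclusive), >120 um."""
    if distance_um < 0 or not np.isfinite(distance_um):
        raise InvalidParameterError(f"distance must be finite >= 0, got {distance_um}")
    lo, hi = DISTANCE_BIN_EDGES
    if distance_um < lo:
        return DISTANCE_BIN_LABELS[0]
    if distance_um <= hi:
        return DISTANCE_BIN_LABELS[1]
    return DISTANCE_BIN_LABELS[2]


def bin_rates_by_distance(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-bin neuron counts and mean/sem rates.

    Expects ``rate_hz`` and ``distance_to_plaque_um`` columns; neurons
    without a defined distance are dropped.
    """
    df = summaries.dropna(subset=["distance_to_plaque_um"]).copy()
    df["distance_bin"] = df["distance_to_plaque_um"].map(assign_distance_bin)
    out = (
        df.groupby("distance_bin")["rate_hz"]
        .agg(n="size", mean_rate_hz="mean", sem_rate_hz="sem")
        .reindex(DISTANCE_BIN_LABELS)
    )
    out["n"] = out["n"].fillna(0).astype(int)
    return out.reset_index()


def rate_distance_spearman(summaries: pd.DataFrame) -> tuple[float, float, int]:
    """Spearman rank correlation of event rate vs plaque distance.

    Returns (r, p, n); ties are handled by midranks.  Degenerate inputs
    (constant rates or distances) yield (nan, nan, n) rather than an
    exception, signalling an undefined correlation.
    """
    df = summaries.dropna(subset=["distance_to_plaque_um", "rate_hz"])
    n = len(df)
    if n < 3:
        raise InvalidParameterError("need >= 3 neurons with distances")
    rates = df["rate_hz"].to_numpy(dtype=float)
    dists = df["distance_to_plaque_um"].to_numpy(dtype=float)
    if np.ptp(rates) == 0 or np.ptp(dists) == 0:
        return float("nan"), float("nan"), n
    res = scipy.stats.spearmanr(dists, rates)
    return float(res.statistic), float(res.pvalue), n
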