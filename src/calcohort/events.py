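"""Per-neuron activity metrics and the peak-counting cross-check."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .deconvolve import EventTrain
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "NeuronSummary",
    "event_rate",
    "classify_active",
    "inactive_fraction",
    "count_peaks",
]

#: Active-neuron gate: event rate strictly greater than this (Hz).
ACTIVE_THRESHOLD_HZ = 0.01
#: Peak-counting defaults: threshold in noise SDs and merge separation.
PEAK_K_SD = 3.0
PEAK_MIN_SEPARATION_S = 1.0


@dataclass(frozen=True)
class NeuronSummary:
    """Activity summary for one ROI with its cohort tags."""

    roi_id: str
    fov_id: str
    animal_id: str
    genotype: str
    cell_type: str
    rate_hz: float
    active: bool
    distance_to_plaque_um: float | None = None


def event_rate(train: EventTrain) -> float:
    """Events per second: deconvolved event count over recording duration."""
    if train.duration_s <= 0:
        raise InvalidParameterError("recording duration must be > 0")
    return train.event_count / train.duration_s


def classify_active(rate_hz: float, threshold_hz: float = ACTIVE_THRESHOLD_HZ) -> bool:
    """Active iff the event rate strictly exceeds the threshold (0.01 Hz)."""
    if rate_hz < 0:
        raise InvalidParameterError("rate must be >= 0")
    return rate_hz > threshold_hz


def inactive_fraction(summaries: pd.DataFrame | list[NeuronSummary]) -> float:
    """Fraction of a group's neurons that fail the active gate.

    Intended to be applied per animal; accepts a summary DataFrame (with
    an ``active`` column) or a list of :class:`NeuronSummary`.
    """
    if isinstance(summaries, pd.DataFrame):
        active = summaries["active"].to_numpy(dtype=bool)
    else:
        active = np.array([s.active for s in summaries], dtype=bool)
    if active.size == 0:
        raise InvalidParameterError("need at least one neuron")
    return float(np.mean(~active))


def count_peaks(
    dff: np.ndarray,
    noise_sigma: float,
    k_sd: float = PEAK_K_SD,
    min_separation_s: float = PEAK_MIN_SEPARATION_S,
    frame_rate_hz: float = 5.0,
) -> int:
    """Deconvolution-free activity estimate: suprathreshold dF/F peaks.

    Counts local maxima above ``k_sd * noise_sigma``; maxima closer than
    ``min_separation_s`` are merged to the larger one.  Used as a sanity
    cross-check that group-level conclusions do not hinge on the
    deconvolution method.
    """
    if k_sd <= 0:
        raise InvalidParameterError("k_sd must be > 0")
    y = np.asarray(dff, dtype=float)
    if y.size < 3:
        return 0
    distance = max(1, int(round(min_separation_s * frame_rate_hz)))
    peaks, _ = scipy.signal.find_peaks(
        y, height=k_sd * noise_sigma, distance=distance
    )
    return int(peaks.size)


def summarize_neurons(table: pd.DataFrame) -> pd.DataFrame:
    """Attach the active flag to a per-neuron rate table (``rate_hz`` column)."""
    if "rate_hz" not in table.columns:
        raise InvalidInputError("table must have a rate_hz column")
    out = table.copy()
    out["active"] = out["rate_hz"] > ACTIVE_THRESHOLD_HZ
    return out
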