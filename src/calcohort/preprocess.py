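"""Raw fluorescence to normalized dF/F.

Pipeline per ROI: subtract the surrounding-neuropil signal with a fixed
weight (0.7), estimate a slowly varying baseline F0 as a rolling quantile
over a 250-frame (50 s at 5 Hz) centered window, and normalize as
dF/F = (F - F0) / F0.

The baseline quantile adapts to how active the neuron is: quiet neurons
use the median of the window, highly active neurons the 10th percentile,
so that frequent transients do not inflate the baseline.  The activity
index is the fraction of frames more than 2 MAD above the median of the
corrected trace, mapped linearly onto quantiles [0.5, 0.1] and saturating
at an index of 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateBaselineError, InvalidParameterError, ShapeError

__all__ = [
    "DffTrace",
    "neuropil_correct",
    "activity_quantile",
    "rolling_baseline",
    "compute_dff",
    "dff_from_raw",
]

DEFAULT_NEUROPIL_WEIGHT = 0.7
DEFAULT_WINDOW_FRAMES = 250
#: Quantile range spanned by the activity rule: median down to 10th percentile.
QUANTILE_HIGH = 0.5
QUANTILE_LOW = 0.1
#: Activity index at which the quantile rule saturates at QUANTILE_LOW.
ACTIVITY_SATURATION = 0.2


@dataclass(frozen=True)
class DffTrace:
    """Normalized trace with the baseline it was computed against."""

    dff: np.ndarray
    f0: np.ndarray
    quantile_used: float
    window_frames: int

    def __post_init__(self) -> None:
        if self.dff.shape != self.f0.shape:
            raise ShapeError("dff and f0 must have equal length")


def neuropil_correct(
    soma_f: np.ndarray,
    neuropil_f: np.ndarray,
    weight: float = DEFAULT_NEUROPIL_WEIGHT,
) -> np.ndarray:
    """Subtract the weighted neuropil signal from the somatic signal.

    corrected_t = soma_t - weight * neuropil_t.  Negative values are
    permitted here; only a non-positive baseline later is fatal.
    """
    soma = np.asarray(soma_f, dtype=float)
    npil = np.asarray(neuropil_f, dtype=float)
    if soma.shape != npil.shape:
        raise ShapeError(
            f"soma and neuropil lengths differ: {soma.shape} vs {npil.shape}"
        )
    if not 0.0 <= weight < 1.0:
        raise InvalidParameterError(f"weight must be in [0, 1), got {weight}")
    return soma - weight * npil


def activity_quantile(corrected: np.ndarray) -> float:
    """Baseline quantile for one neuron under the activity-adaptive rule.

    a = fraction of frames with corrected > median + 2*MAD;
    q = 0.5 - 0.4 * min(a / 0.2, 1), i.e. inactive neurons use the window
    median and strongly active ones the 10th percentile.
    """
    x = np.asarray(corrected, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    a = float(np.mean(x > med + 2.0 * mad))
    frac = min(a / ACTIVITY_SATURATION, 1.0)
    return max(QUANTILE_LOW, QUANTILE_HIGH - (QUANTILE_HIGH - QUANTILE_LOW) * frac)


def rolling_baseline(
    corrected: np.ndarray,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    quantile: float | None = None,
) -> tuple[np.ndarray, float]:
    """Rolling-quantile baseline F0 of a corrected trace.

    The window is centered and truncated at the edges; a trace shorter
    than the window falls back to a single global quantile.  When
    ``quantile`` is None it is chosen once per neuron by
    :func:`activity_quantile`.  Returns ``(f0, quantile_used)``.
    """
    x = np.asarray(corrected, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidParameterError("corrected trace must be 1-D with length >= 2")
    if window_frames < 1:
        raise InvalidParameterError("window_frames must be >= 1")
    q = activity_quantile(x) if quantile is None else float(quantile)
    if not 0.0 < q <= 0.5:
        raise InvalidParameterError(f"baseline quantile must be in (0, 0.5], got {q}")
    if x.size < window_frames:
        f0 = np.full_like(x, np.quantile(x, q))
    else:
        f0 = (
            pd.Series(x)
            .rolling(window=window_frames, center=True, min_periods=1)
            .quantile(q)
            .to_numpy()
        )
    if np.any(f0 <= 0):
        raise DegenerateBaselineError(
            "rolling baseline is non-positive somewhere; trace unusable"
        )
    return f0, q


def compute_dff(corrected: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """dF/F = (F - F0) / F0, elementwise."""
    x = np.asarray(corrected, dtype=float)
    b = np.asarray(f0, dtype=float)
    if x.shape != b.shape:
        raise ShapeError("corrected and f0 must have equal length")
    if np.any(b <= 0):
        raise DegenerateBaselineError("f0 must be strictly positive everywhere")
    return (x - b) / b


def dff_from_raw(
    soma_f: np.ndarray,
    neuropil_f: np.ndarray,
    weight: float = DEFAULT_NEUROPIL_WEIGHT,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    quantile: float | None = None,
) -> DffTrace:
    """Full preprocessing chain: correct -> baseline -> dF/F."""
    corrected = neuropil_correct(soma_f, neuropil_f, weight)
    f0, q = rolling_baseline(corrected, window_frames, quantile)
    return DffTrace(
        dff=compute_dff(corrected, f0),
        f0=f0,
        quantile_used=q,
        window_frames=window_frames,
    )
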