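"""Thresholded non-negative AR1 deconvolution of dF/F traces.

The calcium concentration proxy is modelled as a first-order
autoregressive process driven by non-negative events,

    c_t = gamma * c_{t-1} + s_t,        s_t in {0} union [s_min, inf),

where ``gamma = exp(-dt / tau)`` is set by the indicator decay time
(1.25 s for GCaMP6s/jGCaMP7s) and ``s_min`` constrains every accepted
event to be at least ``s_min_multiplier`` (2.5) times the trace noise
level.  With the sparsity penalty lambda fixed at 0, deconvolution
minimises ``||c - y||^2`` over feasible (c, s).

The solver is a greedy pool-merging scheme in the OASIS family with the
hard threshold folded into the merge condition; :func:`brute_force_oracle`
finds the exact global optimum by support enumeration on short traces and
exists purely to validate the greedy solver.

The initial condition is treated uniformly: ``s_0 = c_0`` and the
threshold constraint applies to frame 0 as well, so the greedy solver and
the oracle optimise over the identical feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "Ar1Model",
    "EventTrain",
    "gamma_from_decay",
    "estimate_noise_sigma",
    "deconvolve_ar1_thresholded",
    "brute_force_oracle",
]

#: Default indicator decay time constant in seconds (GCaMP6s / jGCaMP7s).
DEFAULT_DECAY_S = 1.25
#: Default event-size constraint: events must exceed this multiple of sigma.
DEFAULT_S_MIN_MULTIPLIER = 2.5


def gamma_from_decay(decay_time_s: float, frame_rate_hz: float) -> float:
    """AR1 coefficient implied by an exponential decay time constant.

    gamma = exp(-1 / (frame_rate * decay_time)), i.e. exp(-dt/tau) with
    dt the frame interval.  At 5 Hz and tau = 1.25 s this is
    exp(-0.16) ~= 0.852.
    """
    if decay_time_s <= 0 or frame_rate_hz <= 0:
        raise InvalidParameterError(
            f"decay_time_s and frame_rate_hz must be positive, got "
            f"{decay_time_s}, {frame_rate_hz}"
        )
    return float(np.exp(-1.0 / (frame_rate_hz * decay_time_s)))


def estimate_noise_sigma(dff: np.ndarray, frame_rate_hz: float) -> float:
    """Noise level of a trace from its high-frequency power spectral density.

    Averages the Welch PSD over the band [0.25, 0.5] * frame_rate, where
    calcium transients (decay ~1 s) contribute negligible power, and
    converts to the standard deviation of an equivalent white-noise
    process: sigma = sqrt(mean_PSD * frame_rate / 2).
    """
    y = np.asarray(dff, dtype=float)
    if y.ndim != 1 or y.size < 8:
        raise InvalidParameterError(
            f"need a 1-D trace of at least 8 samples, got shape {y.shape}"
        )
    nperseg = min(256, y.size)
    freqs, psd = scipy.signal.welch(y, fs=frame_rate_hz, nperseg=nperseg)
    band = freqs >= 0.25 * frame_rate_hz
    return float(np.sqrt(np.mean(psd[band]) * frame_rate_hz / 2.0))


@dataclass(frozen=True)
class Ar1Model:
    """Parameters of the thresholded AR1 deconvolution problem.

    Attributes
    ----------
    gamma:
        AR1 coefficient in (0, 1).
    noise_sigma:
        Trace noise level in dF/F units (>= 0).
    s_min_multiplier:
        Event-size constraint: minimum event is this multiple of sigma.
    sparsity_lambda:
        L1 penalty on events; fixed at 0 in this analysis but accepted.
    frame_rate_hz:
        Acquisition rate, used to convert frames to seconds.
    decay_time_s:
        Indicator decay time the gamma was derived from (bookkeeping).
    """

    gamma: float
    noise_sigma: float
    s_min_multiplier: float = DEFAULT_S_MIN_MULTIPLIER
    sparsity_lambda: float = 0.0
    frame_rate_hz: float = 5.0
    decay_time_s: float = DEFAULT_DECAY_S

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise InvalidParameterError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if self.s_min_multiplier <= 0:
            raise InvalidParameterError("s_min_multiplier must be > 0")
        if self.sparsity_lambda < 0:
            raise InvalidParameterError("sparsity_lambda must be >= 0")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be > 0")

    @property
    def s_min(self) -> float:
        """Minimum admissible event amplitude (2.5 x noise by default)."""
        return self.s_min_multiplier * self.noise_sigma

    @classmethod
    def from_trace(
        cls,
        dff: np.ndarray,
        frame_rate_hz: float,
        decay_time_s: float = DEFAULT_DECAY_S,
        s_min_multiplier: float = DEFAULT_S_MIN_MULTIPLIER,
        sparsity_lambda: float = 0.0,
    ) -> "Ar1Model":
        """Build a model for one trace, estimating its noise level per neuron."""
        return cls(
            gamma=gamma_from_decay(decay_time_s, frame_rate_hz),
            noise_sigma=estimate_noise_sigma(dff, frame_rate_hz),
            s_min_multiplier=s_min_multiplier,
            sparsity_lambda=sparsity_lambda,
            frame_rate_hz=frame_rate_hz,
            decay_time_s=decay_time_s,
        )


@dataclass(frozen=True)
class EventTrain:
    """Deconvolution output: per-frame event amplitudes and denoised trace."""

    event_amplitudes: np.ndarray
    denoised: np.ndarray
    frame_rate_hz: float
    s_min: float = 0.0
    objective: float = field(default=float("nan"))

    @property
    def event_count(self) -> int:
        return int(np.count_nonzero(self.event_amplitudes > 0))

    @property
    def event_frames(self) -> np.ndarray:
        return np.flatnonzero(self.event_amplitudes > 0)

    @property
    def duration_s(self) -> float:
        return self.event_amplitudes.size / self.frame_rate_hz


def _rebuild(s: np.ndarray, gamma: float, s_min: float, y: np.ndarray,
             frame_rate_hz: float) -> EventTrain:
    """Reconstruct c from s exactly so c_t = gamma*c_{t-1} + s_t holds to the bit."""
    s = np.asarray(s, dtype=float).copy()
    # snap float slack: events may undershoot s_min by rounding only
    low = (s > 0) & (s < s_min)
    s[low & (s > s_min * (1 - 1e-9))] = s_min
    s[s < 0] = 0.0
    c = np.empty_like(s)
    acc = 0.0
    for t in range(s.size):
        acc = gamma * acc + s[t] if t else s[t]
        c[t] = acc
    obj = float(np.sum((c - y) ** 2))
    return EventTrain(event_amplitudes=s, denoised=c,
                      frame_rate_hz=frame_rate_hz, s_min=s_min, objective=obj)


def deconvolve_ar1_thresholded(dff: np.ndarray, model: Ar1Model) -> EventTrain:
    """Greedy thresholded AR1 deconvolution by pool merging.

    Each frame starts as its own pool with value v, weight w and length l;
    adjacent pools are merged while the event implied at the boundary,
    ``v_next - gamma**l_prev * v_prev``, falls below ``s_min``.  Within a
    pool the denoised trace decays geometrically from the pool value.
    After the forward pass the first pool is clamped onto the feasible set
    {0} union [s_min, inf) and boundary violations introduced by the clamp
    are resolved by re-merging.  The result is a heuristic minimiser of
    ``||c - dff||^2``; see :func:`brute_force_oracle` for the exact one.
    """
    y = np.asarray(dff, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise InvalidInputError(f"dff must be a non-empty 1-D array, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("dff contains NaN or infinite values")

    gamma, s_min, lam = model.gamma, model.s_min, model.sparsity_lambda
    if lam > 0:  # OASIS residual trick: lambda shifts the target trace
        y = y - lam * (1.0 - gamma)
        y[-1] -= lam * gamma  # boundary term

    # pools as parallel lists: value, weight, start, length
    pv: list[float] = []
    pw: list[float] = []
    pt: list[int] = []
    pl: list[int] = []

    def _merge_last() -> None:
        g = gamma ** pl[-2]
        w = pw[-2] + g * g * pw[-1]
        v = (pw[-2] * pv[-2] + g * pw[-1] * pv[-1]) / w
        pv[-2], pw[-2], pl[-2] = v, w, pl[-2] + pl[-1]
        del pv[-1], pw[-1], pt[-1], pl[-1]

    for t, yt in enumerate(y):
        pv.append(float(yt)); pw.append(1.0); pt.append(t); pl.append(1)
        while len(pv) > 1 and pv[-1] < gamma ** pl[-2] * pv[-2] + s_min:
            _merge_last()

    # clamp the first pool onto {0} union [s_min, inf)
    for _ in range(y.size):  # bounded fix-up loop
        changed = False
        if pv[0] < 0.0:
            pv[0] = 0.0
            changed = True
        elif 0.0 < pv[0] < s_min:
            # pool residual under each admissible value; pools are
            # objective-separable, so this choice is local
            k = np.arange(pl[0])
            seg = y[: pl[0]]
            r0 = float(np.sum(seg**2))
            rs = float(np.sum((s_min * gamma**k - seg) ** 2))
            pv[0] = s_min if rs < r0 else 0.0
            changed = True
        if len(pv) > 1 and pv[1] < gamma ** pl[0] * pv[0] + s_min:
            # clamping raised the bar for pool 1's event: merge and retry
            g = gamma ** pl[0]
            w = pw[0] + g * g * pw[1]
            v = (pw[0] * pv[0] + g * pw[1] * pv[1]) / w
            pv[0], pw[0], pl[0] = v, w, pl[0] + pl[1]
            del pv[1], pw[1], pt[1], pl[1]
            changed = True
        if not changed:
            break

    s = np.zeros_like(y)
    prev_v = 0.0
    prev_l = 0
    for i in range(len(pv)):
        s[pt[i]] = pv[i] - (gamma**prev_l * prev_v if i else 0.0)
        prev_v, prev_l = pv[i], pl[i]
    s = _refine_support(np.asarray(dff, dtype=float), s, gamma, s_min)
    return _rebuild(s, gamma, s_min, np.asarray(dff, dtype=float),
                    model.frame_rate_hz)


def _refit_support(y: np.ndarray, support: np.ndarray, gamma: float,
                   s_min: float) -> tuple[np.ndarray, float]:
    """Constrained least squares for a fixed event support.

    Solves min ||K_S s - y||^2 subject to s >= s_min on the support via
    NNLS after the substitution u = s - s_min.  Returns (s, objective).
    """
    n = y.size
    s = np.zeros(n)
    if support.size == 0:
        return s, float(y @ y)
    tt = np.arange(n)
    Ks = np.where(tt[:, None] >= support[None, :],
                  gamma ** (tt[:, None] - support[None, :]), 0.0)
    u, rnorm = scipy.optimize.nnls(Ks, y - s_min * Ks.sum(axis=1))
    s[support] = u + s_min
    return s, float(rnorm**2)


def _refine_support(y: np.ndarray, s: np.ndarray, gamma: float,
                    s_min: float) -> np.ndarray:
    """Back-tracking refinement: add events the merge pass walked past.

    The forward pass can absorb a genuine small event into a
    neighbouring pool.  Candidate frames are screened on the residual:
    the unconstrained amplitude of an extra event at frame u is
    z_u / ||K_u||^2 with z_u the backward-filtered residual; only
    candidates whose amplitude lands strictly inside [s_min, inf) are
    refit (boundary-pinned additions merely soak noise and are
    deliberately rejected).  Repeats until no admissible addition
    improves the objective.
    """
    n = y.size
    if s_min <= 0:
        return s  # no threshold: the pool pass is already optimal
    # ||K_u||^2 = sum_{k=0}^{n-1-u} gamma^(2k)
    g2 = gamma * gamma
    norms = (1.0 - g2 ** (n - np.arange(n))) / (1.0 - g2)
    for _ in range(n):
        c = np.empty(n)
        acc = 0.0
        for t in range(n):
            acc = gamma * acc + s[t] if t else s[t]
            c[t] = acc
        r = y - c
        # z_u = sum_{t>=u} r_t gamma^(t-u), by backward recursion
        z = np.empty(n)
        acc = 0.0
        for t in range(n - 1, -1, -1):
            acc = r[t] + gamma * acc
            z[t] = acc
        amp = z / norms
        cand = np.flatnonzero((amp > s_min * (1 + 1e-9)) & (s == 0))
        if cand.size == 0:
            return s
        obj = float(r @ r)
        best = None
        for u in cand:
            support = np.sort(np.append(np.flatnonzero(s > 0), u))
            s_new, obj_new = _refit_support(y, support, gamma, s_min)
            if obj_new < obj * (1 - 1e-12) and (best is None or obj_new < best[1]):
                best = (s_new, obj_new)
        if best is None:
            return s
        s = best[0]
    return s


def brute_force_oracle(dff: np.ndarray, model: Ar1Model) -> EventTrain:
    """Exact global minimiser of the thresholded AR1 objective (test oracle).

    Enumerates every event-support subset of a short trace and solves the
    corresponding bound-constrained least-squares subproblem (via NNLS
    after shifting events by s_min).  Subsets are visited in order of
    their unconstrained objective, which lower-bounds the constrained
    one, so the search prunes aggressively.  Refuses traces longer than
    20 frames: the enumeration is exponential by construction.
    """
    y = np.asarray(dff, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise InvalidInputError("dff must be a non-empty 1-D array")
    if not np.all(np.isfinite(y)):
        raise InvalidInputError("dff contains NaN or infinite values")
    n = y.size
    if n > 20:
        raise InvalidParameterError(
            f"oracle enumerates 2^n supports; refusing n={n} > 20"
        )
    if model.sparsity_lambda != 0:
        raise InvalidParameterError("oracle implemented for lambda = 0 only")

    gamma, s_min = model.gamma, model.s_min
    # kernel matrix: column u is the AR1 impulse response started at frame u
    tt = np.arange(n)
    K = np.where(tt[:, None] >= tt[None, :],
                 gamma ** (tt[:, None] - tt[None, :]), 0.0)
    G = K.T @ K
    Ky = K.T @ y
    yy = float(y @ y)

    subsets = []
    for mask in range(1, 1 << n):
        idx = np.flatnonzero([(mask >> b) & 1 for b in range(n)])
        Gs = G[np.ix_(idx, idx)]
        a = np.linalg.solve(Gs, Ky[idx])
        uncon = yy - float(Ky[idx] @ a)
        subsets.append((uncon, idx, a))
    subsets.sort(key=lambda rec: rec[0])

    best_obj = yy  # empty support: c = 0
    best_s = np.zeros(n)
    for uncon, idx, a in subsets:
        if uncon >= best_obj:
            break  # sorted: nothing later can beat the incumbent
        if np.all(a >= s_min):
            obj, amps = uncon, a
        else:
            Ks = K[:, idx]
            shift = s_min * Ks.sum(axis=1)
            u, rnorm = scipy.optimize.nnls(Ks, y - shift)
            amps = u + s_min
            obj = rnorm**2
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_s = np.zeros(n)
            best_s[idx] = amps
    return _rebuild(best_s, gamma, s_min, y, model.frame_rate_hz)
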