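"""EMG preprocessing: movement-window detection, filtering, time normalization.

Continuous per-trial recordings are reduced to T x M non-negative
activation matrices: the movement window is located from the fingertip
speed (5% of peak), the EMG is high-pass filtered, full-wave rectified
and low-pass filtered into an envelope, time-normalized to 1000 steps and
trapezoidally integrated into 50 bins, and finally each muscle is scaled
by its maximum across the whole experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from emgsyn.dataset import EMGDataset


@dataclass(frozen=True)
class MovementWindow:
    """Movement onset/offset (seconds) and the analysis-window start.

    The analysis window runs from 100 ms before onset (clipped at the
    trace start) up to the offset.
    """

    t0: float
    t_end: float
    analysis_start: float

    def __post_init__(self) -> None:
        if not self.t0 < self.t_end:
            raise ValueError(f"t0={self.t0} must precede t_end={self.t_end}")


def detect_movement_window(
    speed: np.ndarray, rate: float, fraction: float = 0.05, pre: float = 0.1
) -> MovementWindow:
    """Locate the movement as the span where speed exceeds ``fraction`` of its peak.

    t0 is the first sample above threshold and t_end the last; the
    analysis window starts ``pre`` seconds before t0 (clipped at 0).
    """
    speed = np.asarray(speed, dtype=float)
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    peak = np.max(speed) if speed.size else 0.0
    if peak <= 0:
        raise ValueError("speed trace has no positive maximum; invalid trial")
    above = np.flatnonzero(speed >= fraction * peak)
    t0 = above[0] / rate
    t_end = above[-1] / rate
    if t_end == t0:  # single-sample crossing (e.g. fraction = 1)
        t_end = min((above[-1] + 1) / rate, (speed.size - 1) / rate)
    return MovementWindow(t0=t0, t_end=t_end, analysis_start=max(t0 - pre, 0.0))


def filter_rectify(
    emg: np.ndarray,
    rate: float,
    highpass: float = 20.0,
    lowpass: float = 3.0,
    order: int = 4,
) -> np.ndarray:
    """High-pass, full-wave rectify and zero-phase low-pass an EMG trace.

    Both Butterworth filters are applied forward-backward (``filtfilt``)
    to avoid phase distortion of onset timing.  ``emg`` may be 1-D
    (samples,) or 2-D (samples, channels); the output is clipped at zero
    (rectified envelopes are non-negative by construction, filtering can
    produce small negative ripples).
    """
    emg = np.asarray(emg, dtype=float)
    if rate <= 2 * highpass:
        raise ValueError(
            f"sampling rate {rate} Hz is too low for a {highpass} Hz high-pass"
        )
    sos_hp = signal.butter(order, highpass, btype="highpass", fs=rate, output="sos")
    sos_lp = signal.butter(order, lowpass, btype="lowpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos_hp, emg, axis=0)
    x = np.abs(x)
    x = signal.sosfiltfilt(sos_lp, x, axis=0)
    return np.maximum(x, 0.0)


def resample_integrate(
    envelope: np.ndarray, n_steps: int = 1000, n_bins: int = 50
) -> np.ndarray:
    """Time-normalize an envelope to ``n_steps`` and integrate into ``n_bins``.

    The windowed envelope is linearly resampled onto a uniform grid of
    ``n_steps`` points, treated as a piecewise-linear function, and its
    trapezoidal integral is taken over ``n_bins`` equal consecutive
    segments.  Works on 1-D (samples,) or 2-D (samples, channels) input.
    """
    envelope = np.asarray(envelope, dtype=float)
    if envelope.shape[0] < 2:
        raise ValueError("analysis window must contain at least 2 samples")
    one_d = envelope.ndim == 1
    if one_d:
        envelope = envelope[:, None]

    # resampled signal lives on the step-index grid 0..n_steps-1 (unit
    # spacing), so bin integrals are in (signal unit x step) units
    src = np.linspace(0.0, n_steps - 1.0, envelope.shape[0])
    grid = np.arange(n_steps, dtype=float)
    bounds = np.linspace(0.0, n_steps - 1.0, n_bins + 1)
    # union grid makes the trapezoidal integral exact for the piecewise-
    # linear resampled signal even when bin bounds fall between steps
    xu = np.union1d(grid, bounds)
    out = np.empty((n_bins, envelope.shape[1]))
    for m in range(envelope.shape[1]):
        resampled = np.interp(grid, src, envelope[:, m])
        yu = np.interp(xu, grid, resampled)
        cum = cumulative_trapezoid(yu, xu, initial=0.0)
        out[:, m] = np.diff(np.interp(bounds, xu, cum))
    return out[:, 0] if one_d else out


def amplitude_normalize(
    trials: np.ndarray, return_scales: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Scale each muscle by its maximum over the whole experiment.

    ``trials`` has shape (L, T, M).  Muscles that are zero everywhere are
    flagged with a warning and left at zero.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("expected a (L, T, M) stack of trials")
    scales = trials.max(axis=(0, 1))
    dead = scales <= 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} muscle(s) have all-zero signal; left unscaled",
            stacklevel=2,
        )
    safe = np.where(dead, 1.0, scales)
    out = trials / safe
    if return_scales:
        return out, scales
    return out


def flag_amplitude_outliers(trials: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean (L,) mask of trials whose max exceeds Q3 + k*IQR for any muscle.

    Automatic stand-in for visual artifact screening; off by default in
    the pipeline.
    """
    trials = np.asarray(trials, dtype=float)
    per_trial_max = trials.max(axis=1)  # (L, M)
    q1, q3 = np.percentile(per_trial_max, [25, 75], axis=0)
    limit = q3 + k * (q3 - q1)
    return np.any(per_trial_max > limit, axis=1)


def preprocess_dataset(
    raw_trials: list[dict],
    labels: pd.DataFrame,
    rate: float,
    *,
    highpass: float = 20.0,
    lowpass: float = 3.0,
    n_bins: int = 50,
    n_steps: int = 1000,
    window_fraction: float = 0.05,
) -> EMGDataset:
    """Full preprocessing chain from raw traces to a normalized EMGDataset.

    ``raw_trials`` is a list of dicts with keys ``emg`` (samples x M) and
    ``speed`` (samples,), as produced by the synthetic generator.
    """
    binned = []
    for trial in raw_trials:
        window = detect_movement_window(trial["speed"], rate, window_fraction)
        envelope = filter_rectify(trial["emg"], rate, highpass, lowpass)
        i0 = int(round(window.analysis_start * rate))
        i1 = int(round(window.t_end * rate)) + 1
        binned.append(resample_integrate(envelope[i0:i1], n_steps, n_bins))
    normalized = amplitude_normalize(np.stack(binned))
    return EMGDataset(trials=normalized, labels=labels)
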