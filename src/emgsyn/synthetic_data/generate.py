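"""Synthetic EMG generation from a planted space-by-time model.

Each trial is built as ``W_t @ A_l @ W_s`` with trial coefficients whose
class-conditional means follow a planted tuning map (each temporal synergy
is tuned to a "temporal" task parameter, each spatial synergy to a
"spatial" one), plus optional non-negative additive noise.  The planted
model is the recoverable ground truth for the downstream decomposition,
decoding and clustering stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from emgsyn.dataset import EMGDataset
from emgsyn.synthetic_data.design import (
    SPATIAL_PARAMETERS,
    TEMPORAL_PARAMETERS,
    TaskDesign,
    build_task_design,
)


def _default_temporal_tuning(K: int) -> tuple[str, ...]:
    # early synergy -> movement start, late -> movement end, middle -> direction
    if K == 1:
        return ("start_target",)
    tuning = ["direction"] * K
    tuning[0] = "start_target"
    tuning[-1] = "end_target"
    return tuple(tuning)


def _default_spatial_tuning(N: int) -> tuple[str, ...]:
    return tuple(SPATIAL_PARAMETERS[j % len(SPATIAL_PARAMETERS)] for j in range(N))


@dataclass
class GroundTruthModel:
    """Planted generative model: synergies, tuning map and noise scales.

    ``temporal_gains[i]`` (``spatial_gains[j]``) maps each class value of
    the tuned parameter of temporal synergy i (spatial synergy j) to a
    strictly positive mean gain; the mean coefficient for a movement is
    the product of the two tuned gains.
    """

    temporal_synergies: np.ndarray  # (T, K)
    spatial_synergies: np.ndarray  # (N, M)
    temporal_tuning: tuple[str, ...]
    spatial_tuning: tuple[str, ...]
    temporal_gains: tuple[dict, ...]
    spatial_gains: tuple[dict, ...]
    coefficient_noise_sigma: float = 0.2
    emg_noise_sd: float = 0.05
    seed: int | None = None

    @property
    def T(self) -> int:
        return self.temporal_synergies.shape[0]

    @property
    def K(self) -> int:
        return self.temporal_synergies.shape[1]

    @property
    def N(self) -> int:
        return self.spatial_synergies.shape[0]

    @property
    def M(self) -> int:
        return self.spatial_synergies.shape[1]


@dataclass
class SyntheticDataset:
    """A synthetic EMG dataset together with its generating ground truth."""

    emg: EMGDataset
    truth: GroundTruthModel
    raw_traces: list[dict] | None = field(default=None, repr=False)
    sampling_rate: float | None = None


def _class_gains(
    values, rng: np.random.Generator, min_gain_gap: float, base: float
) -> dict:
    """Strictly positive, pairwise-separated mean gains, one per class value."""
    values = list(values)
    levels = base + min_gain_gap * np.arange(len(values))
    rng.shuffle(levels)
    return {v: float(g) for v, g in zip(values, levels)}


def make_ground_truth(
    K: int,
    N: int,
    T: int = 50,
    M: int = 30,
    seed: int | None = None,
    *,
    coefficient_noise_sigma: float = 0.2,
    emg_noise_sd: float = 0.05,
    min_gain_gap: float = 0.25,
    temporal_tuning: tuple[str, ...] | None = None,
    spatial_tuning: tuple[str, ...] | None = None,
    design: TaskDesign | None = None,
) -> GroundTruthModel:
    """Construct a planted model with ordered temporal bumps and sparse loadings.

    Temporal synergies are truncated-Gaussian bumps of width T/(2K) whose
    peaks are staggered across [0, T); spatial synergies are sparse gamma
    draws with one dominant muscle per synergy (disjoint across synergies).
    Deterministic given ``seed``.
    """
    if K < 1 or N < 1:
        raise ValueError("K and N must be >= 1")
    if T < 2 * K:
        raise ValueError(f"T={T} too small for K={K} temporal bumps (need T >= 2K)")
    if M < N:
        raise ValueError(f"M={M} must be >= N={N}")
    rng = np.random.default_rng(seed)
    design = design if design is not None else build_task_design()

    # evenly staggered bump peaks spanning the trial
    peaks = np.linspace(T / (2 * K), T - T / (2 * K), K)
    width = T / (2 * K)
    grid = np.arange(T)[:, None]
    W_t = np.exp(-0.5 * ((grid - peaks[None, :]) / (width / 2.0)) ** 2)
    W_t[W_t < 1e-4] = 0.0

    W_s = rng.gamma(shape=0.6, scale=0.5, size=(N, M))
    dominant = rng.permutation(M)[:N]
    for j in range(N):
        W_s[j, dominant[j]] += 1.5

    temporal_tuning = (
        tuple(temporal_tuning) if temporal_tuning is not None else _default_temporal_tuning(K)
    )
    spatial_tuning = (
        tuple(spatial_tuning) if spatial_tuning is not None else _default_spatial_tuning(N)
    )
    if len(temporal_tuning) != K or len(spatial_tuning) != N:
        raise ValueError("tuning maps must have one parameter per synergy")
    for p in temporal_tuning:
        if p not in TEMPORAL_PARAMETERS:
            raise ValueError(f"{p!r} is not a temporal task parameter")
    for p in spatial_tuning:
        if p not in SPATIAL_PARAMETERS:
            raise ValueError(f"{p!r} is not a spatial task parameter")

    table = design.parameter_table
    temporal_gains = tuple(
        _class_gains(sorted(table[p].unique()), rng, min_gain_gap, base=0.5)
        for p in temporal_tuning
    )
    spatial_gains = tuple(
        _class_gains(sorted(table[p].unique()), rng, min_gain_gap, base=0.5)
        for p in spatial_tuning
    )
    return GroundTruthModel(
        temporal_synergies=W_t,
        spatial_synergies=W_s,
        temporal_tuning=temporal_tuning,
        spatial_tuning=spatial_tuning,
        temporal_gains=temporal_gains,
        spatial_gains=spatial_gains,
        coefficient_noise_sigma=coefficient_noise_sigma,
        emg_noise_sd=emg_noise_sd,
        seed=seed,
    )


def make_subject_variant(truth: GroundTruthModel, seed: int) -> GroundTruthModel:
    """Re-draw the spatial synergies while keeping the tuning map fixed.

    Emulates a new subject: muscle loadings change, functional roles do
    not, which is exactly the situation functional-similarity clustering
    targets.
    """
    rng = np.random.default_rng(seed)
    N, M = truth.spatial_synergies.shape
    W_s = rng.gamma(shape=0.6, scale=0.5, size=(N, M))
    dominant = rng.permutation(M)[:N]
    for j in range(N):
        W_s[j, dominant[j]] += 1.5
    return replace(truth, spatial_synergies=W_s, seed=seed)


def mean_gain_matrix(truth: GroundTruthModel, movement: dict) -> np.ndarray:
    """K x N matrix of mean coefficients for one movement record."""
    g_t = np.array(
        [truth.temporal_gains[i][movement[p]] for i, p in enumerate(truth.temporal_tuning)]
    )
    g_s = np.array(
        [truth.spatial_gains[j][movement[p]] for j, p in enumerate(truth.spatial_tuning)]
    )
    return np.outer(g_t, g_s)


def sample_trial_coefficients(
    truth: GroundTruthModel,
    movement: dict,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw one K x N coefficient matrix: class-mean gains times lognormal noise."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mean = mean_gain_matrix(truth, movement)
    sigma = truth.coefficient_noise_sigma
    if sigma == 0:
        return mean.copy()
    eps = rng.lognormal(mean=0.0, sigma=sigma, size=mean.shape)
    return mean * eps


def minimum_jerk_speed(n_samples: int, rate: float, duration: float, pad: float) -> np.ndarray:
    """Bell-shaped tangential speed profile (zero outside the movement)."""
    t = np.arange(n_samples) / rate
    tau = (t - pad) / duration
    speed = np.where((tau >= 0) & (tau <= 1), 30 * tau**2 * (1 - tau) ** 2, 0.0)
    return speed


def synthesize_dataset(
    truth: GroundTruthModel,
    design: TaskDesign | None = None,
    reps_per_movement: int = 30,
    seed: int | None = None,
    *,
    raw_traces: bool = False,
    sampling_rate: float = 1000.0,
    movement_duration: float = 1.0,
    pad: float = 0.4,
) -> SyntheticDataset:
    """Generate ``72 * reps_per_movement`` labelled trials from the planted model.

    Each trial is ``W_t @ A_l @ W_s`` plus additive Gaussian noise truncated
    at zero.  With ``raw_traces=True`` a continuous stand-in recording is
    attached per trial: the reconstruction is upsampled to ``sampling_rate``
    and used to amplitude-modulate a zero-mean white carrier, together with
    a minimum-jerk fingertip-speed trace.
    """
    if reps_per_movement < 1:
        raise ValueError("reps_per_movement must be >= 1")
    design = design if design is not None else build_task_design()
    rng = np.random.default_rng(seed)
    table = design.parameter_table
    L = len(table) * reps_per_movement

    trials = np.empty((L, truth.T, truth.M))
    label_rows = []
    traces: list[dict] | None = [] if raw_traces else None
    n_raw = int(round((movement_duration + 2 * pad) * sampling_rate))

    l = 0
    for _, movement in table.iterrows():
        record = movement.to_dict()
        for _ in range(reps_per_movement):
            A = sample_trial_coefficients(truth, record, rng)
            clean = truth.temporal_synergies @ A @ truth.spatial_synergies
            if truth.emg_noise_sd > 0:
                noise = rng.normal(0.0, truth.emg_noise_sd, size=clean.shape)
                trial = np.maximum(clean + noise, 0.0)
            else:
                trial = clean
            trials[l] = trial
            label_rows.append({"trial_id": l, **record})
            if traces is not None:
                traces.append(
                    _raw_trace(trial, rng, n_raw, sampling_rate, movement_duration, pad)
                )
            l += 1

    labels = pd.DataFrame(label_rows)
    emg = EMGDataset(trials=trials, labels=labels)
    return SyntheticDataset(
        emg=emg,
        truth=truth,
        raw_traces=traces,
        sampling_rate=sampling_rate if raw_traces else None,
    )


def _raw_trace(
    trial: np.ndarray,
    rng: np.random.Generator,
    n_raw: int,
    rate: float,
    duration: float,
    pad: float,
) -> dict:
    """Continuous stand-in recording for one trial.

    The 50-bin envelope is placed over the analysis window implied by the
    speed trace (from 100 ms before the 5%-of-peak onset up to the offset)
    and multiplies a zero-mean white carrier.
    """
    speed = minimum_jerk_speed(n_raw, rate, duration, pad)
    above = np.flatnonzero(speed > 0.05 * speed.max())
    t0, t_end = above[0] / rate, above[-1] / rate
    start = max(t0 - 0.1, 0.0)

    t = np.arange(n_raw) / rate
    T = trial.shape[0]
    bin_times = start + (np.arange(T) + 0.5) / T * (t_end - start)
    envelope = np.empty((n_raw, trial.shape[1]))
    for m in range(trial.shape[1]):
        envelope[:, m] = np.interp(t, bin_times, trial[:, m], left=0.0, right=0.0)
    envelope[(t < start) | (t > t_end)] = 0.0
    carrier = rng.standard_normal(envelope.shape)
    return {"emg": envelope * carrier, "speed": speed, "envelope": envelope}
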