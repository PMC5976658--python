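"""Mutual information of decoding confusion matrices, with analytic bias correction.

The plug-in estimate treats the normalized count table as the joint
distribution of true and predicted labels.  The limited-sampling upward
bias is removed with the Panzeri-Treves correction (naive counting of
occupied response bins).  Information is reported in bits, optionally as
a percentage of the maximum log2(V) afforded by a V-class parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class InfoResult:
    """Plug-in and bias-corrected mutual information of one confusion matrix."""

    info_bits: float
    bias_bits: float
    corrected_bits: float  # floored at 0
    corrected_bits_unfloored: float
    max_bits: float
    percent_of_max: float
    n_trials: int


def _validated_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    if counts.sum() <= 0:
        raise ValueError("counts table is empty")
    return counts


def mutual_information_plugin(counts: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint count table.

    I = sum P(t, tp) * log2[ P(t, tp) / (P(t) P(tp)) ], with the
    convention 0 * log(.) = 0.
    """
    counts = _validated_counts(counts)
    P = counts / counts.sum()
    Pt = np.broadcast_to(P.sum(axis=1, keepdims=True), P.shape)
    Pp = np.broadcast_to(P.sum(axis=0, keepdims=True), P.shape)
    mask = P > 0
    # log-space avoids underflow of the Pt*Pp product for extreme tables
    terms = P[mask] * (np.log2(P[mask]) - np.log2(Pt[mask]) - np.log2(Pp[mask]))
    return float(terms.sum())


def pt_corrected_information(counts: np.ndarray) -> InfoResult:
    """Panzeri-Treves bias-corrected information of a V x V confusion table.

    bias = [ sum_t (R_t - 1) - (R - 1) ] / (2 * N * ln 2), where R_t is
    the number of occupied predicted-class bins in row t and R the number
    occupied in the prediction marginal (naive counting).  The corrected
    value is floored at 0 for reporting; the unfloored value is kept.
    """
    counts = _validated_counts(counts)
    n_total = counts.sum()
    plugin = mutual_information_plugin(counts)
    r_rows = np.count_nonzero(counts > 0, axis=1)
    occupied_rows = counts.sum(axis=1) > 0
    r_marginal = np.count_nonzero(counts.sum(axis=0) > 0)
    bias = (np.sum(r_rows[occupied_rows] - 1) - (r_marginal - 1)) / (
        2.0 * n_total * np.log(2.0)
    )
    corrected = plugin - bias
    V = counts.shape[0]
    max_bits = max_information(V) if V >= 2 else 0.0
    floored = max(corrected, 0.0)
    percent = 100.0 * floored / max_bits if max_bits > 0 else 0.0
    return InfoResult(
        info_bits=plugin,
        bias_bits=float(bias),
        corrected_bits=floored,
        corrected_bits_unfloored=float(corrected),
        max_bits=max_bits,
        percent_of_max=percent,
        n_trials=int(round(float(n_total))),
    )


def max_information(V: int) -> float:
    """Maximum mutual information (bits) of a V-class parameter: log2 V."""
    if V < 2:
        raise ValueError("need at least 2 classes")
    return float(np.log2(V))


def percent_of_max(info_bits: float, V: int) -> float:
    """Information as a percentage of the log2(V) maximum."""
    if info_bits < 0:
        raise ValueError("information must be non-negative")
    return 100.0 * info_bits / max_information(V)
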