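"""Array performance metrics: ‖l‖ sensitivity curves, placement, HFC, SNR, PSD.

The Frobenius norm of the lead field, ‖l‖ = sqrt(Σ lᵢ²), quantifies the total
signal an array can measure from a source and predicts reconstruction SNR;
for statistically homogeneous channels it grows with the square root of the
channel count.  This module computes ‖l‖ curves under random channel
subsets and greedy best/worst sensor placement, the homogeneous field
correction (HFC) projector that annihilates spatially uniform interference,
the Hilbert-envelope SNR statistic, and flat-top-window PSD estimates with
dead/noisy channel flagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert, periodogram

from .errors import InvalidArgumentError, UndefinedSNRError


def forward_norm(l) -> float:
    """Frobenius norm of a lead-field vector: sqrt(Σ lᵢ²)."""
    return float(np.linalg.norm(np.asarray(l, dtype=float)))


@dataclass
class SensitivityCurve:
    """‖l_subset‖/‖l_full‖ as a function of channel (or sensor) count."""

    channel_counts: np.ndarray
    mean_ratio: np.ndarray
    sd_ratio: np.ndarray
    selection_mode: str  # "random" | "best" | "worst"
    n_iterations: int
    seed: int | None = None


def random_subset_curve(l, counts, n_iter: int = 20, seed: int = 0) -> SensitivityCurve:
    """Mean ± sd of ‖l_subset‖/‖l_full‖ over random channel subsets."""
    lv = np.asarray(l, dtype=float)
    n = lv.shape[0]
    counts = np.asarray(counts, dtype=int)
    if np.any(counts < 1) or np.any(counts > n):
        raise InvalidArgumentError(f"counts must lie in [1, {n}]")
    rng = np.random.default_rng(seed)
    full = np.linalg.norm(lv)
    mean = np.empty(counts.shape[0])
    sd = np.empty(counts.shape[0])
    for j, k in enumerate(counts):
        ratios = np.empty(n_iter)
        for it in range(n_iter):
            idx = rng.choice(n, size=int(k), replace=False)
            ratios[it] = np.linalg.norm(lv[idx]) / full
        mean[j] = ratios.mean()
        sd[j] = ratios.std(ddof=1) if n_iter > 1 else 0.0
    return SensitivityCurve(counts, mean, sd, "random", n_iter, seed)


def greedy_placement(l, mode: str = "best", sensor_ids=None):
    """Greedy sensor ordering by lead-field contribution.

    ``mode='best'`` adds the largest-contribution sensor first (judicious
    placement); ``'worst'`` the smallest.  When ``sensor_ids`` is given,
    whole sensors (their 3 channels) move together and the curve is indexed
    by sensor count; otherwise single channels are ranked.

    Returns ``(order, curve)``: the orderered unit ids and a
    :class:`SensitivityCurve` of cumulative ‖l‖/‖l_full‖.
    """
    if mode not in ("best", "worst"):
        raise InvalidArgumentError("mode must be 'best' or 'worst'")
    lv = np.asarray(l, dtype=float)
    full_sq = float(lv @ lv)
    if sensor_ids is not None:
        sids = np.asarray(sensor_ids)
        units, inverse = np.unique(sids, return_inverse=True)
        contrib = np.bincount(inverse, weights=lv**2)
    else:
        units = np.arange(lv.shape[0])
        contrib = lv**2
    order = np.argsort(-contrib if mode == "best" else contrib, kind="stable")
    cum = np.sqrt(np.cumsum(contrib[order]) / full_sq) if full_sq > 0 else np.zeros(order.shape)
    counts = np.arange(1, order.shape[0] + 1)
    curve = SensitivityCurve(counts, cum, np.zeros_like(cum), mode, 1)
    return units[order], curve


def hfc_projector(orientations) -> np.ndarray:
    """The N×N projector M = I − O O⁺ that nulls spatially uniform fields.

    O is the (N,3) channel-orientation matrix: a uniform field B produces
    channel signals O·B, which lie in the column space of O and are removed
    exactly.  M is symmetric and idempotent.
    """
    O = np.asarray(orientations, dtype=float)
    if O.ndim != 2 or O.shape[1] != 3:
        raise InvalidArgumentError("orientations must be (N,3)")
    if O.shape[0] < 4:
        raise InvalidArgumentError("HFC needs at least 4 channels")
    if np.linalg.matrix_rank(O) < 3:
        raise InvalidArgumentError("orientation matrix must have rank 3")
    return np.eye(O.shape[0]) - O @ np.linalg.pinv(O)


def hfc_project(data, orientations) -> np.ndarray:
    """Apply homogeneous field correction to (channels × samples) data."""
    M = hfc_projector(orientations)
    return M @ np.asarray(data, dtype=float)


def hilbert_envelope(x) -> np.ndarray:
    """Instantaneous amplitude |analytic signal| along the last axis."""
    return np.abs(hilbert(np.asarray(x, dtype=float), axis=-1))


def envelope_snr(envelope, active_window, rest_window) -> float:
    """(mean(active) − mean(rest)) / sd(rest) of an amplitude envelope.

    Windows are (start, stop) sample index pairs and must be disjoint.
    """
    env = np.asarray(envelope, dtype=float)
    a0, a1 = active_window
    r0, r1 = rest_window
    if not (0 <= a0 < a1 <= env.shape[-1] and 0 <= r0 < r1 <= env.shape[-1]):
        raise InvalidArgumentError("windows must lie inside the envelope")
    if max(a0, r0) < min(a1, r1):
        raise InvalidArgumentError("active and rest windows must be disjoint")
    rest = env[..., r0:r1]
    sd = float(np.std(rest))
    if sd == 0.0:
        raise UndefinedSNRError("rest-window envelope has zero variance")
    return float((np.mean(env[..., a0:a1]) - np.mean(rest)) / sd)


@dataclass
class PSDReport:
    """Amplitude spectral densities (fT/√Hz) and channel quality flags."""

    frequencies: np.ndarray  # (F,)
    asd: np.ndarray  # (N, F) fT/sqrt(Hz)
    band: tuple[float, float]
    band_mean: np.ndarray  # (N,) mean ASD in band
    flags: np.ndarray  # (N,) "ok" | "dead" | "noisy"

    @property
    def bad_channels(self) -> np.ndarray:
        return np.flatnonzero(self.flags != "ok")


def psd_and_bad_channels(
    data,
    sample_rate: float,
    chunk_duration: float = 10.0,
    band: tuple[float, float] = (60.0, 80.0),
    dead_threshold: float = 7.0,
    noisy_threshold: float = 40.0,
) -> PSDReport:
    """Chunked flat-top-window PSD with dead/noisy channel flagging.

    Data (tesla) are segmented into non-overlapping ``chunk_duration``
    chunks; a flat-top-windowed periodogram is computed per chunk and
    averaged, and the amplitude spectral density (sqrt of the PSD, reported
    in fT/√Hz) is summarised over ``band``.  Channels whose band-mean ASD is
    below ``dead_threshold`` are flagged dead; above ``noisy_threshold``,
    noisy.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n_chunk = int(round(chunk_duration * sample_rate))
    n_chunks = x.shape[1] // n_chunk
    if n_chunks < 1:
        raise InvalidArgumentError(
            f"need at least {chunk_duration} s of data for one chunk"
        )
    psd_acc = None
    for c in range(n_chunks):
        seg = x[:, c * n_chunk:(c + 1) * n_chunk]
        freqs, p = periodogram(seg, fs=sample_rate, window="flattop", axis=-1)
        psd_acc = p if psd_acc is None else psd_acc + p
    psd = psd_acc / n_chunks
    asd = np.sqrt(psd) * 1e15  # T/sqrt(Hz) -> fT/sqrt(Hz)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_mean = asd[:, in_band].mean(axis=1)
    flags = np.where(band_mean < dead_threshold, "dead",
                     np.where(band_mean > noisy_threshold, "noisy", "ok"))
    return PSDReport(freqs, asd, band, band_mean, flags)
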