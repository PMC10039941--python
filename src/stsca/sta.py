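"""Temporal spike-triggered averaging of a single LFP trace.

The STA at lag tau is the mean LFP value tau seconds after each trigger
spike; it is the spike-LFP cross-correlation normalized by the spike count.
Spikes whose window would leave the recording are dropped (not zero-padded)
and counted in ``n_dropped``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Recording, SpikeTrain
from .noisestats import combine_plus_minus
from .preprocess import array_mean_lfp

__all__ = ["STAResult", "compute_sta", "subset_sta", "cross_population_sta"]


@dataclass(eq=False)
class STAResult:
    values: np.ndarray
    lags_s: np.ndarray
    n_spikes: int
    noise_estimate: np.ndarray
    snr_db: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != self.lags_s.shape or self.values.shape != self.noise_estimate.shape:
            raise ValueError("values, lags_s and noise_estimate must share a shape")
        if self.n_spikes < 1:
            raise ValueError("n_spikes must be >= 1")


def _retained_indices(n_samples: int, half: int, idx: np.ndarray) -> np.ndarray:
    return idx[(idx >= half) & (idx < n_samples - half)]


def compute_sta(
    lfp: np.ndarray,
    fs_hz: float,
    spike_times_s: np.ndarray,
    window_s: float,
) -> STAResult:
    """Average the LFP trace in ±window_s around each spike time.

    Parameters
    ----------
    lfp : 1-D array, microvolts.
    fs_hz : sampling rate of ``lfp``.
    spike_times_s : trigger times in seconds (any order).
    window_s : half-width of the lag window in seconds.

    The noise estimate and SNR come from the plus-minus even/odd split; for
    a single retained spike both are NaN.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    if lfp.ndim != 1:
        raise ValueError("lfp must be 1-D")
    half = int(round(window_s * fs_hz))
    lags = np.arange(-half, half + 1)
    idx_all = np.asarray(np.round(np.asarray(spike_times_s, dtype=np.float64) * fs_hz), dtype=np.int64)
    idx = _retained_indices(lfp.shape[0], half, idx_all)
    n_dropped = idx_all.shape[0] - idx.shape[0]
    if idx.shape[0] == 0:
        raise ValueError("no spikes retained inside the recording window")

    def accumulate_idx(indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        segs = lfp[indices[:, None] + lags[None, :]]
        return segs.sum(axis=0), np.full(lags.shape, indices.shape[0], dtype=np.int64)

    sums, counts = accumulate_idx(idx)
    values = sums / counts
    if idx.shape[0] >= 2:
        ordered = np.sort(idx)
        pm = combine_plus_minus(
            *accumulate_idx(ordered[0::2]), *accumulate_idx(ordered[1::2])
        )
        noise = pm.noise
        snr = pm.snr_db
    else:
        noise = np.full(lags.shape, np.nan)
        snr = float("nan")
    return STAResult(
        values=values,
        lags_s=lags / fs_hz,
        n_spikes=int(idx.shape[0]),
        noise_estimate=noise,
        snr_db=snr,
        n_dropped=int(n_dropped),
    )


def subset_sta(
    recording_lfp: Recording,
    spikes: SpikeTrain,
    channel_subset,
    window_s: float,
) -> STAResult:
    """STA using only spikes from, and LFP averaged over, a channel subset.

    Emulates sparse sampling of the array (e.g. a random pick of eight
    electrodes).
    """
    subset = sorted({int(c) for c in channel_subset})
    if len(subset) == 0:
        raise ValueError("channel subset must not be empty")
    rows = recording_lfp.channel_index(subset)
    sub_rec = Recording(
        recording_lfp.signals[rows],
        recording_lfp.fs_hz,
        np.array(subset, dtype=np.int64),
        recording_lfp.t0_s,
        None if recording_lfp.exclusion_mask is None else recording_lfp.exclusion_mask[rows],
    )
    sub_spikes = spikes.for_channels(subset)
    if len(sub_spikes) == 0:
        raise ValueError("no spikes on the requested channel subset")
    lfp = array_mean_lfp(sub_rec)
    return compute_sta(lfp, recording_lfp.fs_hz, sub_spikes.times_s, window_s)


def cross_population_sta(
    recording_lfp: Recording,
    spikes: SpikeTrain,
    trigger_channels,
    signal_channels,
    window_s: float,
) -> STAResult:
    """STA with decoupled trigger and signal populations: spikes from
    ``trigger_channels`` trigger on the mean LFP of ``signal_channels``."""
    sig = sorted({int(c) for c in signal_channels})
    trig = sorted({int(c) for c in trigger_channels})
    if not sig or not trig:
        raise ValueError("trigger and signal channel sets must be non-empty")
    rows = recording_lfp.channel_index(sig)
    sub_rec = Recording(
        recording_lfp.signals[rows],
        recording_lfp.fs_hz,
        np.array(sig, dtype=np.int64),
        recording_lfp.t0_s,
        None if recording_lfp.exclusion_mask is None else recording_lfp.exclusion_mask[rows],
    )
    sub_spikes = spikes.for_channels(trig)
    if len(sub_spikes) == 0:
        raise ValueError("no spikes on the trigger channels")
    lfp = array_mean_lfp(sub_rec)
    return compute_sta(lfp, recording_lfp.fs_hz, sub_spikes.times_s, window_s)
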